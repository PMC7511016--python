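"""Equal-area habitat classification and den tallies.

The raw RSF surface is cut into five classes holding equal numbers of
unmasked pixels (breakpoints at the 20/40/60/80 quantiles, upper-inclusive);
"prime" denning habitat is the union of the top two classes.  Because only
pixel ranks matter, the classification is invariant under any strictly
increasing transform of the surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import Grid

CLASS_LABELS = ("low", "low-moderate", "moderate", "moderate-high", "high")


def share_percent(part: float, whole: float) -> int:
    """Percentage of part in whole, rounded half away from zero."""
    if whole == 0:
        raise ValueError("whole must be nonzero")
    return int(np.floor(100.0 * part / whole + 0.5))


@dataclass
class ClassifiedSurface:
    """A raw surface plus its equal-area class grid and breakpoints."""

    raw: Grid
    breakpoints: np.ndarray     # upper limits of classes 1..n-1, ascending
    classes: Grid               # 1..n labels, NaN where raw is nodata
    class_areas_km2: np.ndarray
    labels: tuple[str, ...] = CLASS_LABELS

    @property
    def n_classes(self) -> int:
        return len(self.class_areas_km2)

    def prime_mask(self) -> Grid:
        """1 where the cell is in the top two classes (prime habitat)."""
        c = self.classes.data
        return self.classes.like(
            np.where(np.isfinite(c), (c >= self.n_classes - 1).astype(float), np.nan))


def equal_area_classify(surface: Grid, n_classes: int = 5) -> ClassifiedSurface:
    """Classify a surface into ``n_classes`` equal-pixel-count classes.

    Breakpoints are order statistics of the unmasked pixel values, upper
    inclusive: a value equal to a breakpoint falls in the lower class.
    Raises when heavy ties spanning a quantile make an equal split
    impossible, reporting the split actually achievable.
    """
    vals = surface.data[np.isfinite(surface.data)]
    if np.unique(vals).size < n_classes:
        raise ValueError(f"need at least {n_classes} distinct unmasked values")
    m = vals.size
    order = np.sort(vals)
    idx = [int(np.ceil(m * (i + 1) / n_classes)) - 1 for i in range(n_classes - 1)]
    breakpoints = order[idx]
    if np.unique(breakpoints).size < n_classes - 1:
        raise ValueError("ties span class boundaries; equal split impossible")
    labels = np.searchsorted(breakpoints, surface.data, side="left") + 1.0
    labels = np.where(np.isfinite(surface.data), labels, np.nan)
    counts = np.array([(labels == c).sum() for c in range(1, n_classes + 1)])
    if counts.max() - counts.min() > max(1, int(0.001 * m)):
        raise ValueError(
            "ties prevent an equal-area split; achievable class counts: "
            f"{counts.tolist()}")
    areas = counts * surface.cell_area / 1e6
    return ClassifiedSurface(surface, breakpoints, surface.like(labels), areas)


def tally_dens(classified: ClassifiedSurface, dens: pd.DataFrame) -> pd.DataFrame:
    """Den counts and whole-percent shares per habitat class.

    Dens on nodata cells land in an ``unclassified`` row (logged via the
    count) rather than silently vanishing.  Percentages are computed from
    raw counts, then rounded.
    """
    c = classified.classes.sample(dens["x"].to_numpy(), dens["y"].to_numpy())
    n = len(dens)
    rows = []
    for cls in range(1, classified.n_classes + 1):
        count = int(np.sum(c == cls))
        rows.append((classified.labels[cls - 1], count, share_percent(count, n)))
    unclassified = int(np.sum(~np.isfinite(c)))
    if unclassified:
        rows.append(("unclassified", unclassified, share_percent(unclassified, n)))
    return pd.DataFrame(rows, columns=["class", "count", "percent"])


def tally_percentages(counts) -> list[int]:
    """Whole-percent shares for a vector of per-class den counts."""
    counts = np.asarray(counts)
    total = counts.sum()
    return [share_percent(c, total) for c in counts]


def prime_share_percent(counts) -> int:
    """Percent of dens in the top two classes, counts ordered low -> high."""
    counts = np.asarray(counts)
    return share_percent(counts[-2:].sum(), counts.sum())
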