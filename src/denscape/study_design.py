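"""Study-area mask, used-available design table, and collinearity screen.

Availability is defined at the scale of the whole study area (second-order
selection): the mask is the survey-route buffer minus forest, low elevation
and glaciers, and available points are drawn uniformly over the continuous
unmasked area at a fixed density.  Used dens and available points are pooled
at the population level (Design II) into a single table of standardized
covariate rows for logistic RSF fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString

from .raster import Grid, require_aligned
from .terrain_covariates import COVARIATE_NAMES, CovariateStack

log = logging.getLogger(__name__)


def mask_area_km2(mask: Grid) -> float:
    """Unmasked (value == 1) area in km^2."""
    return float(np.nansum(mask.data == 1) * mask.cell_area / 1e6)


def build_study_mask(dtm: Grid, vhi: Grid, glacier_mask: Grid,
                     route: LineString, buffer_m: float = 1500.0,
                     min_elev: float = 300.0,
                     forest_vhi: float = 5.0) -> Grid:
    """Study-area mask: route buffer minus forest, low ground and glaciers.

    A cell is retained when its centre lies within ``buffer_m`` of the
    survey route, its elevation is at least ``min_elev`` (m), its vegetation
    height index does not exceed ``forest_vhi`` (m), and it is not glacier.
    """
    require_aligned(dtm, vhi, glacier_mask)
    x, y = dtm.center_coords()
    if buffer_m > 0:
        buf = route.buffer(buffer_m)
        inside = shapely.contains_xy(buf, x.ravel(), y.ravel()).reshape(dtm.shape)
    else:
        # degenerate buffer: cells whose footprint the route line touches
        half = dtm.cell_size / 2.0
        boxes = shapely.box(x.ravel() - half, y.ravel() - half,
                            x.ravel() + half, y.ravel() + half)
        inside = shapely.intersects(boxes, route).reshape(dtm.shape)
    ok = (inside
          & (dtm.data >= min_elev)
          & (vhi.data <= forest_vhi)
          & (glacier_mask.data != 1)
          & np.isfinite(dtm.data) & np.isfinite(vhi.data))
    if not ok.any():
        raise ValueError("study-area mask is empty")
    mask = dtm.like(ok.astype(float))
    log.info("study-area mask: %.2f km2 (%d cells)",
             mask_area_km2(mask), int(ok.sum()))
    return mask


def draw_available(mask: Grid, density_per_km2: float = 500.0,
                   seed: int = 0) -> pd.DataFrame:
    """Uniform random available points over the unmasked area.

    The point count is ``round(density * area_km2)``; points are uniform
    over the continuous unmasked surface (uniform cell choice plus uniform
    jitter within the cell), deterministic per seed.
    """
    rows, cols = np.nonzero(mask.data == 1)
    if rows.size == 0:
        raise ValueError("mask is empty")
    n = int(round(density_per_km2 * mask_area_km2(mask)))
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, rows.size, size=n)
    u = rng.uniform(0, 1, size=n)
    v = rng.uniform(0, 1, size=n)
    x = mask.x0 + (cols[pick] + u) * mask.cell_size
    y = mask.y0 - (rows[pick] + v) * mask.cell_size
    return pd.DataFrame({"x": x, "y": y, "label": "available"})


def extract_covariates(points: pd.DataFrame, stack: CovariateStack,
                       strict: bool = False) -> pd.DataFrame:
    """Attach standardized covariate values to a point table.

    Values come from the cell containing each point (half-open cell
    convention).  Rows hitting nodata in any covariate are dropped with a
    logged count; in strict mode dropping more than 10% of rows is an error.
    """
    if not stack.standardized:
        raise ValueError("extract_covariates requires a standardized stack")
    out = points.reset_index(drop=True).copy()
    x = out["x"].to_numpy(dtype=float)
    y = out["y"].to_numpy(dtype=float)
    for name in COVARIATE_NAMES:
        out[name] = stack.grids[name].sample(x, y)
    keep = np.isfinite(out[list(COVARIATE_NAMES)].to_numpy()).all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        log.info("extract_covariates: dropped %d/%d rows on nodata",
                 dropped, len(out))
        if strict and dropped > 0.1 * len(out):
            raise ValueError(f"{dropped}/{len(out)} rows dropped on nodata")
    return out[keep].reset_index(drop=True)


@dataclass
class CollinearityReport:
    """Pairwise correlations and variance inflation factors of covariates."""

    correlation: pd.DataFrame
    vif: pd.Series
    flagged_pairs: list[tuple[str, str, float]]
    flagged_vif: list[tuple[str, float]]

    @property
    def ok(self) -> bool:
        return not self.flagged_pairs and not self.flagged_vif


def collinearity_screen(data: pd.DataFrame, r_max: float = 0.7,
                        vif_max: float = 2.0,
                        covariates: tuple[str, ...] | None = None
                        ) -> CollinearityReport:
    """Screen covariates for collinearity; report, never auto-drop.

    Flags covariate pairs with Pearson |r| >= r_max and covariates with
    VIF = 1/(1 - R^2) >= vif_max, where R^2 comes from regressing each
    covariate on all the others.  The analyst decides what to do: the
    candidate model set is fixed a priori, so automatic removal would
    silently change it.
    """
    names = list(covariates or [c for c in COVARIATE_NAMES if c in data.columns])
    if len(names) < 2:
        raise ValueError("need at least two covariates to screen")
    X = data[names].to_numpy(dtype=float)
    corr = pd.DataFrame(np.corrcoef(X, rowvar=False), index=names, columns=names)
    flagged_pairs = [
        (names[i], names[j], float(corr.iloc[i, j]))
        for i in range(len(names)) for j in range(i + 1, len(names))
        if abs(corr.iloc[i, j]) >= r_max
    ]
    vifs = {}
    for j, name in enumerate(names):
        yj = X[:, j]
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
        vifs[name] = float(np.inf) if r2 >= 1.0 else 1.0 / (1.0 - r2)
    vif = pd.Series(vifs, name="vif")
    flagged_vif = [(n, v) for n, v in vif.items() if v >= vif_max]
    return CollinearityReport(corr, vif, flagged_pairs, flagged_vif)
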