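"""Helicopter-activity intensity, disturbance-risk surface, and overlap
summaries.

Flight-track fixes become a bivariate Gaussian kernel-density surface with
the bandwidth chosen by least-squares cross-validation (LSCV); the raw
intensity multiplied by the raw denning RSF gives the impact-risk surface,
whose top quantile classes mark where high-quality denning terrain meets
intense helicopter use.  Overlap summaries tally prime-habitat area and den
counts inside and outside permitted ski areas and per risk class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .habitat_map import ClassifiedSurface, equal_area_classify, share_percent
from .raster import Grid, require_aligned

log = logging.getLogger(__name__)

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class IntensitySurface:
    """Kernel-density helicopter-use surface with its chosen bandwidth."""

    kde: Grid                    # density, integrates to ~1 over the extent
    bandwidth: tuple[float, float]   # (hx, hy) in metres
    quantile_classes: ClassifiedSurface


@dataclass
class RiskSurface:
    """Cellwise product of intensity and RSF with quantile classes."""

    risk: Grid
    classes: ClassifiedSurface


def _lscv_score(d2: np.ndarray, n: int, h: float) -> float:
    """LSCV(h) on standardized coordinates, up to the positive scale factor
    common to all h (which does not move the argmin).

    For the isotropic Gaussian kernel the integrated squared density has the
    closed form (1/(4 pi n^2 h^2)) sum_ij exp(-d2/(4h^2)) and the
    leave-one-out term is (1/(2 pi n(n-1) h^2)) sum_{i != j} exp(-d2/(2h^2));
    ``d2`` holds the i<j pairwise squared distances.
    """
    h2 = h * h
    int_f2 = (n + 2.0 * np.exp(-d2 / (4.0 * h2)).sum()) / (4.0 * np.pi * n * n * h2)
    loo = np.exp(-d2 / (2.0 * h2)).sum() / (np.pi * n * (n - 1) * h2)
    return int_f2 - 2.0 * loo


def _pairwise_sq_dists(pts: np.ndarray, max_chunk: int = 512) -> np.ndarray:
    """Condensed (i<j) squared distances, computed in row chunks."""
    n = len(pts)
    out = []
    for start in range(0, n, max_chunk):
        block = pts[start:start + max_chunk]
        d = ((block[:, None, :] - pts[None, start:, :]) ** 2).sum(-1)
        ii, jj = np.triu_indices(d.shape[0], k=1, m=d.shape[1])
        out.append(d[ii, jj])
    return np.concatenate(out)


def lscv_bandwidth(xy: np.ndarray, h_lo: float = 0.05, h_hi: float = 3.0,
                   tol: float = 1e-3) -> float:
    """Golden-section LSCV minimizer for the common bandwidth multiplier.

    Operates on coordinates standardized per axis, searching log10(h)
    between ``h_lo`` and ``h_hi`` times the reference scale n**(-1/6)
    (the normal-reference rate for a 2-D Gaussian kernel).
    """
    n = len(xy)
    d2 = _pairwise_sq_dists(xy)
    ref = n ** (-1.0 / 6.0)
    lo, hi = np.log10(h_lo * ref), np.log10(h_hi * ref)
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc = _lscv_score(d2, n, 10 ** c)
    fd = _lscv_score(d2, n, 10 ** d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = _lscv_score(d2, n, 10 ** c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = _lscv_score(d2, n, 10 ** d)
    return float(10 ** ((a + b) / 2.0))


def kde_lscv(fixes: pd.DataFrame, grid_template: Grid,
             bandwidth: tuple[float, float] | None = None) -> IntensitySurface:
    """Helicopter-intensity surface by Gaussian KDE with LSCV bandwidth.

    Coordinates are standardized per axis and a single LSCV multiplier is
    searched, giving per-axis bandwidths (h sx, h sy) in metres; the
    bandwidth is floored at one cell size (with a warning) to keep
    duplicate-heavy data from collapsing the kernel.  The density is
    evaluated exactly on the template grid's cell centres.
    """
    x = fixes["x"].to_numpy(dtype=float)
    y = fixes["y"].to_numpy(dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 fixes")
    if bandwidth is None:
        sx, sy = x.std(ddof=1), y.std(ddof=1)
        std = np.column_stack([(x - x.mean()) / sx, (y - y.mean()) / sy])
        h = lscv_bandwidth(std)
        hx, hy = h * sx, h * sy
    else:
        hx, hy = bandwidth
    cs = grid_template.cell_size
    if hx < cs or hy < cs:
        log.warning("LSCV bandwidth (%.1f, %.1f) m floored at one cell size",
                    hx, hy)
        hx, hy = max(hx, cs), max(hy, cs)
    gx = grid_template.x0 + (np.arange(grid_template.nx) + 0.5) * cs
    gy = grid_template.y0 - (np.arange(grid_template.ny) + 0.5) * cs
    phix = np.exp(-0.5 * ((gx[:, None] - x[None, :]) / hx) ** 2) \
        / (np.sqrt(2 * np.pi) * hx)
    phiy = np.exp(-0.5 * ((gy[:, None] - y[None, :]) / hy) ** 2) \
        / (np.sqrt(2 * np.pi) * hy)
    dens = (phiy @ phix.T) / n
    kde = grid_template.like(dens)
    classes = quantile_classify(kde)
    return IntensitySurface(kde, (float(hx), float(hy)), classes)


def quantile_classify(intensity: Grid, n: int = 5) -> ClassifiedSurface:
    """Five quantile (equal-pixel-count) intensity classes, low to high."""
    return equal_area_classify(intensity, n_classes=n)


def risk_product(intensity: Grid, rsf: Grid) -> RiskSurface:
    """Impact-risk surface: cellwise product of raw intensity and raw RSF.

    The product is then cut into five quantile classes; the top class marks
    where prime denning habitat coincides with the most intense helicopter
    use.  Classification of the product is invariant to any common positive
    rescaling of either factor.
    """
    require_aligned(intensity, rsf)
    risk = intensity.like(intensity.data * rsf.data)
    return RiskSurface(risk, equal_area_classify(risk))


def _valid_polygons(permits) -> list[Polygon]:
    out = []
    for p in permits:
        if not p.is_valid:
            p = shapely.make_valid(p)
            if not p.is_valid or p.is_empty:
                raise ValueError("invalid permit polygon (repair failed)")
        out.append(p)
    return out


def overlap_summary(prime: Grid, permits, dens: pd.DataFrame,
                    risk_classes: ClassifiedSurface | None = None) -> dict:
    """Overlap statistics between prime habitat, permit areas and dens.

    Reports prime-habitat area inside/outside the permitted ski polygons
    (km^2 and whole percent), den counts inside/outside, den counts per
    impact-risk class (with the share in the top two classes), and the
    distance to the nearest permit boundary for each den strictly inside a
    permit area.  Percentages are always derived from the raw counts/areas
    and only then rounded.
    """
    permits = _valid_polygons(permits)
    union = unary_union(permits)
    x, y = prime.center_coords()
    is_prime = prime.data == 1
    inside_cells = shapely.contains_xy(union, x.ravel(), y.ravel()
                                       ).reshape(prime.shape)
    prime_km2 = float(is_prime.sum()) * prime.cell_area / 1e6
    overlap_km2 = float((is_prime & inside_cells).sum()) * prime.cell_area / 1e6
    dx = dens["x"].to_numpy(dtype=float)
    dy = dens["y"].to_numpy(dtype=float)
    den_inside = shapely.contains_xy(union, dx, dy)
    n_dens = len(dens)
    boundary = union.boundary
    dist_inside = np.array([
        shapely.distance(shapely.points(xi, yi), boundary)
        for xi, yi in zip(dx[den_inside], dy[den_inside])])
    report = {
        "prime_km2": prime_km2,
        "prime_overlap_km2": overlap_km2,
        "prime_overlap_percent": share_percent(overlap_km2, prime_km2),
        "dens_total": n_dens,
        "dens_inside": int(den_inside.sum()),
        "dens_outside": int(n_dens - den_inside.sum()),
        "dens_inside_percent": share_percent(int(den_inside.sum()), n_dens),
        "dens_outside_percent": share_percent(int(n_dens - den_inside.sum()),
                                              n_dens),
        "inside_boundary_distance_m": dist_inside,
    }
    if risk_classes is not None:
        c = risk_classes.classes.sample(dx, dy)
        counts = [int(np.sum(c == i)) for i in range(1, risk_classes.n_classes + 1)]
        top2 = int(sum(counts[-2:]))
        report["dens_per_risk_class"] = counts
        report["dens_top2_risk"] = top2
        report["dens_top2_risk_percent"] = share_percent(top2, n_dens)
    return report
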