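"""Terrain and climate covariates derived from elevation rasters.

Computes the eight den-selection covariates from a digital terrain model
(DTM) and digital surface model (DSM):

``dtm``       elevation (m)
``slope``     Horn finite-difference slope (degrees)
``tpi``       topographic position index: elevation minus the mean elevation
              of cells within a 140-m circular window (centre excluded);
              positive = convex terrain
``vrm``       vector ruggedness measure over a 15-m neighbourhood: one minus
              the normalized resultant of unit surface normals
``twi``       topographic wetness index ln(a / tan(slope)) with specific
              catchment area a from multiple-flow-direction routing
``solrad``    clear-sky daily solar radiation for 1 April (Wh m-2 day-1)
``snow.load`` product of elevation scaled 0-1 and leeward exposure, maximal
              opposite the prevailing wind bearing
``vhi``       vegetation height index DSM - DTM (m); > 5 m is forest

plus ``aspect`` (degrees clockwise from north, nodata where flat), which is
an ingredient of vrm/solrad/snow.load but not itself a model covariate.
Covariates are standardized (x - mean)/sd against a reference sample before
any selection modelling.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import Grid, require_aligned

#: covariates that enter selection models, in canonical order
COVARIATE_NAMES = ("dtm", "slope", "tpi", "vrm", "twi", "solrad",
                   "snow.load", "vhi")

FOREST_VHI_M = 5.0          # canopy taller than this is forest
TAN_BETA_FLOOR = np.tan(np.radians(0.1))  # slope floor in the TWI ratio


# ---------------------------------------------------------------------------
# covariate stack container

@dataclass
class CovariateStack:
    """Aligned named covariate grids with optional standardization state."""

    grids: dict[str, Grid]
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)
    standardized: bool = False

    def __post_init__(self) -> None:
        require_aligned(*self.grids.values())

    @property
    def template(self) -> Grid:
        return next(iter(self.grids.values()))

    def term_values(self, term: str) -> np.ndarray:
        """Value matrix for a model term: ``name`` or ``name_sq``."""
        if term.endswith("_sq"):
            base = self.term_values(term[:-3])
            return base ** 2
        if term not in self.grids:
            raise KeyError(f"unknown covariate {term!r}")
        return self.grids[term].data

    def destandardize(self, name: str, values):
        """Inverse of the standardizing transform for one covariate."""
        mean, sd = self.standardization[name]
        return np.asarray(values) * sd + mean


def slope_aspect(dtm: Grid) -> tuple[Grid, Grid]:
    """Slope (degrees) and aspect (degrees clockwise from north) by Horn's
    3x3 finite differences.

    Aspect is the downslope bearing and is nodata where the gradient
    vanishes; edge cells are nodata.
    """
    if dtm.ny < 3 or dtm.nx < 3:
        raise ValueError("dtm must have at least 3x3 cells")
    z = dtm.data
    cs = dtm.cell_size
    wx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]) / (8.0 * cs)
    wy = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]]) / (8.0 * cs)
    p = ndimage.correlate(z, wx, mode="nearest")  # dz/dx (east)
    q = ndimage.correlate(z, wy, mode="nearest")  # dz/dy (north)
    slope = np.degrees(np.arctan(np.hypot(p, q)))
    with np.errstate(invalid="ignore"):
        aspect = np.degrees(np.arctan2(-p, -q)) % 360.0
    aspect[(p == 0) & (q == 0)] = np.nan
    for a in (slope, aspect):
        a[0, :] = a[-1, :] = np.nan
        a[:, 0] = a[:, -1] = np.nan
    return dtm.like(slope), dtm.like(aspect)


def _window_kernel(radius_cells: float, exclude_centre: bool) -> np.ndarray:
    r = int(np.floor(radius_cells))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    k = (np.hypot(dy, dx) <= radius_cells).astype(float)
    if exclude_centre:
        k[r, r] = 0.0
    return k


def tpi(dtm: Grid, radius_m: float = 140.0) -> Grid:
    """Topographic position index over a circular moving window.

    TPI(c) = z(c) - mean{z(n) : 0 < dist(c, n) <= radius}; the centre cell
    is excluded from the mean and cells near the grid edge use whatever
    neighbours are available.  Positive values indicate convex terrain.
    """
    if radius_m < dtm.cell_size:
        raise ValueError("radius must be at least one cell size")
    z = dtm.data
    k = _window_kernel(radius_m / dtm.cell_size, exclude_centre=True)
    valid = np.isfinite(z).astype(float)
    zf = np.where(np.isfinite(z), z, 0.0)
    num = ndimage.correlate(zf, k, mode="constant", cval=0.0)
    den = ndimage.correlate(valid, k, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = z - num / den
    return dtm.like(out)


def vrm(slope: Grid, aspect: Grid, window_m: float = 15.0) -> Grid:
    """Vector ruggedness measure: 1 - |sum of unit normals| / N.

    Unit surface normals n = (sin s sin a, sin s cos a, cos s) are summed
    over a square window (15 m = 3x3 cells at 5-m resolution); flat cells
    (undefined aspect) contribute the vertical normal.  0 = smooth terrain,
    values approach 1 only in extremely rugged terrain.
    """
    require_aligned(slope, aspect)
    w = int(round(window_m / slope.cell_size))
    if w < 1:
        raise ValueError("window smaller than one cell")
    s = np.radians(slope.data)
    a = np.radians(aspect.data)
    flat = ~np.isfinite(a)
    a = np.where(flat, 0.0, a)
    nx = np.sin(s) * np.sin(a)
    ny = np.sin(s) * np.cos(a)
    nz = np.cos(s)
    nx = np.where(flat, 0.0, nx)
    ny = np.where(flat, 0.0, ny)
    nz = np.where(flat & np.isfinite(s), 1.0, nz)
    valid = np.isfinite(nz)
    sums = []
    for comp in (nx, ny, nz):
        comp = np.where(valid, comp, 0.0)
        sums.append(ndimage.uniform_filter(comp, size=w, mode="constant",
                                           cval=0.0) * w * w)
    count = ndimage.uniform_filter(valid.astype(float), size=w,
                                   mode="constant", cval=0.0) * w * w
    resultant = np.sqrt(sums[0] ** 2 + sums[1] ** 2 + sums[2] ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 1.0 - resultant / count
    out = np.where(valid, np.clip(out, 0.0, 1.0), np.nan)
    return slope.like(out)


# ---------------------------------------------------------------------------
# hydrology: pit filling and multiple-flow-direction accumulation

_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]


def fill_pits(dtm: Grid) -> Grid:
    """Priority-flood depression filling (raises pits to their spill level)."""
    z = dtm.data
    ny, nx = z.shape
    filled = np.full_like(z, np.inf)
    closed = np.zeros(z.shape, dtype=bool)
    heap: list[tuple[float, int, int]] = []
    for r in range(ny):
        for c in (0, nx - 1):
            heapq.heappush(heap, (z[r, c], r, c))
            closed[r, c] = True
    for c in range(1, nx - 1):
        for r in (0, ny - 1):
            heapq.heappush(heap, (z[r, c], r, c))
            closed[r, c] = True
    while heap:
        zv, r, c = heapq.heappop(heap)
        filled[r, c] = zv
        for dr, dc in _NEIGHBOURS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < ny and 0 <= cc < nx and not closed[rr, cc]:
                closed[rr, cc] = True
                heapq.heappush(heap, (max(z[rr, cc], zv), rr, cc))
    return dtm.like(filled)


def flow_accumulation(dtm: Grid, method: str = "md8",
                      md_exponent: float = 1.1) -> Grid:
    """Flow accumulation (m^2 of upslope area, own cell included).

    ``md8`` distributes each cell's accumulated area among all lower
    8-neighbours with weights proportional to (drop/distance)**md_exponent
    (Freeman's multiple-flow-direction scheme); ``d8`` sends everything to
    the steepest-descent neighbour and exists as the simple oracle variant.
    Run on a pit-filled surface so every cell drains to the edge.
    """
    if method not in ("md8", "d8"):
        raise ValueError("method must be 'md8' or 'd8'")
    z = dtm.data
    ny, nx = z.shape
    cs = dtm.cell_size
    acc = np.full(z.shape, cs * cs)
    order = np.argsort(z, axis=None)[::-1]  # highest first
    for idx in order:
        r, c = divmod(int(idx), nx)
        zv = z[r, c]
        slopes = []
        for dr, dc in _NEIGHBOURS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < ny and 0 <= cc < nx and z[rr, cc] < zv:
                dist = cs * np.hypot(dr, dc)
                slopes.append(((zv - z[rr, cc]) / dist, rr, cc))
        if not slopes:
            continue
        if method == "d8":
            _, rr, cc = max(slopes)
            acc[rr, cc] += acc[r, c]
        else:
            weights = np.array([s[0] for s in slopes]) ** md_exponent
            weights = weights / weights.sum()
            for w, (_, rr, cc) in zip(weights, slopes):
                acc[rr, cc] += w * acc[r, c]
    return dtm.like(acc)


def twi(dtm: Grid, slope: Grid | None = None, method: str = "md8") -> Grid:
    """Topographic wetness index ln(a / tan beta).

    The specific catchment area a is the pit-filled multiple-flow-direction
    accumulation divided by the contour width (one cell size); tan beta is
    floored at tan(0.1 deg) so near-flat cells do not blow up.  High values
    mark wet, convergent positions.
    """
    if slope is None:
        slope, _ = slope_aspect(dtm)
    filled = fill_pits(dtm)
    acc = flow_accumulation(filled, method=method)
    a = acc.data / dtm.cell_size
    tan_beta = np.maximum(np.tan(np.radians(slope.data)), TAN_BETA_FLOOR)
    with np.errstate(invalid="ignore"):
        out = np.log(a / tan_beta)
    return dtm.like(out)


# ---------------------------------------------------------------------------
# climate covariates

def _solar_declination(day_of_year: int) -> float:
    return np.radians(23.45 * np.sin(2 * np.pi * (284 + day_of_year) / 365.0))


def solar_radiation(dtm: Grid, slope: Grid, aspect: Grid,
                    latitude_deg: float = 59.3, day_of_year: int = 91,
                    step_minutes: float = 15.0, transmittance: float = 0.7,
                    diffuse_fraction: float = 0.3,
                    solar_constant: float = 1367.0) -> Grid:
    """Clear-sky daily solar radiation on the tilted surface (Wh m-2 day-1).

    Direct beam uses a simple air-mass attenuated transmittance
    ``S0 * tau**(1/cos Z)`` projected on the surface via
    cos(theta) = cos s cos Z + sin s sin Z cos(A_sun - aspect), zeroed when
    the sun is below the cell's own horizon plane (self-shading only; no
    cast shadows).  Diffuse is isotropic: f * S0 * cos Z * (1 + cos s)/2.
    The sum is integrated over daylight in fixed steps (default 15 min)
    for 1 April (day 91).
    """
    if abs(latitude_deg) >= 66.5:
        raise ValueError("polar latitudes not supported")
    require_aligned(dtm, slope, aspect)
    phi = np.radians(latitude_deg)
    delta = _solar_declination(day_of_year)
    s = np.radians(slope.data)
    a = np.radians(np.where(np.isfinite(aspect.data), aspect.data, 0.0))
    cos_s, sin_s = np.cos(s), np.sin(s)
    total = np.zeros(dtm.shape)
    step_h = step_minutes / 60.0
    hours = np.arange(step_h / 2, 24, step_h)
    for t in hours:
        h = np.radians(15.0 * (t - 12.0))  # hour angle
        cos_z = np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.cos(h)
        if cos_z <= 0:
            continue
        sin_z = np.sqrt(1.0 - cos_z ** 2)
        # sun unit vector (east, north, up)
        sun_e = -np.cos(delta) * np.sin(h)
        sun_n = np.cos(phi) * np.sin(delta) - np.sin(phi) * np.cos(delta) * np.cos(h)
        az = np.arctan2(sun_e, sun_n)
        beam = solar_constant * transmittance ** (1.0 / cos_z)
        cos_theta = cos_s * cos_z + sin_s * sin_z * np.cos(az - a)
        direct = beam * np.maximum(cos_theta, 0.0)
        diffuse = diffuse_fraction * solar_constant * cos_z * (1 + cos_s) / 2.0
        total += (direct + diffuse) * step_h
    out = np.where(np.isfinite(slope.data), total, np.nan)
    return dtm.like(out)


def snow_load(dtm: Grid, aspect: Grid,
              prevailing_bearing: float = 135.0) -> Grid:
    """Snow-load index: scaled elevation times leeward exposure, in [0, 1].

    E = (z - z_min)/(z_max - z_min) over the extent; the exposure term
    W = (1 + cos(aspect - (prevailing + 180)))/2 peaks on the lee side of
    the prevailing wind (315 deg for 135-deg winds).  Flat cells, which
    carry no wind-exposure information, get W = 0.5.
    """
    require_aligned(dtm, aspect)
    z = dtm.data
    zmin, zmax = np.nanmin(z), np.nanmax(z)
    if zmax == zmin:
        raise ValueError("flat elevation range: snow load undefined")
    elev = (z - zmin) / (zmax - zmin)
    lee = prevailing_bearing + 180.0
    with np.errstate(invalid="ignore"):
        w = (1.0 + np.cos(np.radians(aspect.data - lee))) / 2.0
    w = np.where(np.isfinite(aspect.data), w, 0.5)
    out = np.where(np.isfinite(z), elev * w, np.nan)
    return dtm.like(out)


def vhi(dsm: Grid, dtm: Grid) -> Grid:
    """Vegetation height index: DSM - DTM in metres.

    Slightly negative values can occur with noisy input surfaces and are
    preserved as-is.
    """
    if dsm.shape != dtm.shape:
        raise ValueError("dsm/dtm shape mismatch")
    require_aligned(dsm, dtm)
    return dtm.like(dsm.data - dtm.data)


# ---------------------------------------------------------------------------
# stack assembly and standardization

def build_stack(dtm: Grid, dsm: Grid, latitude_deg: float = 59.3,
                prevailing_bearing: float = 135.0,
                tpi_radius_m: float = 140.0, vrm_window_m: float = 15.0,
                solar_day: int = 91) -> CovariateStack:
    """Compute all covariates from the two elevation surfaces."""
    slope_g, aspect_g = slope_aspect(dtm)
    grids = {
        "dtm": dtm,
        "slope": slope_g,
        "aspect": aspect_g,
        "tpi": tpi(dtm, tpi_radius_m),
        "vrm": vrm(slope_g, aspect_g, vrm_window_m),
        "twi": twi(dtm, slope=slope_g),
        "solrad": solar_radiation(dtm, slope_g, aspect_g,
                                  latitude_deg=latitude_deg,
                                  day_of_year=solar_day),
        "snow.load": snow_load(dtm, aspect_g, prevailing_bearing),
        "vhi": vhi(dsm, dtm),
    }
    return CovariateStack(grids)


def save_stack(stack: CovariateStack, outdir) -> None:
    """Write every grid as an ASCII raster plus a standardization JSON."""
    import json
    from pathlib import Path

    from .raster import write_ascii_grid

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, g in stack.grids.items():
        write_ascii_grid(g, outdir / f"{name.replace('.', '_')}.asc")
    meta = {
        "standardized": stack.standardized,
        "standardization": {k: list(v) for k, v in stack.standardization.items()},
    }
    (outdir / "standardization.json").write_text(json.dumps(meta, indent=2))


def load_stack(stackdir) -> CovariateStack:
    """Read a stack written by :func:`save_stack`."""
    import json
    from pathlib import Path

    from .raster import read_ascii_grid

    stackdir = Path(stackdir)
    grids = {}
    for name in COVARIATE_NAMES + ("aspect",):
        path = stackdir / f"{name.replace('.', '_')}.asc"
        if path.exists():
            grids[name] = read_ascii_grid(path)
    meta_path = stackdir / "standardization.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    params = {k: tuple(v) for k, v in meta.get("standardization", {}).items()}
    return CovariateStack(grids, standardization=params,
                          standardized=bool(meta.get("standardized", False)))


def standardize(stack: CovariateStack, reference: pd.DataFrame) -> CovariateStack:
    """Standardize the model covariates against a reference point sample.

    Each covariate is transformed to (x - mean)/sd where mean and sd are
    computed from the covariate values at the reference points (normally
    the available sample, which defines the availability distribution).
    Parameters are stored for the inverse transform.  Aspect, a circular
    quantity, is left untouched.
    """
    if len(reference) == 0:
        raise ValueError("reference sample is empty")
    out: dict[str, Grid] = {"aspect": stack.grids["aspect"]}
    params: dict[str, tuple[float, float]] = {}
    for name in COVARIATE_NAMES:
        g = stack.grids[name]
        if name in reference.columns:
            vals = reference[name].to_numpy(dtype=float)
        else:
            vals = g.sample(reference["x"].to_numpy(), reference["y"].to_numpy())
        vals = vals[np.isfinite(vals)]
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        if not sd > 0:
            raise ValueError(f"covariate {name!r} has zero sd in the reference sample")
        out[name] = g.like((g.data - mean) / sd)
        params[name] = (mean, sd)
    return CovariateStack(out, standardization=params, standardized=True)
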