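"""Synthetic alpine landscape and den-selection simulator.

Generates every input the den-selection pipeline needs — a rugged alpine
terrain model, a surface model carrying canopy below the forest line, a
glacier mask, an aerial survey route, heliports with flight-track fixes —
and places dens by exact weighted sampling from a known exponential
selection function, so that parameter recovery and every downstream stage
can be tested end to end without any field data.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, Point

from .raster import Grid

CANOPY_MAX_M = 25.0        # tallest subalpine conifer canopy, metres
CANOPY_TAPER_M = 40.0      # vertical scale of the krummholz transition


@dataclass
class LandscapeConfig:
    """Configuration of a synthetic study landscape.

    Defaults emulate the coastal-mainland alpine setting the pipeline is
    designed for: elevations spanning roughly 300–2,050 m, a forest line
    averaging 480 +/- 168 m, and snowfall-bearing winds from 135 degrees.
    """

    seed: int = 0
    extent: tuple[int, int] = (128, 128)   # (ny, nx) cells
    cell_size: float = 5.0                 # m
    relief: tuple[float, float] = (300.0, 2048.0)  # min/max elevation, m
    forest_line_mean: float = 480.0        # m
    forest_line_sd: float = 168.0          # m
    glacier_fraction: float = 0.05         # fraction of cells, highest first
    heliport_count: int = 3
    prevailing_wind_bearing: float = 135.0  # degrees from north
    spectral_exponent: float = 1.8         # roughness of the terrain spectrum

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        lo, hi = self.relief
        if not lo < hi:
            raise ValueError("relief min must be below relief max")
        if not lo <= self.forest_line_mean <= hi:
            raise ValueError("forest_line_mean must lie within the relief range")
        if not 0 <= self.glacier_fraction < 1:
            raise ValueError("glacier_fraction must be in [0, 1)")


@dataclass
class TrueSelection:
    """Known selection function w(x) = exp(sum beta_i x_i) used to place dens.

    Term names follow the covariate naming of the model module: a bare
    covariate name for a linear term, ``name_sq`` for its square; all terms
    act on standardized covariates.
    """

    term_names: list[str]
    beta: np.ndarray
    n_dens: int = 89

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.term_names) != self.beta.size:
            raise ValueError("one beta per term required")
        if self.n_dens < 1:
            raise ValueError("n_dens must be >= 1")


def generate_dtm(cfg: LandscapeConfig) -> Grid:
    """Synthesize a terrain model by Fourier spectral synthesis.

    White noise is shaped in the frequency domain by a radial power-law
    filter ``|F| ~ f**(-spectral_exponent)`` and the inverse transform is
    rescaled exactly to the configured relief range.  Larger exponents give
    smoother terrain.
    """
    ny, nx = cfg.extent
    if ny < 32 or nx < 32:
        raise ValueError("extent must be at least 32x32 cells for "
                         "moving-window terrain metrics to be meaningful")
    rng = np.random.default_rng(cfg.seed)
    noise = rng.standard_normal((ny, nx))
    spec = np.fft.rfft2(noise)
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.rfftfreq(nx)[None, :]
    f = np.hypot(fy, fx)
    with np.errstate(divide="ignore"):
        filt = np.where(f > 0, f ** (-cfg.spectral_exponent), 0.0)
    z = np.fft.irfft2(spec * filt, s=(ny, nx))
    lo, hi = cfg.relief
    z = lo + (z - z.min()) / (z.max() - z.min()) * (hi - lo)
    return Grid(z, cfg.cell_size)


def _forest_line_field(cfg: LandscapeConfig, shape: tuple[int, int],
                       rng: np.random.Generator) -> np.ndarray:
    """Spatially varying forest-line elevation, clipped to +/- 2 sd."""
    raw = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(raw, sigma=max(shape) / 16, mode="reflect")
    sd = smooth.std()
    unit = smooth / sd if sd > 0 else np.zeros(shape)
    return cfg.forest_line_mean + cfg.forest_line_sd * np.clip(unit, -2, 2)


def generate_dsm(dtm: Grid, cfg: LandscapeConfig) -> Grid:
    """Surface model = terrain + canopy.

    Canopy height follows a logistic profile of depth below a noisy
    forest-line elevation: ~15-30 m well below the line, tapering through
    krummholz to under a metre above it.  DSM >= DTM everywhere.
    """
    rng = np.random.default_rng((cfg.seed, 1))
    fl = _forest_line_field(cfg, dtm.shape, rng)
    depth = fl - dtm.data  # positive below the forest line
    profile = 1.0 / (1.0 + np.exp(-depth / CANOPY_TAPER_M))
    mult = rng.uniform(0.6, 1.2, size=dtm.shape)
    canopy = CANOPY_MAX_M * profile * mult
    return dtm.like(dtm.data + np.maximum(canopy, 0.0))


def generate_route_and_glaciers(dtm: Grid, cfg: LandscapeConfig
                                ) -> tuple[LineString, Grid]:
    """Survey route through the mid-elevation band and a glacier mask.

    The route follows, column band by column band, the smoothed row closest
    to the mid-relief elevation.  Glaciers occupy the configured fraction of
    the highest cells.
    """
    z = dtm.data
    zs = ndimage.gaussian_filter(z, sigma=3, mode="reflect")
    mid = 0.5 * (cfg.relief[0] + cfg.relief[1])
    n_knots = max(8, dtm.nx // 8)
    cols = np.linspace(0, dtm.nx - 1, n_knots).astype(int)
    rows = []
    prev = None
    for c in cols:
        cost = np.abs(zs[:, c] - mid)
        if prev is not None:
            cost = cost + 0.5 * np.abs(np.arange(dtm.ny) - prev) * dtm.cell_size
        r = int(np.argmin(cost))
        rows.append(r)
        prev = r
    rows = np.convolve(rows, np.ones(3) / 3, mode="same")
    rows[0], rows[-1] = rows[0] * 1.5 - rows[1] * 0.5, rows[-1] * 1.5 - rows[-2] * 0.5
    x, y = dtm.cell_center(np.clip(rows, 0, dtm.ny - 1), cols)
    route = LineString(np.column_stack([x, y]))

    if cfg.glacier_fraction <= 0:
        mask = np.zeros(dtm.shape)
    else:
        thresh = np.quantile(z, 1.0 - cfg.glacier_fraction)
        mask = (z >= thresh).astype(float)
    return route, dtm.like(mask)


def place_heliports(dtm: Grid, cfg: LandscapeConfig) -> list[Point]:
    """Heliports at low-elevation, well-separated cells (valley staging)."""
    rng = np.random.default_rng((cfg.seed, 2))
    z = dtm.data
    low = np.argwhere(z <= np.quantile(z, 0.25))
    ports: list[Point] = []
    min_sep = 0.25 * min(dtm.ny, dtm.nx) * dtm.cell_size
    candidates = low[rng.permutation(len(low))]
    for r, c in candidates:
        x, y = dtm.cell_center(r, c)
        if all(p.distance(Point(x, y)) >= min_sep for p in ports):
            ports.append(Point(float(x), float(y)))
        if len(ports) == cfg.heliport_count:
            break
    return ports


def generate_permit_areas(heliports: list[Point], radius_m: float):
    """Synthetic heli-ski permit polygons: discs around each heliport.

    Stand-in for the administratively drawn permit units of a real study
    area, which have no generative model; a disc of the operating radius
    captures their essential property (terrain reachable from a heliport).
    """
    return [p.buffer(radius_m, quad_segs=32) for p in heliports]


def simulate_dens(stack, truth: TrueSelection, mask: Grid,
                  seed: int) -> pd.DataFrame:
    """Place dens by exact weighted sampling from the true selection function.

    Cells are drawn without replacement from the unmasked cells with
    probability proportional to ``exp(sum beta x)`` (Gumbel top-k, which
    realises successive sampling without replacement exactly), then each den
    is jittered uniformly within its cell so the point -> cell lookup is
    invertible.

    Parameters
    ----------
    stack
        Standardized CovariateStack providing the term grids.
    truth
        Selection coefficients on the standardized scale and the den count.
    mask
        Grid with 1 = available terrain, 0/NaN = excluded.
    """
    if not stack.standardized:
        raise ValueError("simulate_dens requires a standardized covariate stack")
    ok = mask.data == 1
    eta = np.zeros(mask.shape)
    for name, b in zip(truth.term_names, truth.beta):
        x = stack.term_values(name)
        eta = eta + b * x
        ok &= np.isfinite(x)
    rows, cols = np.nonzero(ok)
    if truth.n_dens > rows.size:
        raise ValueError(f"n_dens={truth.n_dens} exceeds {rows.size} unmasked cells")
    rng = np.random.default_rng(seed)
    gumbel = rng.gumbel(size=rows.size)
    keys = eta[rows, cols] + gumbel
    pick = np.argsort(keys)[::-1][: truth.n_dens]
    r, c = rows[pick], cols[pick]
    u = rng.uniform(0, 1, size=truth.n_dens)
    v = rng.uniform(0, 1, size=truth.n_dens)
    x = mask.x0 + (c + u) * mask.cell_size
    y = mask.y0 - (r + v) * mask.cell_size
    return pd.DataFrame({"x": x, "y": y, "label": "used"})


def simulate_flight_tracks(heliports: list[Point], n_fixes: int,
                           spread: float, seed: int) -> pd.DataFrame:
    """Helicopter flight fixes clustered around heliports.

    Fixes are drawn from an equal-weight mixture of bivariate Gaussians
    centred on the heliports, each elongated along a random per-heliport
    run bearing (the along-route blur of repeated ski runs).
    """
    if len(heliports) < 1:
        raise ValueError("at least one heliport required")
    rng = np.random.default_rng(seed)
    centres = np.array([[p.x, p.y] for p in heliports])
    bearings = rng.uniform(0, 2 * np.pi, size=len(heliports))
    which = rng.integers(0, len(heliports), size=n_fixes)
    base = rng.standard_normal((n_fixes, 2)) * spread
    along = rng.standard_normal(n_fixes) * (2.0 * spread)
    u = np.column_stack([np.sin(bearings[which]), np.cos(bearings[which])])
    xy = centres[which] + base + along[:, None] * u
    return pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "label": "fix"})
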