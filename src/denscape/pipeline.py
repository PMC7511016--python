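"""End-to-end synthetic study assembly.

Chains the generators and design steps into one call: landscape ->
covariates -> study-area mask -> available sample -> standardization ->
den simulation -> design table.  Used by the command-line interface, the
test-suite and the reproduction script; each stage remains individually
callable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from . import study_design, synthetic_landscape as sl, terrain_covariates as tc
from .raster import Grid

#: Selection coefficients echoing the magnitudes reported for alpine
#: den selection (standardized scale), on the 8-term terrain+dry-snow model.
REFERENCE_TERMS = ["dtm", "dtm_sq", "slope", "slope_sq", "snow.load",
                   "twi", "vhi", "vrm"]
REFERENCE_BETA = np.array([-1.91, -1.78, 0.64, -0.17, 0.23, -0.37, 0.18, -0.48])


def reference_truth(n_dens: int = 89) -> sl.TrueSelection:
    """Reference den-selection truth used across tests and examples."""
    return sl.TrueSelection(list(REFERENCE_TERMS), REFERENCE_BETA.copy(),
                            n_dens=n_dens)


@dataclass
class StudyData:
    """All artifacts of one synthetic study realisation."""

    cfg: sl.LandscapeConfig
    truth: sl.TrueSelection
    dtm: Grid
    dsm: Grid
    glaciers: Grid
    route: LineString
    heliports: list[Point]
    stack: tc.CovariateStack          # standardized
    stack_raw: tc.CovariateStack      # pre-standardization
    mask: Grid
    available: pd.DataFrame
    dens: pd.DataFrame
    design: pd.DataFrame = field(repr=False)


def simulate_study(cfg: sl.LandscapeConfig,
                   truth: sl.TrueSelection | None = None,
                   available_density: float = 500.0,
                   buffer_m: float = 1500.0) -> StudyData:
    """Generate a complete synthetic study from one configuration.

    All randomness descends from ``cfg.seed`` through independent child
    seeds per stage.  Availability is standardized first (the available
    sample defines each covariate's mean/sd), then dens are simulated from
    the standardized stack so the recovery target is exactly ``truth``.
    """
    kids = np.random.SeedSequence(cfg.seed).generate_state(4) % (2 ** 31)
    if truth is None:
        truth = reference_truth()
    dtm = sl.generate_dtm(cfg)
    dsm = sl.generate_dsm(dtm, cfg)
    route, glaciers = sl.generate_route_and_glaciers(dtm, cfg)
    heliports = sl.place_heliports(dtm, cfg)
    stack_raw = tc.build_stack(dtm, dsm,
                               prevailing_bearing=cfg.prevailing_wind_bearing)
    mask = study_design.build_study_mask(dtm, stack_raw.grids["vhi"],
                                         glaciers, route, buffer_m=buffer_m)
    available = study_design.draw_available(mask, available_density,
                                            seed=int(kids[0]))
    stack = tc.standardize(stack_raw, available)
    dens = sl.simulate_dens(stack, truth, mask, seed=int(kids[1]))
    pts = pd.concat([dens, available], ignore_index=True)
    design = study_design.extract_covariates(pts, stack)
    return StudyData(cfg=cfg, truth=truth, dtm=dtm, dsm=dsm,
                     glaciers=glaciers, route=route, heliports=heliports,
                     stack=stack, stack_raw=stack_raw, mask=mask,
                     available=available, dens=dens, design=design)
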