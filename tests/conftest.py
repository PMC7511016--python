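"""Shared fixtures: one small synthetic study realisation per session."""

import numpy as np
import pytest

import denscape as dn


@pytest.fixture(scope="session")
def study():
    """A complete small synthetic study (128x128 cells, 150 dens)."""
    cfg = dn.LandscapeConfig(seed=42, extent=(128, 128))
    return dn.simulate_study(cfg, dn.reference_truth(n_dens=150))


@pytest.fixture(scope="session")
def spec14():
    return next(s for s in dn.candidate_set() if s.id == 14)


@pytest.fixture(scope="session")
def fit14(study, spec14):
    return dn.fit(study.design, spec14)


def plane_grid(slope_x=0.0, slope_y=0.0, shape=(12, 12), cell_size=5.0,
               z0=100.0):
    """Grid of the plane z = z0 + slope_x * x + slope_y * y (cell centres)."""
    ny, nx = shape
    g = dn.Grid(np.zeros(shape), cell_size)
    x, y = g.center_coords()
    return g.like(z0 + slope_x * x + slope_y * y)
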