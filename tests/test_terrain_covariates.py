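"""Covariate derivations against analytic planes and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

import denscape as dn
from denscape import terrain_covariates as tc
from conftest import plane_grid


class TestSlopeAspect:
    def test_plane_rising_east(self):
        g = plane_grid(slope_x=0.1)
        slope, aspect = tc.slope_aspect(g)
        inner = slope.data[1:-1, 1:-1]
        assert np.allclose(inner, np.degrees(np.arctan(0.1)))
        assert inner[0, 0] == pytest.approx(5.71, abs=0.005)
        # z rises eastward, so the downslope face points west
        assert np.allclose(aspect.data[1:-1, 1:-1], 270.0)

    def test_plane_rising_north(self):
        g = plane_grid(slope_y=0.2)
        _, aspect = tc.slope_aspect(g)
        assert np.allclose(aspect.data[1:-1, 1:-1], 180.0)

    def test_horizontal_plane(self):
        g = plane_grid()
        slope, aspect = tc.slope_aspect(g)
        assert np.allclose(slope.data[1:-1, 1:-1], 0.0)
        assert np.isnan(aspect.data[1:-1, 1:-1]).all()

    def test_edges_are_nodata(self):
        slope, _ = tc.slope_aspect(plane_grid(slope_x=0.3))
        assert np.isnan(slope.data[0, :]).all()
        assert np.isnan(slope.data[:, -1]).all()


class TestTpi:
    def test_inclined_plane_is_zero(self):
        g = plane_grid(slope_x=0.3, slope_y=-0.1, shape=(15, 15))
        out = tc.tpi(g, radius_m=15.0)  # 3-cell window
        interior = out.data[3:-3, 3:-3]
        assert np.abs(interior).max() < 1e-9 * np.ptp(g.data)

    def test_peak_sign_contract(self):
        g = plane_grid(shape=(11, 11))
        data = g.data.copy()
        data[5, 5] += 10.0
        out = tc.tpi(g.like(data), radius_m=15.0)
        assert out.data[5, 5] > 0
        assert out.data[5, 4] < 0 and out.data[4, 5] < 0

    def test_matches_brute_force_window_loop(self):
        rng = np.random.default_rng(11)
        g = dn.Grid(rng.uniform(0, 100, (21, 21)), cell_size=5.0)
        radius_m = 15.0  # 3 cells
        out = tc.tpi(g, radius_m)
        expect = np.empty_like(g.data)
        r_cells = radius_m / g.cell_size
        for i in range(21):
            for j in range(21):
                neigh = []
                for di in range(-3, 4):
                    for dj in range(-3, 4):
                        if di == dj == 0 or np.hypot(di, dj) > r_cells:
                            continue
                        if 0 <= i + di < 21 and 0 <= j + dj < 21:
                            neigh.append(g.data[i + di, j + dj])
                expect[i, j] = g.data[i, j] - np.mean(neigh)
        np.testing.assert_allclose(out.data, expect, atol=1e-9)

    def test_radius_below_cell_size_refused(self):
        with pytest.raises(ValueError):
            tc.tpi(plane_grid(), radius_m=1.0)


def _brute_vrm(slope_deg, aspect_deg, w):
    """Independent windowed vector-sum implementation."""
    s = np.radians(slope_deg)
    a = np.radians(aspect_deg)
    flat = ~np.isfinite(a)
    nx = np.where(flat, 0.0, np.sin(s) * np.sin(a))
    ny = np.where(flat, 0.0, np.sin(s) * np.cos(a))
    nz = np.where(flat & np.isfinite(s), 1.0, np.cos(s))
    ny_, nx_ = slope_deg.shape
    half = w // 2
    out = np.full(slope_deg.shape, np.nan)
    for i in range(ny_):
        for j in range(nx_):
            vx = vy = vz = cnt = 0.0
            for di in range(-half, half + 1):
                for dj in range(-half, half + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < ny_ and 0 <= jj < nx_ and np.isfinite(nz[ii, jj]):
                        vx += nx[ii, jj]
                        vy += ny[ii, jj]
                        vz += nz[ii, jj]
                        cnt += 1
            if np.isfinite(nz[i, j]) and cnt:
                out[i, j] = 1.0 - np.sqrt(vx**2 + vy**2 + vz**2) / cnt
    return out


class TestVrm:
    def test_uniform_plane_is_smooth(self):
        g = plane_grid(slope_x=0.2, slope_y=0.1)
        slope, aspect = tc.slope_aspect(g)
        out = tc.vrm(slope, aspect)
        assert np.nanmax(np.abs(out.data)) < 1e-12

    def test_bounded_unit_interval(self, study):
        v = study.stack.grids["vrm"]
        raw = study.stack.destandardize("vrm", v.data)
        raw = raw[np.isfinite(raw)]
        assert raw.min() >= 0.0 and raw.max() <= 1.0

    def test_matches_hand_vector_sum(self):
        rng = np.random.default_rng(3)
        slope = dn.Grid(rng.uniform(0, 80, (9, 9)), cell_size=5.0)
        aspect = slope.like(rng.uniform(0, 360, (9, 9)))
        out = tc.vrm(slope, aspect, window_m=15.0)
        expect = _brute_vrm(slope.data, aspect.data, 3)
        np.testing.assert_allclose(out.data, expect, atol=1e-12)

    def test_flat_cells_use_vertical_normal(self):
        slope = dn.Grid(np.zeros((5, 5)), cell_size=5.0)
        aspect = slope.like(np.full((5, 5), np.nan))
        out = tc.vrm(slope, aspect)
        assert np.allclose(out.data, 0.0)


def _recursive_accumulation(z, cs, exponent=1.1):
    """Memoized recursive MD8 accumulation (independent of the sorted loop)."""
    ny, nx = z.shape
    import functools

    def weights_from(i, j):
        ws = []
        for di, dj in tc._NEIGHBOURS:
            ii, jj = i + di, j + dj
            if 0 <= ii < ny and 0 <= jj < nx and z[ii, jj] < z[i, j]:
                drop = (z[i, j] - z[ii, jj]) / (cs * np.hypot(di, dj))
                ws.append((drop ** exponent, ii, jj))
        tot = sum(w for w, _, _ in ws)
        return [(w / tot, ii, jj) for w, ii, jj in ws] if tot else []

    @functools.lru_cache(maxsize=None)
    def acc(i, j):
        total = cs * cs
        for di, dj in tc._NEIGHBOURS:
            ii, jj = i + di, j + dj
            if 0 <= ii < ny and 0 <= jj < nx and z[ii, jj] > z[i, j]:
                for w, ti, tj in weights_from(ii, jj):
                    if (ti, tj) == (i, j):
                        total += w * acc(ii, jj)
        return total

    return np.array([[acc(i, j) for j in range(nx)] for i in range(ny)])


class TestTwi:
    def test_monotone_downslope_on_plane(self):
        g = plane_grid(slope_y=0.1, shape=(10, 10))  # drains south (down rows? no)
        out = tc.twi(g)
        # z rises with y (north), water flows to the south = increasing row
        col = out.data[1:-1, 5]
        assert (np.diff(col) > 0).all()

    def test_valley_wetter_than_ridge(self):
        ny, nx = 12, 11
        g = dn.Grid(np.zeros((ny, nx)), cell_size=5.0)
        x, y = g.center_coords()
        # V-valley along the centre column, draining south
        z = 0.5 * np.abs(x - x.mean()) + 0.2 * y
        g = g.like(z)
        out = tc.twi(g)
        crest = out.data[2, 1]        # upper side slope, no contributors
        valley = out.data[ny - 2, nx // 2]  # valley bottom, downstream
        assert crest < valley

    def test_matches_recursive_oracle(self):
        ny, nx = 10, 10
        g = dn.Grid(np.zeros((ny, nx)), cell_size=5.0)
        x, y = g.center_coords()
        z = 0.4 * np.abs(x - x.mean()) + 0.15 * y
        filled = tc.fill_pits(g.like(z))
        acc = tc.flow_accumulation(filled)
        expect = _recursive_accumulation(filled.data, 5.0)
        np.testing.assert_allclose(acc.data, expect, atol=1e-6)

    def test_pit_filling_removes_depressions(self):
        rng = np.random.default_rng(5)
        g = dn.Grid(rng.uniform(0, 50, (20, 20)), cell_size=5.0)
        filled = tc.fill_pits(g)
        # filling only raises, and no interior cell remains a strict pit
        assert (filled.data >= g.data - 1e-12).all()
        z = filled.data
        for i in range(1, 19):
            for j in range(1, 19):
                nb_min = min(z[i + di, j + dj] for di, dj in tc._NEIGHBOURS)
                assert z[i, j] >= nb_min


class TestSolarRadiation:
    def test_south_facing_exceeds_north_facing(self):
        slope = dn.Grid(np.full((3, 3), 30.0), cell_size=5.0)
        south = slope.like(np.full((3, 3), 180.0))
        north = slope.like(np.full((3, 3), 0.0))
        dtm = slope.like(np.zeros((3, 3)))
        s = tc.solar_radiation(dtm, slope, south).data[1, 1]
        n = tc.solar_radiation(dtm, slope, north).data[1, 1]
        assert s > n

    def test_flat_cell_matches_fine_step_integration(self):
        slope = dn.Grid(np.zeros((3, 3)), cell_size=5.0)
        aspect = slope.like(np.full((3, 3), np.nan))
        dtm = slope.like(np.zeros((3, 3)))
        coarse = tc.solar_radiation(dtm, slope, aspect,
                                    step_minutes=15.0).data[1, 1]
        # independent 1-minute numeric integration of the same irradiance
        phi = np.radians(59.3)
        delta = np.radians(23.45 * np.sin(2 * np.pi * (284 + 91) / 365.0))
        total = 0.0
        for t in np.arange(0.5 / 60, 24, 1.0 / 60):
            h = np.radians(15.0 * (t - 12.0))
            cz = np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.cos(h)
            if cz <= 0:
                continue
            direct = 1367.0 * 0.7 ** (1.0 / cz) * cz
            diffuse = 0.3 * 1367.0 * cz
            total += (direct + diffuse) / 60.0
        assert coarse == pytest.approx(total, rel=0.01)

    def test_diffuse_linearity_with_zero_direct(self):
        slope = dn.Grid(np.full((3, 3), 20.0), cell_size=5.0)
        aspect = slope.like(np.full((3, 3), 90.0))
        dtm = slope.like(np.zeros((3, 3)))
        one = tc.solar_radiation(dtm, slope, aspect, transmittance=0.0,
                                 diffuse_fraction=0.3).data[1, 1]
        two = tc.solar_radiation(dtm, slope, aspect, transmittance=0.0,
                                 diffuse_fraction=0.6).data[1, 1]
        assert two == pytest.approx(2.0 * one, rel=1e-12)

    def test_polar_latitude_refused(self):
        g = dn.Grid(np.zeros((3, 3)), cell_size=5.0)
        with pytest.raises(ValueError):
            tc.solar_radiation(g, g, g, latitude_deg=70.0)


class TestSnowLoad:
    def _grids(self, z, aspect_deg):
        dtm = dn.Grid(np.array(z, dtype=float), cell_size=5.0)
        return dtm, dtm.like(np.array(aspect_deg, dtype=float))

    def test_boundary_values(self):
        dtm, aspect = self._grids([[0.0, 500.0, 1000.0]],
                                  [[315.0, 225.0, 315.0]])
        out = tc.snow_load(dtm, aspect).data
        assert out[0, 2] == pytest.approx(1.0)       # leeward at max elevation
        assert out[0, 1] == pytest.approx(0.25)      # half exposure, mid elev
        dtm2, aspect2 = self._grids([[0.0, 1000.0]], [[135.0, 135.0]])
        out2 = tc.snow_load(dtm2, aspect2).data
        assert np.allclose(out2, 0.0, atol=1e-12)    # windward kills the index

    def test_flat_cells_get_half_exposure(self):
        dtm, aspect = self._grids([[0.0, 1000.0]], [[np.nan, np.nan]])
        out = tc.snow_load(dtm, aspect).data
        assert out[0, 1] == pytest.approx(0.5)

    def test_bounded_unit_interval(self, study):
        raw = study.stack.destandardize("snow.load",
                                        study.stack.grids["snow.load"].data)
        raw = raw[np.isfinite(raw)]
        assert raw.min() >= 0.0 and raw.max() <= 1.0

    def test_flat_relief_refused(self):
        dtm, aspect = self._grids([[5.0, 5.0]], [[0.0, 90.0]])
        with pytest.raises(ValueError):
            tc.snow_load(dtm, aspect)


class TestVhi:
    def test_difference_and_shape_check(self):
        dtm = dn.Grid(np.full((4, 4), 100.0), cell_size=5.0)
        assert np.allclose(tc.vhi(dtm, dtm).data, 0.0)
        dsm = dtm.like(dtm.data + 7.0)
        out = tc.vhi(dsm, dtm)
        assert np.allclose(out.data, 7.0)
        assert (out.data > tc.FOREST_VHI_M).all()
        with pytest.raises(ValueError):
            tc.vhi(dn.Grid(np.zeros((3, 3)), cell_size=5.0), dtm)


class TestStandardize:
    def _stack_123(self):
        grids = {}
        for name in tc.COVARIATE_NAMES:
            grids[name] = dn.Grid(np.array([[1.0, 2.0, 3.0]]), cell_size=1.0)
        grids["aspect"] = dn.Grid(np.zeros((1, 3)), cell_size=1.0)
        ref = pd.DataFrame({"x": [0.5, 1.5, 2.5], "y": [0.5, 0.5, 0.5]})
        return tc.CovariateStack(grids), ref

    def test_three_point_reference(self):
        stack, ref = self._stack_123()
        std = tc.standardize(stack, ref)
        np.testing.assert_allclose(std.grids["dtm"].data, [[-1.0, 0.0, 1.0]])

    def test_reference_sample_becomes_zero_mean_unit_sd(self, study):
        av = study.available
        for name in tc.COVARIATE_NAMES:
            vals = study.stack.grids[name].sample(av["x"].to_numpy(),
                                                  av["y"].to_numpy())
            vals = vals[np.isfinite(vals)]
            assert abs(vals.mean()) < 1e-10
            assert vals.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_inverse_roundtrip(self, study):
        g = study.stack.grids["slope"]
        raw = study.stack.destandardize("slope", g.data)
        mean, sd = study.stack.standardization["slope"]
        np.testing.assert_allclose((raw - mean) / sd, g.data, atol=1e-10)

    def test_zero_sd_names_covariate(self):
        stack, ref = self._stack_123()
        stack.grids["twi"] = dn.Grid(np.full((1, 3), 2.0), cell_size=1.0)
        with pytest.raises(ValueError, match="twi"):
            tc.standardize(stack, ref)


class TestInvariances:
    def test_translation_invariance_in_z(self):
        rng = np.random.default_rng(7)
        g = dn.Grid(rng.uniform(0, 100, (25, 25)), cell_size=5.0)
        shifted = g.like(g.data + 123.0)
        s1, a1 = tc.slope_aspect(g)
        s2, a2 = tc.slope_aspect(shifted)
        np.testing.assert_allclose(s1.data, s2.data, atol=1e-9)
        np.testing.assert_allclose(tc.tpi(g).data, tc.tpi(shifted).data,
                                   atol=1e-9)
        np.testing.assert_allclose(tc.vrm(s1, a1).data, tc.vrm(s2, a2).data,
                                   atol=1e-12, equal_nan=True)

    def test_rotation_consistency(self):
        rng = np.random.default_rng(8)
        g = dn.Grid(rng.uniform(0, 100, (20, 20)), cell_size=5.0)
        rot = dn.Grid(np.rot90(g.data), cell_size=5.0)
        s, a = tc.slope_aspect(g)
        sr, ar = tc.slope_aspect(rot)
        np.testing.assert_allclose(sr.data, np.rot90(s.data),
                                   atol=1e-9, equal_nan=True)
        # rotating the DEM 90 deg CCW shifts every bearing by -90 deg
        expect = (np.rot90(a.data) - 90.0) % 360.0
        np.testing.assert_allclose(ar.data, expect, atol=1e-9, equal_nan=True)
        np.testing.assert_allclose(tc.tpi(rot).data, np.rot90(tc.tpi(g).data),
                                   atol=1e-9)

    def test_windowed_metrics_match_brute_force_random_grids(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            g = dn.Grid(rng.uniform(0, 200, (25, 25)), cell_size=5.0)
            np.testing.assert_allclose(
                tc.tpi(g, 15.0).data,
                _brute_tpi(g.data, 3.0), atol=1e-9)
            s, a = tc.slope_aspect(g)
            np.testing.assert_allclose(
                tc.vrm(s, a, 15.0).data,
                _brute_vrm(s.data, a.data, 3), atol=1e-12)

    def test_solar_nonnegative_on_landscape(self, study):
        raw = study.stack.destandardize("solrad",
                                        study.stack.grids["solrad"].data)
        assert np.nanmin(raw) >= 0.0


def _brute_tpi(z, r_cells):
    ny, nx = z.shape
    out = np.empty_like(z)
    r = int(np.floor(r_cells))
    for i in range(ny):
        for j in range(nx):
            neigh = []
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if di == dj == 0 or np.hypot(di, dj) > r_cells:
                        continue
                    if 0 <= i + di < ny and 0 <= j + dj < nx:
                        neigh.append(z[i + di, j + dj])
            out[i, j] = z[i, j] - np.mean(neigh)
    return out
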