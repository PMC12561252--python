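import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tearmap as tm
from tearmap.mapping import CENTRAL_QC_RADIUS, PIVOT_RING_COUNTS


def _map_on(grid, values, **kw):
    return tm.TearFilmMap(grid=grid, values=values, **kw)


class TestQC:
    def test_clean_map_passes(self, small_grid):
        res = tm.qc_check(_map_on(small_grid, np.full(small_grid.shape, 0.1)))
        assert res.passed and res.central_coverage == 1.0 and not res.reasons

    def test_missing_central_disc_fails(self, small_grid):
        vals = np.full(small_grid.shape, 0.1)
        vals[small_grid.ring_radii <= CENTRAL_QC_RADIUS, :] = np.nan
        res = tm.qc_check(_map_on(small_grid, vals))
        assert not res.passed
        assert res.reasons == {"incomplete_central_coverage"}

    def test_partial_coverage_hand_count(self):
        """7 of 10 central cells present -> coverage 0.7, fails at 0.9."""
        grid = tm.PolarGrid(ring_radii=np.array([1.0, 3.0]),
                            meridian_angles=np.arange(0, 360, 36.0))
        vals = np.full(grid.shape, 0.1)
        vals[0, :3] = np.nan  # 3 of the 10 central-ring cells missing
        res = tm.qc_check(_map_on(grid, vals), min_coverage=0.9)
        assert res.central_coverage == pytest.approx(0.7)
        assert not res.passed

    def test_artefact_flags_copied(self, small_grid):
        res = tm.qc_check(_map_on(small_grid, np.full(small_grid.shape, 0.1),
                                  artefact_flags={"blink_artefact"}))
        assert res.reasons == {"blink_artefact"}

    @given(st.integers(0, 23))
    @settings(max_examples=20, deadline=None)
    def test_qc_monotone_in_missingness(self, n_missing_rings):
        """Adding missing central cells never turns a failing map into a passing one."""
        grid = tm.make_standard_grid(5.0, 24, 36)
        vals = np.full(grid.shape, 0.1)
        vals[:max(n_missing_rings, 0), ::2] = np.nan
        before = tm.qc_check(_map_on(grid, vals), min_coverage=0.95)
        vals2 = vals.copy()
        vals2[0, :] = np.nan
        after = tm.qc_check(_map_on(grid, vals2), min_coverage=0.95)
        assert after.central_coverage <= before.central_coverage
        if not before.passed:
            assert not after.passed


class TestLowpass:
    def test_zero_sigma_is_identity(self, small_grid):
        rng = np.random.default_rng(0)
        m = _map_on(small_grid, rng.uniform(0, 1, small_grid.shape))
        out = tm.lowpass_filter(m, 0.0, 0.0)
        assert np.array_equal(out.values, m.values)

    def test_constant_preserved(self, small_grid):
        m = _map_on(small_grid, np.full(small_grid.shape, 0.3))
        out = tm.lowpass_filter(m, 0.5, 15.0)
        assert np.allclose(out.values, 0.3)

    def test_spike_spread_and_mass_conserved(self):
        grid = tm.make_standard_grid(5.0, 25, 60)
        vals = np.zeros(grid.shape)
        vals[12, 30] = 1.0
        m = _map_on(grid, vals)
        out = tm.lowpass_filter(m, 0.0, 30.0)
        # angular-only smoothing with wrap conserves row mass exactly
        assert out.values[12].sum() == pytest.approx(1.0, abs=1e-9)
        assert out.values.max() < 1.0

    def test_missing_cells_stay_missing(self, small_grid):
        vals = np.full(small_grid.shape, 0.2)
        vals[5, 5] = np.nan
        out = tm.lowpass_filter(_map_on(small_grid, vals), 0.3, 10.0)
        assert np.isnan(out.values[5, 5])
        assert np.isfinite(out.values).sum() == np.isfinite(vals).sum()
        # masked normalisation keeps neighbours at the constant value
        assert np.allclose(out.values[np.isfinite(out.values)], 0.2)


class TestResample:
    def test_identity_on_same_grid(self, quadratic_map):
        m, _ = quadratic_map
        out = tm.resample_to_grid(m, m.grid)
        assert np.array_equal(out.values, m.values)

    def test_quadratic_field_exact(self, quadratic_map):
        m, (a, b) = quadratic_map
        coarse = tm.make_standard_grid(5.0, 25, 90)
        src = tm.resample_to_grid(m, coarse)
        fine = tm.make_standard_grid(5.0, 50, 180)
        out = tm.resample_to_grid(src, fine)
        r, _ = fine.mesh()
        err = np.abs(out.values - (a + b * (r / 5.0) ** 2))
        assert np.nanmax(err) < 1e-3 * b

    def test_constant_field(self, small_grid):
        m = _map_on(small_grid, np.full(small_grid.shape, 0.25))
        out = tm.resample_to_grid(m, tm.make_standard_grid(4.0, 20, 40))
        assert np.allclose(out.values, 0.25)

    def test_extrapolation_rejected(self, small_grid):
        m = _map_on(small_grid, np.full(small_grid.shape, 0.25))
        with pytest.raises(ValueError, match="extrapolation"):
            tm.resample_to_grid(m, tm.make_standard_grid(6.0, 10, 36))


class TestPivotLayout:
    @pytest.mark.parametrize("eye", ["OD", "OS"])
    def test_121_points(self, eye):
        layout = tm.build_pivot_layout(eye, 5.0)
        assert layout.n_points == 121
        assert sum((1,) + PIVOT_RING_COUNTS) == 121

    def test_ring_structure(self):
        layout = tm.build_pivot_layout("OD", 5.0)
        radii = np.unique(layout.radii)
        assert np.allclose(radii, [0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        for k, count in enumerate(PIVOT_RING_COUNTS, start=1):
            on_ring = np.isclose(layout.radii, 1.0 * k)
            assert on_ring.sum() == count
            angles = np.sort(layout.angles[on_ring])
            assert np.allclose(np.diff(angles), 360.0 / count)

    def test_os_is_mirror_of_od(self):
        od = tm.build_pivot_layout("OD", 5.0)
        os_ = tm.build_pivot_layout("OS", 5.0)
        assert np.allclose(od.radii, os_.radii)
        assert np.allclose((180.0 - od.angles) % 360.0, os_.angles)


class TestPivotExtraction:
    def test_constant_map(self, small_grid):
        m = _map_on(small_grid, np.full(small_grid.shape, 0.17))
        pv = tm.extract_pivots(m, tm.build_pivot_layout("OD", 5.0))
        assert np.allclose(pv.values, 0.17)

    def test_quadratic_field(self, quadratic_map):
        m, (a, b) = quadratic_map
        layout = tm.build_pivot_layout("OD", 5.0)
        pv = tm.extract_pivots(m, layout)
        expected = a + b * (layout.radii / 5.0) ** 2
        assert np.nanmax(np.abs(pv.values - expected)) < 1e-3 * b

    def test_missing_sector_propagates(self, quadratic_map):
        m, _ = quadratic_map
        vals = m.values.copy()
        angles = m.grid.meridian_angles
        sector = (angles >= 150.0) & (angles <= 210.0)
        vals[:, sector] = np.nan
        m2 = _map_on(m.grid, vals)
        layout = tm.build_pivot_layout("OD", 5.0)
        pv = tm.extract_pivots(m2, layout)
        # pivots well inside the sector (margin > one angular stencil) are missing
        inside = (layout.angles > 160.0) & (layout.angles < 200.0) & (layout.radii > 0)
        outside = (layout.angles < 140.0) | (layout.angles > 220.0)
        assert np.all(~np.isfinite(pv.values[inside]))
        assert np.all(np.isfinite(pv.values[outside]))

    def test_commutes_with_resampling(self, small_cohort):
        """Extract-then-resample vs resample-then-extract agree on smooth fields."""
        cohort, truths = small_cohort
        m = tm.TearFilmMap(grid=cohort.records[0].pre_map.grid,
                           values=np.maximum(truths[0].post, 0))
        layout = tm.build_pivot_layout("OD", 5.0)
        direct = tm.extract_pivots(m, layout)
        fine = tm.make_standard_grid(5.0, 50, 180)
        via = tm.extract_pivots(tm.resample_to_grid(m, fine), layout)
        rng = np.ptp(m.values[np.isfinite(m.values)])
        assert np.nanmax(np.abs(direct.values - via.values)) < 1e-2 * rng


class TestRingExtraction:
    def test_constant_and_count(self, small_grid):
        m = _map_on(small_grid, np.full(small_grid.shape, 0.4))
        vals = tm.extract_ring_values(m, 3.0, 30.0)
        assert len(vals) == 12 and np.allclose(vals, 0.4)

    def test_cosine_field(self):
        grid = tm.make_standard_grid(5.0, 50, 180)
        _, th = grid.mesh()
        m = _map_on(grid, 2.0 + np.cos(np.deg2rad(th)))
        vals = tm.extract_ring_values(m, 2.0, 90.0) - 2.0
        assert np.allclose(vals, [1.0, 0.0, -1.0, 0.0], atol=1e-2)

    def test_bad_step_rejected(self, small_grid):
        m = _map_on(small_grid, np.full(small_grid.shape, 0.4))
        with pytest.raises(ValueError):
            tm.extract_ring_values(m, 2.0, 100.0)


class TestGlobalMean:
    def test_constant(self, small_grid):
        m = _map_on(small_grid, np.full(small_grid.shape, 0.21))
        assert tm.global_mean(m, 3.0) == pytest.approx(0.21)

    def test_quadratic_closed_form(self, quadratic_map):
        """Area-weighted mean of a + b (r/R)^2 over the full disc is a + b/2."""
        m, (a, b) = quadratic_map
        assert tm.global_mean(m, 5.0) == pytest.approx(a + b / 2, rel=2e-2)

    def test_all_missing_zone_rejected(self, small_grid):
        vals = np.full(small_grid.shape, 0.1)
        vals[small_grid.ring_radii <= 2.0, :] = np.nan
        with pytest.raises(ValueError):
            tm.global_mean(_map_on(small_grid, vals), 1.5)

    def test_linearity_with_group_mean(self, small_cohort):
        """global_mean of the mean map equals the mean of per-eye global means."""
        cohort, _ = small_cohort
        mean_map = tm.group_mean_map(cohort, "G2", "post")
        per_eye = [tm.global_mean(r.post_map, 4.0)
                   for r in cohort if r.group == "G2"]
        assert tm.global_mean(mean_map, 4.0) == pytest.approx(np.mean(per_eye),
                                                              abs=1e-12)


class TestGroupMeanAndDifference:
    def test_identical_maps_average_to_themselves(self, small_cohort):
        cohort, _ = small_cohort
        recs = [r for r in cohort if r.group == "G1"]
        mean_map = tm.group_mean_map(tm.Cohort(records=recs[:1]), "G1", "pre")
        assert np.allclose(mean_map.values, recs[0].pre_map.values)

    def test_cellwise_mean_matches_bruteforce(self, small_cohort):
        cohort, _ = small_cohort
        mean_map = tm.group_mean_map(cohort, "G3", "post")
        stack = np.stack([r.post_map.values for r in cohort if r.group == "G3"])
        assert np.allclose(mean_map.values, stack.mean(axis=0))

    def test_difference_identities(self, small_cohort):
        cohort, truths = small_cohort
        rec = cohort.records[0]
        zero = tm.difference_map(rec.post_map, rec.post_map)
        assert np.allclose(zero.values, 0.0)
        grid = rec.pre_map.grid
        pre = tm.TearFilmMap(grid=grid, values=np.maximum(truths[0].pre, 0))
        post = tm.TearFilmMap(grid=grid, values=np.maximum(truths[0].post, 0),
                              session="post")
        diff = tm.difference_map(post, pre)
        assert np.allclose(diff.values, truths[0].effect, atol=1e-12)

    def test_difference_missing_propagation(self, small_grid):
        a = np.full(small_grid.shape, 0.2)
        b = a.copy()
        b[3, 3] = np.nan
        pre = _map_on(small_grid, b)
        post = _map_on(small_grid, a, session="post")
        diff = tm.difference_map(post, pre)
        assert np.isnan(diff.values[3, 3])

    def test_grid_mismatch_rejected(self, small_grid):
        a = _map_on(small_grid, np.full(small_grid.shape, 0.2))
        other = tm.make_standard_grid(5.0, 10, 36)
        b = _map_on(other, np.full(other.shape, 0.2), session="post")
        with pytest.raises(ValueError):
            tm.difference_map(b, a)


class TestCentration:
    def test_all_positive_difference_undefined(self, small_grid):
        diff = tm.TearFilmMap(grid=small_grid,
                              values=np.full(small_grid.shape, 0.5),
                              modality="tangential_curvature")
        assert tm.estimate_centration(diff, threshold=-0.5) is None

    def test_wrong_modality_rejected(self, small_grid):
        m = _map_on(small_grid, np.full(small_grid.shape, 0.1))
        with pytest.raises(ValueError):
            tm.estimate_centration(m)
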