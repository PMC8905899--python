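"""DVH curve, index and constraint-check contracts with brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from biorange import dvh
from biorange.grid import VoxelGrid


def brute_force_dx(doses: np.ndarray, x: float) -> float:
    """Exhaustive nearest-rank search: largest observed dose d such that at
    least x% of the voxels receive >= d."""
    best = 0.0
    n = doses.size
    for d in np.sort(doses):
        if (doses >= d).sum() / n >= x / 100.0:
            best = d
    return best


def grid_of(values) -> VoxelGrid:
    arr = np.asarray(values, dtype=float)
    return VoxelGrid(arr.reshape(arr.size, 1, 1))


def struct_for(grid: VoxelGrid, name="s", **kw) -> dvh.Structure:
    return dvh.Structure(name, np.ones(grid.shape, dtype=bool), **kw)


class TestDVHCurve:
    def test_uniform_dose_step_curve(self):
        g = grid_of(np.full(50, 10.0))
        curve = dvh.dvh(g, struct_for(g))
        assert curve.volume_at(0.0) == 1.0
        assert curve.volume_at(9.9) == 1.0
        assert curve.volume_at(10.5) == 0.0

    def test_two_voxel_structure_half_volume(self):
        g = grid_of([1.0, 3.0])
        curve = dvh.dvh(g, struct_for(g))
        assert curve.volume_at(2.0) == pytest.approx(0.5)

    def test_monotone_nonincreasing_and_starts_at_one(self, rng):
        g = grid_of(rng.uniform(0, 60, 500))
        curve = dvh.dvh(g, struct_for(g))
        assert curve.cum_volume_fraction[0] == 1.0
        assert np.all(np.diff(curve.cum_volume_fraction) <= 0)

    def test_mean_dose_recovered_from_curve_integral(self, rng):
        bin_width = 0.1
        g = grid_of(rng.uniform(0, 30, 1000))
        curve = dvh.dvh(g, struct_for(g), bin_width)
        # Riemann sum of the cumulative curve equals the mean dose
        integral = curve.cum_volume_fraction.sum() * bin_width
        assert integral == pytest.approx(g.data.mean(), abs=bin_width / 2)

    def test_empty_structure_rejected(self):
        g = grid_of(np.ones(4))
        s = dvh.Structure("empty", np.zeros(g.shape, dtype=bool))
        with pytest.raises(ValueError):
            dvh.dvh(g, s)


class TestDosePercentile:
    def test_ranked_doses_d95(self):
        g = grid_of(np.arange(1.0, 101.0))
        d95 = dvh.dose_percentile(g, struct_for(g), 95.0)
        assert 5.0 <= d95 <= 6.0

    def test_ranked_doses_d05(self):
        g = grid_of(np.arange(1.0, 101.0))
        d05 = dvh.dose_percentile(g, struct_for(g), 5.0)
        assert 95.0 <= d05 <= 96.0

    def test_uniform_dose_any_coverage(self):
        g = grid_of(np.full(30, 42.0))
        for x in (5.0, 50.0, 95.0):
            assert dvh.dose_percentile(g, struct_for(g), x) == pytest.approx(42.0)

    @pytest.mark.parametrize("x", [5.0, 35.0, 95.0])
    def test_agrees_with_exhaustive_search_within_one_gap(self, rng, x):
        doses = rng.uniform(0, 70, 400)
        g = grid_of(doses)
        val = dvh.dose_percentile(g, struct_for(g), x)
        oracle = brute_force_dx(doses, x)
        gap = np.diff(np.sort(doses)).max()
        assert abs(val - oracle) <= gap

    def test_d95_never_exceeds_d05(self, rng):
        for _ in range(200):
            g = grid_of(rng.uniform(0, 80, 64))
            s = struct_for(g)
            assert dvh.dose_percentile(g, s, 95.0) <= dvh.dose_percentile(g, s, 5.0)

    def test_invalid_coverage_rejected(self):
        g = grid_of(np.ones(5))
        with pytest.raises(ValueError):
            dvh.dose_percentile(g, struct_for(g), 0.0)

    @given(
        doses=arrays(np.float64, st.integers(5, 60),
                     elements=st.floats(0.0, 80.0)),
        x=st.floats(1.0, 99.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_dx_is_a_coverage_quantile_for_any_dose_array(self, doses, x):
        g = grid_of(doses)
        val = dvh.dose_percentile(g, struct_for(g), x)
        # at least x% of voxels receive >= any dose strictly below Dx
        assert (doses >= val).sum() / doses.size >= x / 100.0 - 1.0 / doses.size
        assert doses.min() <= val <= doses.max()


class TestIndices:
    def test_uniform_dose_ratio_100_percent(self):
        g = grid_of(np.full(20, 54.0))
        idx = dvh.indices(g, struct_for(g), prescribed_dose=54.0)
        assert idx.dmean_over_dp_pct == pytest.approx(100.0)
        assert idx.dmax == idx.dmean == pytest.approx(54.0)

    def test_linearity_under_dose_scaling(self, rng):
        vals = rng.uniform(10, 60, 300)
        a = dvh.indices(grid_of(vals), struct_for(grid_of(vals)))
        b = dvh.indices(grid_of(1.1 * vals), struct_for(grid_of(vals)))
        for field in ("dmax", "dmean", "d95", "d05"):
            assert getattr(b, field) == pytest.approx(1.1 * getattr(a, field), rel=1e-12)

    def test_ordering_invariants(self, rng):
        g = grid_of(rng.uniform(0, 80, 500))
        idx = dvh.indices(g, struct_for(g))
        assert idx.d95 <= idx.dmean <= idx.dmax
        assert idx.d95 <= idx.d05 <= idx.dmax


class TestV95Volume:
    def test_no_voxels_above_threshold(self):
        g = grid_of(np.full(10, 1.0))
        assert dvh.v95_volume(g, None, 60.0) == 0.0

    def test_volume_in_cubic_centimetres(self):
        data = np.zeros((10, 10, 10))
        data.flat[:1000] = 60.0
        g = VoxelGrid(data, spacing=1.5)
        assert dvh.v95_volume(g, None, 60.0) == pytest.approx(1000 * 1.5**3 / 1000.0)

    def test_nonincreasing_in_prescription(self, rng):
        g = VoxelGrid(rng.uniform(0, 70, (8, 8, 8)))
        vols = [dvh.v95_volume(g, None, dp) for dp in (40.0, 50.0, 60.0, 70.0)]
        assert vols == sorted(vols, reverse=True)

    def test_body_mask_restricts_volume(self, rng):
        g = VoxelGrid(np.full((4, 4, 4), 60.0))
        body = dvh.Structure("body", np.zeros((4, 4, 4), dtype=bool), kind="body")
        body.mask[:2] = True
        assert dvh.v95_volume(g, body, 60.0) == pytest.approx(32 * g.voxel_volume_cm3)

    def test_consistent_with_dvh_curve_lookup(self, rng):
        vals = rng.uniform(0, 70, 1000)
        g = grid_of(vals)
        s = struct_for(g)
        dp = 60.0
        curve = dvh.dvh(g, s, 0.1)
        via_curve = curve.volume_at(0.95 * dp) * s.n_voxels * g.voxel_volume_cm3
        direct = dvh.v95_volume(g, s, dp)
        assert abs(via_curve - direct) <= s.n_voxels * g.voxel_volume_cm3 * 0.01


class TestConstraintCheck:
    def test_below_limit_no_exceedance(self):
        res = dvh.constraint_check({"chiasm": 50.0})
        assert res[0].exceedance == 0.0 and not res[0].exceeded

    def test_fourteen_gy_above_limit(self):
        res = dvh.constraint_check({"brainstem_core": 68.0})
        assert res[0].exceedance == pytest.approx(14.0) and res[0].exceeded

    def test_whole_brainstem_checked_against_both_limits(self):
        res = dvh.constraint_check({"brainstem_core": 60.0, "brainstem_surface": 60.0})
        by_name = {r.structure: r for r in res}
        assert by_name["brainstem_core"].exceedance == pytest.approx(6.0)
        assert by_name["brainstem_surface"].exceedance == 0.0

    def test_unknown_structure_skipped(self):
        assert dvh.constraint_check({"spinal_cord": 70.0}) == []
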