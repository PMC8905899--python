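"""LET scoring and RBE model contracts, with independent oracles."""

import numpy as np
import pytest

from biorange import letrbe
from biorange.grid import VoxelGrid
from biorange.letrbe import DepositEvent, RBEModelParams


def lq_isoeffect_rbe(d, let, alpha_beta):
    """Independent RBE oracle via the linear-quadratic isoeffect equation.

    Protons with fraction dose d produce effect E = a_p d + b_p d**2 where
    a_p = a_x RBE_max and b_p = b_x RBE_min**2; the RBE is the photon dose
    producing the same effect, divided by d.  Solved as a quadratic root
    rather than through the closed-form RBE expression.
    """
    p = RBEModelParams(alpha_beta=alpha_beta)
    rbe_max = p.p0 + p.p1 * let / alpha_beta
    rbe_min = p.p2 - p.p3 * np.sqrt(alpha_beta) * let
    b_x = 1.0
    a_x = alpha_beta * b_x
    effect = a_x * rbe_max * d + b_x * rbe_min**2 * d**2
    d_x = (-a_x + np.sqrt(a_x**2 + 4 * b_x * effect)) / (2 * b_x)
    return d_x / d


class TestEventScoring:
    def test_single_event_identity(self):
        ev = [DepositEvent((1, 1, 1), dE=1.0, stopping_power=7.5)]
        grid = letrbe.letd_from_events(ev, (3, 3, 3))
        assert grid.data[1, 1, 1] == pytest.approx(7.5)

    def test_dose_weighted_mean_of_two_events(self):
        ev = [
            DepositEvent((0, 0, 0), dE=1.0, stopping_power=2.0),
            DepositEvent((0, 0, 0), dE=1.0, stopping_power=4.0),
        ]
        grid = letrbe.letd_from_events(ev, (2, 2, 2))
        assert grid.data[0, 0, 0] == pytest.approx(3.0)

    def test_scaling_all_deposits_leaves_letd_unchanged(self, rng):
        events = [
            DepositEvent(
                tuple(rng.integers(0, 4, 3)),
                dE=float(rng.uniform(0.1, 2.0)),
                stopping_power=float(rng.uniform(0.5, 12.0)),
            )
            for _ in range(200)
        ]
        scaled = [
            DepositEvent(e.voxel_index, 3.7 * e.dE, e.stopping_power) for e in events
        ]
        a = letrbe.letd_from_events(events, (4, 4, 4))
        b = letrbe.letd_from_events(scaled, (4, 4, 4))
        np.testing.assert_allclose(a.data, b.data, rtol=1e-12)

    def test_empty_voxels_score_zero(self):
        grid = letrbe.letd_from_events([DepositEvent((0, 0, 0), 1.0, 2.0)], (2, 2, 2))
        assert grid.data[1, 1, 1] == 0.0

    def test_out_of_grid_event_rejected(self):
        with pytest.raises(IndexError):
            letrbe.letd_from_events([DepositEvent((5, 0, 0), 1.0, 2.0)], (3, 3, 3))


class TestCombineLETd:
    def test_single_field_passthrough(self, rng):
        dose = VoxelGrid(rng.uniform(0, 2, (4, 4, 4)))
        let = VoxelGrid(rng.uniform(0, 10, (4, 4, 4)))
        out = letrbe.combine_letd([dose], [let])
        mask = dose.data > 0
        np.testing.assert_allclose(out.data[mask], let.data[mask])

    def test_two_field_weighted_mean(self):
        d1 = VoxelGrid(np.full((1, 1, 1), 1.0))
        d2 = VoxelGrid(np.full((1, 1, 1), 3.0))
        l1 = VoxelGrid(np.full((1, 1, 1), 2.0))
        l2 = VoxelGrid(np.full((1, 1, 1), 6.0))
        out = letrbe.combine_letd([d1, d2], [l1, l2])
        assert out.data[0, 0, 0] == pytest.approx(5.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            letrbe.combine_letd(
                [VoxelGrid(np.ones((2, 2, 2)))], [VoxelGrid(np.ones((3, 3, 3)))]
            )

    def test_equivalent_to_event_scoring_on_pooled_events(self, rng):
        """Field-wise dose-weighted averaging must equal event-level scoring
        of the pooled event population (the defining identity of LET_d)."""
        shape = (5, 5, 5)
        fields = []
        pooled = []
        for _ in range(3):
            events = [
                DepositEvent(
                    tuple(rng.integers(0, 5, 3)),
                    dE=float(rng.uniform(0.05, 1.5)),
                    stopping_power=float(rng.uniform(0.5, 15.0)),
                )
                for _ in range(300)
            ]
            pooled.extend(events)
            dose = np.zeros(shape)
            for e in events:
                dose[e.voxel_index] += e.dE
            letd = letrbe.letd_from_events(events, shape)
            fields.append((VoxelGrid(dose), letd))
        combined = letrbe.combine_letd([f[0] for f in fields], [f[1] for f in fields])
        oracle = letrbe.letd_from_events(pooled, shape)
        np.testing.assert_allclose(combined.data, oracle.data, rtol=1e-12, atol=1e-14)


class TestMcNamaraRBE:
    def test_worked_value_matches_independent_solver(self):
        rbe = letrbe.rbe_mcnamara(2.0, 10.0, RBEModelParams(alpha_beta=4.0))
        assert rbe == pytest.approx(1.41033, abs=5e-5)
        assert rbe == pytest.approx(lq_isoeffect_rbe(2.0, 10.0, 4.0), abs=1e-9)

    def test_zero_let_closed_form(self):
        p = RBEModelParams(alpha_beta=4.0)
        expected = (np.sqrt(16 + 32 * p.p0 + 16 * p.p2**2) - 4.0) / 4.0
        assert letrbe.rbe_mcnamara(2.0, 0.0, p) == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing_in_let(self):
        lets = np.linspace(0.0, 20.0, 400)
        rbe = letrbe.rbe_mcnamara(2.0, lets, RBEModelParams(alpha_beta=4.0))
        assert np.all(np.diff(rbe) > 0)

    def test_zero_dose_limit_is_rbe_max(self):
        p = RBEModelParams(alpha_beta=6.0)
        rbe0 = letrbe.rbe_mcnamara(0.0, 5.0, p)
        assert rbe0 == pytest.approx(p.p0 + p.p1 * 5.0 / 6.0, rel=1e-12)

    def test_high_alpha_beta_limit_approaches_rbe_max(self):
        """As alpha/beta -> infinity, RBE -> RBE_max up to the quadratic
        residual d*(p3*LET)^2, which stays below 1e-3 for LET <= 5 at d=2."""
        p = RBEModelParams(alpha_beta=1e6)
        rbe = letrbe.rbe_mcnamara(2.0, 5.0, p)
        rbe_max = p.p0 + p.p1 * 5.0 / 1e6
        assert rbe == pytest.approx(rbe_max, abs=1e-3)

    def test_negative_inputs_rejected(self):
        p = RBEModelParams()
        with pytest.raises(ValueError):
            letrbe.rbe_mcnamara(-1.0, 5.0, p)
        with pytest.raises(ValueError):
            letrbe.rbe_mcnamara(2.0, -5.0, p)


class TestDoseRBE:
    def test_constant_rbe_is_uniform_factor(self, rng):
        phys = VoxelGrid(np.ones((3, 3, 3)))
        out = letrbe.dose_rbe(phys, None, None, 5, "cRBE")
        np.testing.assert_allclose(out.dose.data, 1.1)

    def test_low_let_vrbe_within_closed_form_band(self):
        phys = VoxelGrid(np.full((2, 2, 2), 30.0))
        let = VoxelGrid(np.zeros((2, 2, 2)))
        out = letrbe.dose_rbe(phys, let, None, 15, "vRBE-McNamara",
                              alpha_beta_normal=4.0)
        ratio = out.dose.data / phys.data
        assert np.all(ratio >= 1.00) and np.all(ratio <= 1.10)

    def test_alpha_beta_map_two_valued(self):
        phys = VoxelGrid(np.ones((4, 4, 4)))
        let = VoxelGrid(np.full((4, 4, 4), 3.0))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[:2] = True
        out = letrbe.dose_rbe(phys, let, mask, 1, "vRBE-McNamara",
                              alpha_beta_target=6.0, alpha_beta_normal=2.0)
        assert np.all(out.alpha_beta_map.data[mask] == 6.0)
        assert np.all(out.alpha_beta_map.data[~mask] == 2.0)

    def test_missing_let_grid_rejected_for_vrbe(self):
        with pytest.raises(ValueError):
            letrbe.dose_rbe(VoxelGrid(np.ones((2, 2, 2))), None, None, 1, "vRBE-McNamara")

    def test_vrbe_crbe_pointwise_consistency(self, rng):
        """vRBE dose exceeds cRBE dose exactly where RBE(d, LET) > 1.1."""
        phys = VoxelGrid(rng.uniform(0.5, 3.0, (6, 6, 6)) * 30)
        let = VoxelGrid(rng.uniform(0.0, 12.0, (6, 6, 6)))
        v = letrbe.dose_rbe(phys, let, None, 30, "vRBE-McNamara", alpha_beta_normal=2.0)
        c = letrbe.dose_rbe(phys, None, None, 30, "cRBE")
        above = v.rbe.data >= 1.1
        assert np.all(v.dose.data[above] >= c.dose.data[above])
        assert np.all(v.dose.data[~above] <= c.dose.data[~above])

    def test_fractionation_direction(self):
        """At fixed total physical dose, more fractions (smaller d) raises the
        vRBE-weighted dose in the RBE_max > RBE_min regime."""
        phys = VoxelGrid(np.full((2, 2, 2), 60.0))
        let = VoxelGrid(np.full((2, 2, 2), 5.0))
        d30 = letrbe.dose_rbe(phys, let, None, 30, "vRBE-McNamara", alpha_beta_normal=2.0)
        d60 = letrbe.dose_rbe(phys, let, None, 60, "vRBE-McNamara", alpha_beta_normal=2.0)
        assert np.all(d60.dose.data > d30.dose.data)


class TestRBEMapStats:
    def test_all_below_threshold_reports_missing(self):
        rbe = VoxelGrid(np.full((3, 3, 3), 1.2))
        d = VoxelGrid(np.full((3, 3, 3), 0.1))
        out = letrbe.rbe_map_stats(rbe, d, 60.0, {})
        assert np.isnan(out["body"]["mean"]) and out["body"]["n_voxels"] == 0

    def test_uniform_rbe_above_threshold(self):
        rbe = VoxelGrid(np.full((3, 3, 3), 1.2))
        d = VoxelGrid(np.full((3, 3, 3), 30.0))
        out = letrbe.rbe_map_stats(rbe, d, 60.0, {})
        assert out["body"]["mean"] == out["body"]["min"] == out["body"]["max"] == 1.2

    def test_threshold_is_five_percent_of_prescription(self):
        d = VoxelGrid(np.array([[[1.0, 4.0]]]))
        rbe = VoxelGrid(np.array([[[2.0, 1.5]]]))
        out = letrbe.rbe_map_stats(rbe, d, 60.0, {})
        # 1.0 < 3.0 = 5% of 60 -> excluded; only the 4.0 Gy voxel counts
        assert out["body"]["mean"] == 1.5 and out["body"]["n_voxels"] == 1
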