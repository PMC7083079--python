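"""Tests of the fitting functional: cost components, critical points,
information function and assembly."""

import warnings

import numpy as np
import pytest

from ogttfit.objective import (
    CostWeights,
    ObjectiveEvaluator,
    build_interpolant,
    cost_error,
    cost_exp,
    cost_spline,
    detect_critical_points,
    information_function,
    total_cost,
)
from ogttfit.params import ParameterSet
from ogttfit.records import OGTTRecord
from ogttfit.solver import PROTOCOL_TIMES, SolverSettings, Trajectory, sample_at, simulate


def _self_record(params, pid="self"):
    traj = simulate(params, SolverSettings(method="rk4"))
    G, I = sample_at(traj, PROTOCOL_TIMES)
    return OGTTRecord(pid, PROTOCOL_TIMES, G, I), traj


@pytest.fixture(scope="module")
def self_pair(params):
    return _self_record(params)


class TestCostExp:
    def test_noiseless_self_consistency(self, params, weights, self_pair):
        record, traj = self_pair
        assert cost_exp(record, traj, weights) < 1e-8

    def test_alpha_zero_ignores_insulin(self, params, weights, self_pair):
        record, traj = self_pair
        w0 = CostWeights(alpha=0.0)
        perturbed = OGTTRecord(record.patient_id, record.times,
                               record.G_exp, record.I_exp * 1.5)
        assert cost_exp(perturbed, traj, w0) == pytest.approx(
            cost_exp(record, traj, w0), abs=1e-14)

    def test_term_wise_oracle(self, params, weights, self_pair):
        record, traj = self_pair
        shifted = OGTTRecord(record.patient_id, record.times,
                             record.G_exp * 1.07, record.I_exp * 0.9)
        got = cost_exp(shifted, traj, weights)
        Gn, In = sample_at(traj, record.times)
        g2 = (shifted.G_exp.max() - shifted.G_exp.min()) ** 2
        i2 = (shifted.I_exp.max() - shifted.I_exp.min()) ** 2
        expected = (sum((shifted.G_exp - Gn) ** 2) / (5 * g2)
                    + weights.alpha * sum((shifted.I_exp - In) ** 2) / (5 * i2))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_flat_record_falls_back_to_basal_scaling(self, params, weights, self_pair):
        _, traj = self_pair
        flat = OGTTRecord("flat", PROTOCOL_TIMES,
                          np.full(5, 90.0), np.full(5, 8.0))
        with pytest.warns(UserWarning, match="flat"):
            val = cost_exp(flat, traj, weights)
        assert np.isfinite(val)


class TestInterpolant:
    def test_spline_boundary_passes_through_points(self, weights):
        rec = OGTTRecord("p", PROTOCOL_TIMES,
                         [90, 140, 120, 100, 95], [8, 40, 35, 20, 12])
        f = build_interpolant(rec, CostWeights(phi=1.0))
        G, I = f(rec.times)
        np.testing.assert_allclose(G, rec.G_exp, rtol=1e-12)
        np.testing.assert_allclose(I, rec.I_exp, rtol=1e-12)

    def test_polynomial_boundary_is_quadratic(self):
        rec = OGTTRecord("p", PROTOCOL_TIMES,
                         [90, 140, 120, 100, 95], [8, 40, 35, 20, 12])
        f = build_interpolant(rec, CostWeights(phi=0.0))
        ts = np.linspace(0, 120, 41)
        G, _ = f(ts)
        # a quadratic has vanishing third finite differences
        d3 = np.diff(G, n=3)
        np.testing.assert_allclose(d3, 0.0, atol=1e-9)

    def test_constant_record_reproduced_for_any_phi(self):
        rec = OGTTRecord("p", PROTOCOL_TIMES, np.full(5, 95.0), np.full(5, 9.0))
        for phi in (0.0, 0.3, 1.0):
            G, I = build_interpolant(rec, CostWeights(phi=phi))(np.linspace(0, 120, 25))
            np.testing.assert_allclose(G, 95.0, rtol=1e-12)
            np.testing.assert_allclose(I, 9.0, rtol=1e-12)


class TestCostSpline:
    def test_oscillation_between_samples_is_penalized(self, params, weights, self_pair):
        record, traj = self_pair
        # add a 15-min-period bump vanishing at every sample time
        bump = 8.0 * np.sin(2 * np.pi * traj.times / 15.0) ** 2
        bump[traj.times % 30 == 0] = 0.0
        wavy = Trajectory(traj.times, traj.S, traj.J, traj.L,
                          traj.G + bump, traj.I, params)
        assert cost_exp(record, wavy, weights) < 1e-6
        assert cost_spline(record, wavy, weights) > \
            cost_spline(record, traj, weights) + 1e-3

    def test_dense_grid_refinement_stability(self, params, weights, self_pair):
        record, _ = self_pair
        t1 = simulate(params, SolverSettings(method="rk4", dense_step=1.0))
        t2 = simulate(params, SolverSettings(method="rk4", dense_step=0.5))
        j1 = cost_spline(record, t1, weights)
        j2 = cost_spline(record, t2, weights,
                         dense_times=t2.times[t2.times <= record.times[-1]])
        assert j2 == pytest.approx(j1, rel=1e-2)


class TestCostError:
    def test_exact_passage_is_free(self, params, weights, self_pair):
        record, traj = self_pair
        assert cost_error(record, traj, weights) == 0.0

    def test_boundary_displacement_cheaper_than_mse(self, params, weights, self_pair):
        record, traj = self_pair
        # displace one measured point vertically by exactly delta_rel * value
        g = record.G_exp.copy()
        g[2] *= 1 + weights.delta_rel
        moved = OGTTRecord("m", record.times, g, record.I_exp)
        je = cost_error(moved, traj, weights)
        jx = cost_exp(moved, traj, weights)
        assert je < jx
        assert je < 1e-6  # at (or numerically inside) the ellipse boundary

    def test_temporal_shift_absorbed(self, params, weights, self_pair):
        record, traj = self_pair
        shifted = Trajectory(traj.times, traj.S, traj.J, traj.L,
                             np.interp(traj.times - 2.0, traj.times, traj.G),
                             np.interp(traj.times - 2.0, traj.times, traj.I),
                             params)
        dje = cost_error(record, shifted, weights) - cost_error(record, traj, weights)
        djx = cost_exp(record, shifted, weights) - cost_exp(record, traj, weights)
        assert dje < 0.1 * djx


class TestCriticalPoints:
    def test_single_rise_then_fall(self, weights):
        rec = OGTTRecord("p", PROTOCOL_TIMES,
                         [90, 140, 120, 100, 95], [8, 8.5, 9, 9.5, 10])
        cons = detect_critical_points(rec, weights)
        glucose = [c for c in cons if c.curve == "glucose"]
        assert len(glucose) == 1
        c = glucose[0]
        assert c.kind == "maximum"
        assert c.index == 1
        assert c.time_interval == (0.0, 60.0)
        assert c.value_interval[0] <= 140 <= c.value_interval[1]

    def test_monotone_curves_give_no_constraints(self, weights):
        rec = OGTTRecord("p", PROTOCOL_TIMES,
                         [90, 100, 120, 130, 140], [8, 10, 15, 20, 28])
        assert detect_critical_points(rec, weights) == []

    def test_double_peak_gives_three_constraints(self, weights):
        rec = OGTTRecord("p", PROTOCOL_TIMES,
                         [90, 150, 110, 145, 100], [8, 9, 10, 11, 12])
        cons = detect_critical_points(rec, weights)
        kinds = [c.kind for c in cons if c.curve == "glucose"]
        assert kinds == ["maximum", "minimum", "maximum"]

    def test_tie_counts_as_no_sign_change(self, weights):
        rec = OGTTRecord("p", PROTOCOL_TIMES,
                         [90, 140, 140, 100, 95], [8, 9, 10, 11, 12])
        cons = [c for c in detect_critical_points(rec, weights)
                if c.curve == "glucose"]
        # only the 140 -> 140 -> 100 corner can qualify, and the zero
        # difference blocks the strict inequality at index 1
        assert all(c.index != 1 for c in cons)

    def test_combined_maximum_is_six(self, weights):
        zigzag = [90, 150, 110, 145, 100]
        rec = OGTTRecord("p", PROTOCOL_TIMES, zigzag,
                         [8, 50, 20, 45, 10])
        cons = detect_critical_points(rec, weights)
        assert len(cons) == 6

    def test_never_more_than_three_per_curve(self, weights, rng):
        for _ in range(100):
            g = 90 + 60 * rng.random(5)
            i = 8 + 40 * rng.random(5)
            rec = OGTTRecord("p", PROTOCOL_TIMES, g, i)
            cons = detect_critical_points(rec, weights)
            per_curve = {"glucose": 0, "insulin": 0}
            for c in cons:
                per_curve[c.curve] += 1
            assert per_curve["glucose"] <= 3 and per_curve["insulin"] <= 3


class TestInformationFunction:
    def test_self_consistency(self, weights, noiseless_cohort):
        records, truths = noiseless_cohort
        for rec, tru in zip(records, truths):
            traj = simulate(tru, SolverSettings(method="rk4"))
            cons = detect_critical_points(rec, weights)
            feasible, violation = information_function(traj, cons, weights.delta_t)
            assert feasible, f"{rec.patient_id} infeasible at its own truth"
            assert violation == 0.0

    def test_doubled_peak_is_infeasible(self, weights, noiseless_cohort):
        records, truths = noiseless_cohort
        rec, tru = records[0], truths[0]
        cons = detect_critical_points(rec, weights)
        assert cons, "archetype should produce at least one constraint"
        inflated = tru.replace(eta=tru.eta * 3)
        traj = simulate(inflated, SolverSettings(method="rk4"))
        feasible, violation = information_function(traj, cons, weights.delta_t)
        assert not feasible
        assert violation > 0

    def test_empty_constraints_always_feasible(self, params, weights):
        traj = simulate(params, SolverSettings(method="rk4"))
        assert information_function(traj, [], weights.delta_t) == (True, 0.0)


class TestTotalCost:
    def test_additivity_of_components(self, params, weights, box, self_pair):
        record, _ = self_pair
        other = params.replace(eta=params.eta * 1.1)
        b = total_cost(record, other, weights, theta_ref=params, box=box,
                       settings=SolverSettings(method="rk4"))
        expected = (weights.lambda1 * b.j_exp + weights.lambda2 * b.j_spline
                    + weights.lambda3 * b.j_error + weights.epsilon * b.j_reg)
        if b.feasible:
            assert b.total == pytest.approx(expected, abs=1e-12)

    def test_epsilon_zero_independent_of_reference(self, params, box, self_pair):
        record, _ = self_pair
        w = CostWeights(epsilon=0.0)
        ref_a = params.free_vector()
        ref_b = params.free_vector() * 1.3
        ta = total_cost(record, params, w, theta_ref=ref_a, box=box,
                        settings=SolverSettings(method="rk4"))
        tb = total_cost(record, params, w, theta_ref=ref_b, box=box,
                        settings=SolverSettings(method="rk4"))
        assert ta.total == tb.total

    def test_noiseless_truth_matches_data_exactly(self, params, weights, box,
                                                  self_pair):
        # at the generating parameters the data and error terms vanish and
        # the point is feasible; J_spline stays positive by construction
        # (the interpolant is not the model curve)
        record, _ = self_pair
        b = total_cost(record, params, weights, theta_ref=params, box=box,
                       settings=SolverSettings(method="rk4"))
        assert b.j_exp < 1e-8
        assert b.j_error == 0.0
        assert b.j_reg == 0.0
        assert b.feasible

    def test_infeasible_hard_mode_is_sentinel(self, weights, box,
                                              noiseless_cohort):
        records, truths = noiseless_cohort
        rec, tru = records[0], truths[0]
        inflated = tru.replace(eta=tru.eta * 3)
        b = total_cost(rec, inflated, weights, box=box, mode="hard",
                       settings=SolverSettings(method="rk4"))
        assert b.total == np.inf and not b.feasible

    def test_soft_mode_is_finite_and_larger(self, weights, box, noiseless_cohort):
        records, truths = noiseless_cohort
        rec, tru = records[0], truths[0]
        inflated = tru.replace(eta=tru.eta * 3)
        b = total_cost(rec, inflated, weights, box=box, mode="soft",
                       settings=SolverSettings(method="rk4"))
        base = (weights.lambda1 * b.j_exp + weights.lambda2 * b.j_spline
                + weights.lambda3 * b.j_error)
        assert np.isfinite(b.total)
        assert b.total > base


class TestEvaluator:
    def test_counts_evaluations_and_matches_total_cost(self, params, weights,
                                                       box, self_pair):
        record, _ = self_pair
        ev = ObjectiveEvaluator(record, weights, box=box,
                                theta_ref=params.free_vector(),
                                settings=SolverSettings(method="rk4"))
        b1 = ev.evaluate_params(params)
        assert ev.n_evals == 1
        b2 = total_cost(record, params, weights, theta_ref=params, box=box,
                        settings=SolverSettings(method="rk4"), mode="soft")
        assert b1.total == pytest.approx(b2.total, rel=1e-12)

    def test_simulation_failure_is_infinite_cost(self, params, weights, box,
                                                 self_pair):
        record, _ = self_pair
        ev = ObjectiveEvaluator(record, weights, box=box,
                                settings=SolverSettings(method="rk4"))
        bad = params.replace(k_lambda=20.0, k_xg=0.05, k_xgi=5e-3, eta=2e-2,
                             gamma=8.0, beta=10.0, k_xi=0.1)
        b = ev.evaluate_params(bad)
        assert b.total == np.inf
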