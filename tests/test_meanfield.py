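"""Tests for the averaged dynamics: drifts, thresholds, equilibria."""

import math

import numpy as np
import pytest

from rstdp import meanfield as mf
from rstdp.action import ActionSelectionConfig
from rstdp.core import PlasticityRule
from rstdp.value import ValueEstimationConfig


def action_params(kind="additive", alpha=1.0, **kw):
    rule = PlasticityRule(kind, alpha=alpha, lambda_rate=0.01)
    return mf.AveragedParams.from_action_config(
        ActionSelectionConfig(**kw), rule)


def value_params(kind="additive", alpha=1.0, **kw):
    rule = PlasticityRule(kind, alpha=alpha, lambda_rate=0.001)
    return mf.AveragedParams.from_value_config(
        ValueEstimationConfig(**kw), rule)


def action_field(kind, params):
    n = params.n_inputs

    def f(x):
        d1, d2 = mf.action_drift(kind, x[:n], x[n:], params)
        return np.concatenate([np.atleast_1d(d1), np.atleast_1d(d2)])
    return f


def value_field(kind, params):
    n = params.n_inputs

    def f(x):
        dw, dp = mf.value_drift(kind, x[:n], x[n], params)
        return np.concatenate([np.atleast_1d(dw), [dp]])
    return f


class TestThresholds:
    def test_action_threshold_single_input(self):
        assert mf.alpha_threshold_action(0.7, 0.02, [10.0]) == pytest.approx(
            8.142857142857142, abs=1e-12)

    def test_action_threshold_two_inputs(self):
        assert mf.alpha_threshold_action(0.7, 0.02, [15.0, 5.0]) == \
            pytest.approx(4.571428571428571, abs=1e-12)

    def test_action_threshold_vanishing_tau(self):
        assert mf.alpha_threshold_action(0.7, 1e-12, [10.0]) > 1e9

    def test_value_threshold_defaults(self):
        assert mf.alpha_threshold_value(0.02, 10.0) == pytest.approx(6.0)

    def test_value_threshold_higher_rate(self):
        assert mf.alpha_threshold_value(0.02, 20.0) == pytest.approx(3.5)

    def test_value_threshold_zero_rate(self):
        assert mf.alpha_threshold_value(0.02, 0.0) == math.inf

    def test_action_threshold_consistent_with_drift_sign(self):
        # bisection on the drift sign at small equal weights reproduces the
        # closed form to 1e-6, for both rate configurations
        for rates in ([10.0], [15.0, 5.0]):
            n = len(rates)
            target = mf.alpha_threshold_action(0.7, 0.02, rates)

            def drift_sign(alpha):
                p = action_params("additive", alpha, rates=tuple(rates))
                w = np.full(n, 1e-4)
                d1, _ = mf.action_drift("additive", w, w, p)
                return float(np.sum(d1))

            lo_a, hi_a = 1.5, 20.0
            assert drift_sign(lo_a) > 0 > drift_sign(hi_a)
            for _ in range(60):
                mid = 0.5 * (lo_a + hi_a)
                if drift_sign(mid) > 0:
                    lo_a = mid
                else:
                    hi_a = mid
            assert abs(0.5 * (lo_a + hi_a) - target) < 1e-6

    def test_value_threshold_consistent_with_condition(self):
        # the stability-sum sign flips exactly at alpha* = 6 at defaults
        w = np.array([0.75])
        for alpha, expected in ((5.999, True), (6.001, False)):
            p = value_params("additive", alpha)
            assert mf.stability_condition_value("additive", w, 7.5,
                                                p) is expected


class TestStabilityCondition:
    def test_reduces_to_scalar_condition_at_n1(self):
        # additive, N=1: condition holds iff tau (alpha - 1) < 1/r1
        for alpha in (1.0, 4.0, 7.0):
            p = value_params("additive", alpha)
            expected = 0.02 * (alpha - 1.0) < 0.1
            assert mf.stability_condition_value(
                "additive", [0.75], 7.5, p) is expected

    def test_alpha_one_always_stable(self):
        p = value_params("symmetric", 1.0)
        assert mf.stability_condition_value("symmetric", [0.6], 7.5, p)


class TestDriftZeros:
    def test_origin_is_action_equilibrium(self, rule_kind):
        p = action_params(rule_kind)
        d1, d2 = mf.action_drift(rule_kind, [0.0], [0.0], p)
        assert abs(d1[0]) < 1e-10 and abs(d2[0]) < 1e-10

    def test_symmetric_corner_attractor_is_zero(self):
        p = action_params("symmetric")
        d1, d2 = mf.action_drift("symmetric", [1.0], [0.0], p)
        assert abs(d1[0]) < 1e-10 and abs(d2[0]) < 1e-10

    def test_corticostriatal_fixed_point_is_zero(self):
        p = action_params("corticostriatal")
        w1s, w2s = mf.corticostriatal_action_fixed_points(p)
        assert (w1s, w2s) == pytest.approx((0.890625, 0.109375), abs=1e-9)
        d1, d2 = mf.action_drift("corticostriatal", [w1s], [w2s], p)
        assert abs(d1[0]) < 1e-10 and abs(d2[0]) < 1e-10

    def test_value_reward_matching_zero_drift(self):
        # <w,r>/N = p R1* + (1-p) R2* nullifies the weight drift
        # p=0.6 -> mean reward 0.6*7.5 + 0.4*2.5 = 5.5 = 10 * 0.55
        p = value_params("additive")
        dw, _ = mf.value_drift("additive", [0.55], 0.6, p)
        assert abs(dw[0]) < 1e-12

    def test_value_p_boundaries_freeze_preference(self):
        p = value_params("symmetric")
        for p0 in (0.0, 1.0):
            _, dp = mf.value_drift("symmetric", [0.4], p0, p)
            assert dp == 0.0

    def test_value_origin_family_member(self):
        # w = 0, p = R2*/(R1*+R2*) = 0.25 has zero drift in both coordinates
        p = value_params("additive")
        dw, dp = mf.value_drift("additive", [0.0], 0.25, p)
        assert abs(dw[0]) < 1e-12 and abs(dp) < 1e-12


class TestEquilibriumCatalogue:
    def test_symmetric_value_boundary_point(self):
        p = value_params("symmetric")
        assert mf.symmetric_w1_boundary_p(p) == pytest.approx(0.75)
        eqs = mf.enumerate_equilibria("value", "symmetric", p)
        labels = {e.label for e in eqs}
        assert "w=1,p=0.75" in labels

    def test_value_w0_family_includes_quarter(self):
        eqs = mf.enumerate_equilibria("value", "additive",
                                      value_params("additive"))
        assert any(np.allclose(e.location, [0.0, 0.25]) for e in eqs)

    def test_corticostriatal_action_attractor(self):
        p = action_params("corticostriatal")
        eqs = mf.enumerate_equilibria("action", "corticostriatal", p)
        star = next(e for e in eqs if e.label == "(w1*,w2*)")
        assert star.stability == "attractor"
        assert np.all(star.eigenvalues.real < 0)

    def test_symmetric_action_corner_classification(self):
        # below threshold: (1,0) attractor, (0,1) repeller, corners saddles
        p = action_params("symmetric", alpha=1.0)
        eqs = {e.label: e for e in
               mf.enumerate_equilibria("action", "symmetric", p)}
        assert eqs["origin"].stability == "saddle"
        assert eqs["w1=1,w2=0"].stability == "attractor"
        assert eqs["w1=0,w2=1"].stability == "repeller"
        assert eqs["w1=1,w2=1"].stability == "saddle"

    def test_all_analytic_equilibria_have_tiny_residual(self):
        for setting, kinds, mk in (
            ("action", ("additive", "symmetric", "corticostriatal"),
             action_params),
            ("value", ("additive", "symmetric"), value_params),
        ):
            for kind in kinds:
                p = mk(kind, 4.0 if setting == "value" else 5.0)
                f = (action_field if setting == "action" else value_field)(
                    kind, p)
                for e in mf.enumerate_equilibria(setting, kind, p):
                    assert np.linalg.norm(f(e.location)) < 1e-10, e.label


class TestNumericCriticalPoints:
    def test_additive_action_clipping_corner_low_alpha(self):
        f = action_field("additive", action_params("additive", 1.0))
        eqs = mf.find_critical_points_numeric(f, 2, grid_density=9)
        clipped = [e for e in eqs if e.kind == "boundary-clipped"]
        assert any(np.allclose(e.location, [1.0, 0.0]) for e in clipped)
        assert not any(np.allclose(e.location, [0.0, 1.0]) for e in clipped)

    def test_additive_action_clipping_corner_high_alpha(self):
        f = action_field("additive", action_params("additive", 9.0))
        eqs = mf.find_critical_points_numeric(f, 2, grid_density=9)
        clipped = [e for e in eqs if e.kind == "boundary-clipped"]
        assert any(np.allclose(e.location, [0.0, 1.0]) for e in clipped)

    def test_corticostriatal_value_interior_points(self):
        f = value_field("corticostriatal", value_params("corticostriatal"))
        eqs = mf.find_critical_points_numeric(f, 2, grid_density=9)
        interior_w = [e for e in eqs
                      if e.kind == "numeric" and e.location[0] > 1e-3]
        assert len(interior_w) == 2
        # neither satisfies w r = R1* or R2*: the value estimate is biased
        for e in interior_w:
            west = e.location[0] * 10.0
            assert min(abs(west - 7.5), abs(west - 2.5)) > 0.2


class TestIntegration:
    def test_path_stays_at_equilibrium(self):
        p = value_params("additive")
        f = value_field("additive", p)
        _, path = mf.integrate_averaged(f, [0.75, 1.0], 5000.0)
        assert np.max(np.abs(path - [0.75, 1.0])) < 1e-6

    def test_action_flow_reaches_optimal_corner(self):
        p = action_params("additive", 1.0)
        f = action_field("additive", p)
        # the approach to w2 = 0 is asymptotic (the Ep(1-Ep) prefactor
        # collapses once the channels separate), so use a long horizon
        _, path = mf.integrate_averaged(f, [0.5, 0.5], 120_000.0)
        assert path[-1, 0] > 0.9 * path[:, 0].max()
        assert path[-1, 1] < 0.1

    def test_value_flow_climbs_center_manifold(self):
        p = value_params("additive", 1.0)
        f = value_field("additive", p)
        _, path = mf.integrate_averaged(f, [0.5, 0.5], 40_000.0)
        assert abs(path[-1, 0] - 0.75) < 0.02
        assert path[-1, 1] > 0.95
        late = path[-50:, 1]
        assert np.all(np.diff(late) > -1e-9)  # p non-decreasing late


class TestMonteCarloOracle:
    def test_action_drift_matches_single_cycle_mc(self):
        cfg = ActionSelectionConfig(T_del=6.0, r_dop=1 / 8.0, n_steps=1,
                                    n_trials=1)
        rule = PlasticityRule("additive", alpha=2.0, lambda_rate=0.01)
        params = mf.AveragedParams.from_action_config(
            cfg, rule, causal_scale=math.exp(-0.001 / rule.tau))
        params = mf.AveragedParams(**{**params.__dict__, "dt": 0.001})
        w1, w2 = [0.6], [0.35]
        pred = mf.action_drift("additive", w1, w2, params)
        (m1, m2), (s1, s2) = mf.monte_carlo_action_drift(
            "additive", w1, w2, cfg, rule, seed=1, n_trials=4000, tail_s=6.0)
        assert abs(m1[0] - pred[0][0]) < 3 * s1[0]
        assert abs(m2[0] - pred[1][0]) < 3 * s2[0]

    def test_corticostriatal_value_drift_matches_mc(self):
        # validates the semi-analytic positive/negative-dopamine split
        cfg = ValueEstimationConfig(T_del=5.0, n_steps=1, n_trials=1)
        rule = PlasticityRule("corticostriatal", alpha=1.0,
                              lambda_rate=0.001)
        params = mf.AveragedParams.from_value_config(
            cfg, rule, causal_scale=math.exp(-0.001 / rule.tau))
        params = mf.AveragedParams(**{**params.__dict__, "dt": 0.001})
        for w0, p0 in ((0.55, 0.4), (0.3, 0.8)):
            pred = mf.value_drift("corticostriatal", [w0], p0, params)
            mean, se = mf.monte_carlo_value_drift(
                "corticostriatal", [w0], p0, cfg, rule, seed=2,
                n_trials=5000, tail_s=6.0)
            assert abs(mean[0] - pred[0][0]) < 3 * se[0]
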