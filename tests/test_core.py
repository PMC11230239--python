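"""Unit tests for the stochastic simulation primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rstdp.core import (
    ChannelState,
    ConfigurationError,
    DopamineState,
    PlasticityRule,
    SimGrid,
    SpikeTrain,
    UnsupportedRuleQuery,
    decay,
    deposit_spikes,
    dopamine_step,
    sample_input_spikes,
    scaling_factors,
    thin_postsynaptic,
    weight_update,
)


class TestSampleInputSpikes:
    def test_zero_rate_gives_empty_train(self, grid, rng):
        (train,) = sample_input_spikes([0.0], 5.0, grid, rng)
        assert len(train) == 0

    def test_poisson_moments(self, grid, rng):
        # many independent units stand in for many seeds: each unit's count
        # over 1 s at 10 s^-1 should have mean 10 and variance ~ 10
        n_units = 10_000
        trains = sample_input_spikes(np.full(n_units, 10.0), 1.0, grid, rng)
        counts = np.array([len(t) for t in trains])
        se_mean = math.sqrt(10.0 / n_units)
        assert abs(counts.mean() - 10.0) < 4 * se_mean
        # Bernoulli-thinned grid: variance n p (1-p) = 9.9
        assert abs(counts.var() - 9.9) < 0.5

    def test_units_uncorrelated(self, grid, rng):
        t1, t2 = sample_input_spikes([10.0, 10.0], 10.0, grid, rng)
        n_bins = grid.n_bins(10.0)
        x1 = np.zeros(n_bins)
        x2 = np.zeros(n_bins)
        x1[(t1.times / grid.dt).round().astype(int)] = 1
        x2[(t2.times / grid.dt).round().astype(int)] = 1
        corr = np.corrcoef(x1, x2)[0, 1]
        assert abs(corr) < 4.0 / math.sqrt(n_bins)

    @pytest.mark.parametrize("rates", [[-1.0], [2000.0]])
    def test_invalid_rates_raise(self, grid, rng, rates):
        with pytest.raises(ConfigurationError):
            sample_input_spikes(rates, 1.0, grid, rng)


class TestThinPostsynaptic:
    def test_zero_weights_give_empty_train(self, grid, rng):
        pre = sample_input_spikes([20.0], 5.0, grid, rng)
        post = thin_postsynaptic(pre, [0.0], 1, grid, rng)
        assert len(post) == 0

    def test_unit_weight_copies_with_delay(self, grid, rng):
        pre = sample_input_spikes([20.0], 5.0, grid, rng)
        post = thin_postsynaptic(pre, [1.0], 1, grid, rng)
        keep = pre[0].times + grid.epsilon < 5.0
        np.testing.assert_allclose(post.times,
                                   pre[0].times[keep] + grid.epsilon,
                                   atol=1e-9)

    def test_rate_matches_linear_poisson(self, grid, rng):
        # N=2, r=(15,5), w=(0.5,0.5) -> postsynaptic rate <w,r>/N = 5 s^-1
        duration = 40.0
        pre = sample_input_spikes([15.0, 5.0], duration, grid, rng)
        post = thin_postsynaptic(pre, [0.5, 0.5], 2, grid, rng)
        expected = 5.0 * duration
        assert abs(len(post) - expected) < 3 * math.sqrt(expected)


class TestDecay:
    def test_zero_dt_is_identity(self):
        assert decay(0.73, 0.02, 0.0) == 0.73

    @pytest.mark.parametrize("dt,expected", [(0.001, 0.95), (0.005, 0.78)])
    def test_pairing_attenuation_constants(self, dt, expected):
        # e^{-eps/tau} for the default and the enlarged synaptic delay
        assert round(decay(1.0, 0.02, dt), 2) == expected

    def test_invalid_tau_raises(self):
        with pytest.raises(ConfigurationError):
            decay(1.0, 0.0, 0.001)


def _run_pair(order, gap_bins, tau=0.02, dt=0.001):
    """Hand-integrate an isolated spike pair through decay + deposits."""
    state = ChannelState([0.5])
    events = {0: order[0], gap_bins: order[1]}
    for b in range(gap_bins + 1):
        state.A_pre = state.A_pre * math.exp(-dt / tau)
        state.A_post = state.A_post * math.exp(-dt / tau)
        state.E_plus = state.E_plus * math.exp(-dt / tau)
        state.E_minus = state.E_minus * math.exp(-dt / tau)
        kind = events.get(b)
        deposit_spikes(state, [kind == "pre"], kind == "post", tau)
    return state


class TestDepositSpikes:
    def test_no_events_leaves_traces_at_zero(self):
        state = ChannelState([0.2])
        deposit_spikes(state, [False], False)
        assert state.A_post == 0.0
        assert np.all(state.E_plus == 0) and np.all(state.E_minus == 0)

    @pytest.mark.parametrize("gap_bins", [1, 5, 20])
    def test_pre_before_post_feeds_e_plus(self, gap_bins):
        state = _run_pair(("pre", "post"), gap_bins)
        assert state.E_plus[0] == pytest.approx(
            math.exp(-gap_bins * 0.001 / 0.02), rel=1e-12)
        assert state.E_minus[0] == 0.0

    @pytest.mark.parametrize("gap_bins", [1, 5, 20])
    def test_post_before_pre_feeds_e_minus(self, gap_bins):
        state = _run_pair(("post", "pre"), gap_bins)
        assert state.E_minus[0] == pytest.approx(
            math.exp(-gap_bins * 0.001 / 0.02), rel=1e-12)
        assert state.E_plus[0] == 0.0

    def test_pair_additivity_for_separated_pairs(self):
        # two pre->post pairs far apart: eligibility adds up independently
        tau, t_eli, dt = 0.02, 1.0, 0.001
        state = ChannelState([0.5])
        pair_bins = [(0, 2), (500, 503)]
        last = 503
        for b in range(last + 1):
            state.A_pre = state.A_pre * math.exp(-dt / tau)
            state.A_post = state.A_post * math.exp(-dt / tau)
            state.E_plus = state.E_plus * math.exp(-dt / t_eli)
            state.E_minus = state.E_minus * math.exp(-dt / t_eli)
            pre = any(b == p for p, _ in pair_bins)
            post = any(b == q for _, q in pair_bins)
            deposit_spikes(state, [pre], post, tau)
        expected = (math.exp(-2 * dt / tau) * math.exp(-(last - 2) * dt / t_eli)
                    + math.exp(-3 * dt / tau))
        assert state.E_plus[0] == pytest.approx(expected, rel=1e-9)


class TestScalingFactors:
    def test_additive_factors_are_weight_independent(self, make_rule):
        f_p, f_m = scaling_factors(make_rule("additive", alpha=1.0), 0.3)
        assert (f_p, f_m) == (1.0, 1.0)

    @pytest.mark.parametrize("w,expected", [(0.0, 0.0), (1.0, 0.0),
                                            (0.5, 0.25)])
    def test_symmetric_soft_bound(self, make_rule, w, expected):
        f_p, f_m = scaling_factors(make_rule("symmetric", alpha=1.0), w)
        assert f_p == pytest.approx(expected)
        assert f_m == pytest.approx(expected)

    def test_corticostriatal_query_unsupported(self, make_rule):
        with pytest.raises(UnsupportedRuleQuery):
            scaling_factors(make_rule("corticostriatal"), 0.5)


class TestWeightUpdate:
    def test_zero_dopamine_leaves_weights(self, make_rule, rule_kind):
        state = ChannelState([0.4], E_plus=[2.0], E_minus=[1.0])
        weight_update(make_rule(rule_kind), state, 0.0, 0.001)
        assert state.w[0] == 0.4

    def test_corticostriatal_potentiation_shrinks_near_one(self, make_rule):
        rule = make_rule("corticostriatal", lambda_rate=1.0)
        deltas = []
        for w in (0.2, 0.6, 0.99):
            state = ChannelState([w], E_plus=[1.0], E_minus=[0.0])
            weight_update(rule, state, 2.0, 0.001)
            deltas.append(state.w[0] - w)
        assert all(d >= 0 for d in deltas)
        assert deltas[0] > deltas[1] > deltas[2]

    def test_additive_clips_at_zero(self, make_rule):
        rule = make_rule("additive", lambda_rate=10.0)
        state = ChannelState([0.0], E_plus=[5.0], E_minus=[0.0])
        weight_update(rule, state, -3.0, 0.01)
        assert state.w[0] == 0.0
        assert state.clip_count == 1

    @pytest.mark.parametrize("d_sign", [-1.0, 1.0])
    @pytest.mark.parametrize("trace", ["plus", "minus"])
    def test_sign_table_all_rules(self, make_rule, rule_kind, d_sign, trace):
        # weights move with sign(D * (E+ - E-)) under every rule
        rule = make_rule(rule_kind, alpha=1.5, lambda_rate=1.0)
        for w in (0.1, 0.5, 0.9):
            state = ChannelState([w],
                                 E_plus=[1.0 if trace == "plus" else 0.0],
                                 E_minus=[0.0 if trace == "plus" else 1.0])
            weight_update(rule, state, 2.0 * d_sign, 0.001)
            expected = d_sign * (1 if trace == "plus" else -1)
            assert np.sign(state.w[0] - w) == expected

    def test_corticostriatal_bound_tracks_change_direction(self, make_rule):
        # increasing updates scale with (1-w), decreasing with alpha*w:
        # the respective update magnitudes vanish at the approached boundary
        rule = make_rule("corticostriatal", alpha=2.0, lambda_rate=1.0)
        up = ChannelState([1.0], E_plus=[1.0], E_minus=[0.0])
        weight_update(rule, up, 1.0, 0.001)
        assert up.w[0] == 1.0  # (1-w) = 0 exactly
        down = ChannelState([0.0], E_plus=[0.0], E_minus=[1.0])
        weight_update(rule, down, 1.0, 0.001)
        assert down.w[0] == 0.0  # alpha*w = 0 exactly


class TestDopamineStep:
    def test_one_time_constant_decay(self):
        dop = DopamineState(D=1.0, tau_dop=1.0)
        out = dopamine_step(dop, None, 1.0)
        assert out.D == pytest.approx(math.exp(-1.0))

    def test_negative_pulse_allowed(self):
        out = dopamine_step(DopamineState(D=0.0), -0.5, 0.001)
        assert out.D == pytest.approx(-0.5, rel=1e-6)

    def test_pulses_far_apart_do_not_interact(self):
        # default action-setting gap of 21 s vs tau_dop = 1 s
        dop = DopamineState(D=1.0, tau_dop=1.0)
        out = dopamine_step(dop, None, 21.0)
        assert abs(out.D) < 1e-3


class TestGridAndTrain:
    def test_epsilon_must_sit_on_grid(self):
        with pytest.raises(ConfigurationError):
            SimGrid(dt=0.001, epsilon=0.0015)
        with pytest.raises(ConfigurationError):
            SimGrid(dt=0.002, epsilon=0.001)

    def test_spike_train_validation(self):
        with pytest.raises(ConfigurationError):
            SpikeTrain(np.array([0.2, 0.1]), 1.0)
        with pytest.raises(ConfigurationError):
            SpikeTrain(np.array([0.5, 1.5]), 1.0)

    def test_count_in_half_open_window(self):
        train = SpikeTrain(np.array([0.1, 0.2, 0.3]), 1.0)
        assert train.count_in(0.1, 0.3) == 2


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.tuples(st.booleans(), st.booleans()),
                min_size=1, max_size=60),
       st.floats(min_value=-3.0, max_value=3.0))
def test_traces_never_negative_and_weights_bounded(events, d_level):
    """Invariant: traces stay non-negative and weights stay in [0, 1] under
    arbitrary event sequences and dopamine levels."""
    rule = PlasticityRule("symmetric", alpha=2.0, lambda_rate=5.0)
    state = ChannelState([0.5])
    dt, tau, t_eli = 0.001, 0.02, 1.0
    for pre, post in events:
        state.A_pre = state.A_pre * math.exp(-dt / tau)
        state.A_post = state.A_post * math.exp(-dt / tau)
        state.E_plus = state.E_plus * math.exp(-dt / t_eli)
        state.E_minus = state.E_minus * math.exp(-dt / t_eli)
        deposit_spikes(state, [pre], post, tau)
        weight_update(rule, state, d_level, dt)
        assert state.A_pre[0] >= 0 and state.A_post >= 0
        assert state.E_plus[0] >= 0 and state.E_minus[0] >= 0
        assert 0.0 <= state.w[0] <= 1.0
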