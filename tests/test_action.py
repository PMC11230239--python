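"""Tests for the two-channel action-selection setting."""

import math

import numpy as np
import pytest
from scipy.special import expit

from rstdp.action import (
    ActionSelectionConfig,
    expected_choice_probability,
    expected_choice_probability_from_means,
    rpe_dopamine,
    run_action_selection,
    select_action,
    windowed_rate,
)
from rstdp.core import ConfigurationError, PlasticityRule, SimGrid, SpikeTrain


class TestWindowedRate:
    def test_empty_train_gives_zero(self):
        assert windowed_rate(SpikeTrain(np.array([]), 20.0), 12.0, 1.0,
                             10.0) == 0.0

    def test_count_over_width(self):
        times = np.linspace(1.05, 1.95, 10)
        train = SpikeTrain(times, 20.0)
        assert windowed_rate(train, 12.0, 1.0, 10.0) == pytest.approx(10.0)

    def test_delay_segment_excluded(self):
        train = SpikeTrain(np.array([2.5, 5.0, 11.9]), 20.0)
        assert windowed_rate(train, 12.0, 1.0, 10.0) == 0.0

    def test_window_before_zero_raises(self):
        with pytest.raises(ConfigurationError):
            windowed_rate(SpikeTrain(np.array([]), 20.0), 5.0, 1.0, 10.0)


class TestSelectAction:
    def test_deterministic_count_comparison(self, rng):
        assert all(select_action(5, 3, 1e6, rng) == 0 for _ in range(20))
        assert all(select_action(3, 5, 1e6, rng) == 1 for _ in range(20))

    def test_ties_broken_fairly(self, rng):
        picks = np.array([select_action(4, 4, 1e6, rng) for _ in range(2000)])
        assert abs(picks.mean() - 0.5) < 4 * 0.5 / math.sqrt(2000)

    def test_moderate_beta_is_logistic(self, rng):
        picks = np.array([select_action(6, 4, 0.5, rng) for _ in range(4000)])
        p1 = expit(0.5 * 2)
        assert abs((picks == 0).mean() - p1) < 4 * math.sqrt(
            p1 * (1 - p1) / 4000)


class TestExpectedChoiceProbability:
    def test_exchangeable_channels_give_half(self):
        for beta in (1.0, 1e6):
            assert expected_choice_probability([0.4], [0.4], [10.0],
                                               beta=beta) == pytest.approx(0.5)

    def test_closed_form_one_vs_zero(self):
        # n1 = 1, n2 = 0, deterministic choice: P(N1>=1) + 0.5 P(N1=0)
        ep = expected_choice_probability_from_means(1.0, 0.0, beta=1e6)
        assert ep == pytest.approx(1.0 - 0.5 * math.exp(-1.0), abs=1e-10)

    def test_monte_carlo_oracle_moderate_beta(self, rng):
        n1, n2, beta = 6.3, 4.1, 0.7
        ep = expected_choice_probability_from_means(n1, n2, T_win=1.0,
                                                    beta=beta)
        samples = expit(beta * (rng.poisson(n1, 100_000)
                                - rng.poisson(n2, 100_000)))
        assert abs(ep - samples.mean()) < 3 * samples.std() / math.sqrt(
            100_000)


class TestRpeDopamine:
    def test_perfectly_predicted_reward(self):
        assert rpe_dopamine(0, 1.0, 2.0, 1.0) == 0.0

    def test_positive_surprise(self):
        assert rpe_dopamine(0, 0.5, 2.0, 1.0) == pytest.approx(0.5)

    def test_negative_surprise(self):
        assert rpe_dopamine(1, 0.5, 2.0, 1.0) == pytest.approx(-0.5)


class TestConfig:
    def test_window_must_fit_in_cycle(self):
        with pytest.raises(ConfigurationError):
            ActionSelectionConfig(T_win=1.0, T_del=25.0)

    def test_a_sel_bounds(self):
        with pytest.raises(ConfigurationError):
            ActionSelectionConfig(a_sel=1.5)


class TestRunActionSelection:
    def test_accounting_one_action_reward_pulse_per_step(self, grid):
        cfg = ActionSelectionConfig(n_steps=5, n_trials=3)
        rule = PlasticityRule("additive", lambda_rate=0.01)
        traj = run_action_selection(cfg, rule, grid, seed=3)
        assert traj.actions.shape == (3, 5)
        assert traj.rewards.shape == (3, 5)
        assert traj.pulses.shape == (3, 5)
        # reward follows the chosen action under the static contingency
        expected = np.where(traj.actions == 0, cfg.R1_star, cfg.R2_star)
        np.testing.assert_array_equal(traj.rewards, expected)

    def test_learns_more_rewarded_action(self, grid):
        cfg = ActionSelectionConfig(n_steps=150, n_trials=8)
        rule = PlasticityRule("additive", lambda_rate=0.01)
        traj = run_action_selection(cfg, rule, grid, seed=5)
        w1 = traj.final_weights[:, 0].mean()
        w2 = traj.final_weights[:, 1].mean()
        assert w1 > w2
        assert (traj.actions[:, -50:] == 0).mean() > 0.7

    def test_channel_exchange_symmetry(self, grid):
        # swapping the rewards swaps the roles of the channels
        rule = PlasticityRule("additive", lambda_rate=0.01)
        base = ActionSelectionConfig(n_steps=120, n_trials=8)
        swap = ActionSelectionConfig(n_steps=120, n_trials=8, R1_star=1.0,
                                     R2_star=2.0)
        t_base = run_action_selection(base, rule, grid, seed=9)
        t_swap = run_action_selection(swap, rule, grid, seed=10)
        gap_base = (t_base.final_weights[:, 0]
                    - t_base.final_weights[:, 1]).mean()
        gap_swap = (t_swap.final_weights[:, 0]
                    - t_swap.final_weights[:, 1]).mean()
        assert gap_base > 0.2
        assert gap_swap < -0.2

    def test_no_sustain_long_delay_blocks_learning(self, grid):
        # eligibility decays over T_del >> tau_eli: weights barely move
        cfg = ActionSelectionConfig(sustain=False, T_del=10.0, n_steps=40,
                                    n_trials=6)
        rule = PlasticityRule("additive", lambda_rate=0.01)
        traj = run_action_selection(cfg, rule, grid, seed=7)
        assert np.all(np.abs(traj.final_weights - 0.5) < 0.02)
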