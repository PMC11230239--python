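"""The two-channel action-selection setting.

Two postsynaptic neurons ("action channels") receive statistically
independent Poisson inputs with a shared rate vector r.  Once per dopamine
cycle of length 1/r_dop, postsynaptic spikes are counted over a window of
length T_win; the channel with more spikes wins (inverse temperature beta,
effectively deterministic at the default beta = 1e6, ties broken by a
fair coin) and the agent receives that action's reward.  After a delay T_del
a dopamine pulse carries the reward-prediction error

    D_k = R* - (R1* E[p] + R2* (1 - E[p])),

where E[p] -- the expected probability of choosing action 1 given the current
weights -- encodes the assumption that the agent's state-value estimate is
accurate.  Between the end of one counting window and the start of the next,
cortical input is silenced except (optionally) in the selected channel, where
it persists at a fraction a_sel of the full rate; this sustained activity is
what bridges the credit-assignment gap when T_del >> tau_eli.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit

from . import _kernels
from .core import ConfigurationError, PlasticityRule, SimGrid, SpikeTrain
from .trajectory import ActionTrajectory

DETERMINISM_BETA = _kernels.DET_BETA

__all__ = [
    "ActionSelectionConfig",
    "windowed_rate",
    "select_action",
    "expected_choice_probability",
    "rpe_dopamine",
    "run_action_selection",
    "single_cycle_weight_change_action",
]


@dataclass(frozen=True)
class ActionSelectionConfig:
    """Task parameters for the action-selection setting (defaults: N=1).

    The cycle is 1/r_dop long and must accommodate the counting window plus
    the reward delay (T_win + T_del <= 1/r_dop).
    """

    rates: tuple = (10.0,)
    R1_star: float = 2.0
    R2_star: float = 1.0
    T_win: float = 1.0
    T_del: float = 10.0
    r_dop: float = 1.0 / 21.0
    beta: float = 1.0e6
    a_sel: float = 0.7
    sustain: bool = True
    switch_period: int | None = None
    n_steps: int = 1000
    n_trials: int = 100
    w_init: float = 0.5

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.rates):
            raise ConfigurationError("rates must be non-negative")
        if self.T_win + self.T_del > 1.0 / self.r_dop + 1e-9:
            raise ConfigurationError(
                "T_win + T_del must not exceed the dopamine period 1/r_dop"
            )
        if not 0.0 <= self.a_sel <= 1.0:
            raise ConfigurationError("a_sel must lie in [0, 1]")
        if self.switch_period is not None and self.switch_period <= 0:
            raise ConfigurationError("switch_period must be positive or None")

    @property
    def n_inputs(self) -> int:
        return len(self.rates)


def windowed_rate(train: SpikeTrain, t_dop: float, T_win: float,
                  T_del: float) -> float:
    """Spike-count rate estimate over [t_dop - T_win - T_del, t_dop - T_del).

    The window is half-open (left-closed); events in the delay segment are
    excluded.
    """
    t0 = t_dop - T_win - T_del
    if t0 < -1e-12:
        raise ConfigurationError("counting window extends before t=0")
    return train.count_in(t0, t_dop - T_del) / T_win


def select_action(count1: int, count2: int, beta: float, rng,
                  T_win: float = 1.0) -> int:
    """Choose an action (0 = A1, 1 = A2) from the two window spike counts.

    For beta at or above the determinism threshold the larger count wins and
    ties are broken by a fair coin; otherwise A1 is drawn with probability
    logistic(beta * (count1 - count2) / T_win).
    """
    if count1 < 0 or count2 < 0:
        raise ConfigurationError("counts must be non-negative")
    if beta >= DETERMINISM_BETA:
        if count1 != count2:
            return 0 if count1 > count2 else 1
        return 0 if rng.random() < 0.5 else 1
    p1 = expit(beta * (count1 - count2) / T_win)
    return 0 if rng.random() < p1 else 1


def expected_choice_probability(w1, w2, rates, T_win: float = 1.0,
                                beta: float = 1.0e6,
                                tail_tol: float = 1e-12) -> float:
    """E[p]: expected probability of choosing A1 given the current weights.

    The two window counts are Poisson with means n_k = T_win <w_k, r> / N.
    For beta in the deterministic regime this is P(N1 > N2) + 0.5 P(N1 = N2);
    otherwise the double sum of the logistic choice function over the
    truncated Poisson supports (tails below tail_tol dropped).
    """
    w1 = np.atleast_1d(np.asarray(w1, float))
    w2 = np.atleast_1d(np.asarray(w2, float))
    rates = np.atleast_1d(np.asarray(rates, float))
    N = rates.size
    n1 = T_win * float(w1 @ rates) / N
    n2 = T_win * float(w2 @ rates) / N
    return expected_choice_probability_from_means(n1, n2, T_win, beta, tail_tol)


def expected_choice_probability_from_means(n1: float, n2: float,
                                           T_win: float = 1.0,
                                           beta: float = 1.0e6,
                                           tail_tol: float = 1e-12) -> float:
    hi = int(stats.poisson.ppf(1.0 - tail_tol, max(n1, n2, 1e-12))) + 1
    k = np.arange(hi + 1)
    p1 = stats.poisson.pmf(k, n1)
    p2 = stats.poisson.pmf(k, n2)
    if beta >= DETERMINISM_BETA:
        cdf2 = np.concatenate(([0.0], np.cumsum(p2)[:-1]))  # P(N2 < k)
        return float(p1 @ cdf2 + 0.5 * p1 @ p2)
    diff = (k[:, None] - k[None, :]) * (beta / T_win)
    return float(p1 @ expit(diff) @ p2)


def rpe_dopamine(chosen: int, Ep: float, R1_star: float,
                 R2_star: float) -> float:
    """Reward-prediction-error pulse: R* minus the expected reward.

    chosen is 0 for A1, 1 for A2; the expectation uses E[p] under the
    accurate-state-value assumption.
    """
    if not 0.0 <= Ep <= 1.0:
        raise ConfigurationError("Ep must lie in [0, 1]")
    r_star = R1_star if chosen == 0 else R2_star
    return r_star - (R1_star * Ep + R2_star * (1.0 - Ep))


def _kernel_args(config: ActionSelectionConfig, grid: SimGrid):
    cycle_bins = grid.n_bins(1.0 / config.r_dop)
    win_bins = grid.n_bins(config.T_win)
    del_bins = grid.n_bins(config.T_del)
    return cycle_bins, win_bins, del_bins


def run_action_selection(config: ActionSelectionConfig, rule: PlasticityRule,
                         grid: SimGrid = SimGrid(), seed: int = 0,
                         w_init=None) -> ActionTrajectory:
    """Simulate the full stochastic action-selection task.

    Returns the per-step trajectory across ``config.n_trials`` independent
    trials.  Each trial has its own RNG stream derived from ``seed``, so
    trial t is reproducible regardless of how many trials run.
    """
    N = config.n_inputs
    cycle_bins, win_bins, del_bins = _kernel_args(config, grid)
    if w_init is None:
        w0 = np.full((config.n_trials, 2, N), config.w_init)
    else:
        w0 = np.broadcast_to(
            np.asarray(w_init, float), (config.n_trials, 2, N)
        ).copy()
    seeds = np.random.SeedSequence(seed).generate_state(config.n_trials)
    out = _kernels.action_kernel(
        seeds, w0, np.asarray(config.rates, float),
        config.R1_star, config.R2_star, config.beta, config.a_sel,
        config.sustain, int(config.switch_period or 0), config.n_steps,
        rule.rule_id, rule.alpha, rule.lambda_rate, rule.tau, rule.tau_eli,
        1.0,  # tau_dop
        grid.dt, grid.eps_bins, cycle_bins, win_bins, del_bins,
        0, 1e-12, False, np.empty(0),
    )
    (w_traj, counts, actions, rewards, pulses, eps_rec,
     w_final, clips, _) = out
    time_s = (np.arange(config.n_steps) + 1) / config.r_dop
    return ActionTrajectory(time_s, w_traj, counts, actions, rewards,
                            pulses, eps_rec, w_final, clips, seed)


def single_cycle_weight_change_action(
    config: ActionSelectionConfig, rule: PlasticityRule, w_frozen,
    grid: SimGrid = SimGrid(), seed: int = 0, n_trials: int = 10_000,
    tail_s: float = 8.0,
):
    """Per-trial weight change over one dopamine cycle from a frozen state.

    Runs a single cycle (residual segment silent, full-rate window, action
    choice, sustained/silent delay, one pulse) plus a post-pulse tail of
    ``tail_s`` seconds during which the dopamine transient finishes
    integrating against the ongoing sustained activity.  Returns an array of
    shape (n_trials, 2, N) of weight changes.
    """
    N = config.n_inputs
    cycle_bins, win_bins, del_bins = _kernel_args(config, grid)
    w0 = np.broadcast_to(np.asarray(w_frozen, float), (n_trials, 2, N)).copy()
    seeds = np.random.SeedSequence(seed).generate_state(n_trials)
    out = _kernels.action_kernel(
        seeds, w0, np.asarray(config.rates, float),
        config.R1_star, config.R2_star, config.beta, config.a_sel,
        config.sustain, 0, 1,
        rule.rule_id, rule.alpha, rule.lambda_rate, rule.tau, rule.tau_eli,
        1.0,
        grid.dt, grid.eps_bins, cycle_bins, win_bins, del_bins,
        grid.n_bins(tail_s), 1e-12, False, np.empty(0),
    )
    w_final = out[6]
    return w_final - w0
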