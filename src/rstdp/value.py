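"""The single-neuron value-estimation setting.

One postsynaptic neuron's windowed firing rate R_bar is read out as the
agent's value estimate, and the dopamine pulse carries the prediction error
D_k = R* - R_bar.  Action selection is abstract: a preference difference
R_diff = R_bar_1 - R_bar_2 (reward units) sets the choice probability
p = logistic(beta * R_diff) and integrates the same dopamine signal,
dR_diff/dt = lambda_bar * D(t) * A_bar(t), where A_bar is +1 after choosing
A1 and -1 after A2.  Inputs fire continuously at the full rate r -- there is
no silencing and no sustained-activity fraction in this setting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from . import _kernels
from .core import ConfigurationError, PlasticityRule, SimGrid
from .trajectory import ValueTrajectory

__all__ = [
    "ValueEstimationConfig",
    "PreferenceState",
    "value_rpe",
    "preference_update",
    "choice_probability",
    "run_value_estimation",
    "single_cycle_weight_change_value",
]


@dataclass(frozen=True)
class ValueEstimationConfig:
    """Task parameters for the value-estimation setting (defaults: N=1)."""

    rates: tuple = (10.0,)
    R1_star: float = 7.5
    R2_star: float = 2.5
    T_win: float = 1.0
    T_del: float = 3.0
    r_dop: float = 1.0 / 7.0
    beta: float = 1.0
    lambda_bar: float = 0.0025
    p_init: float = 0.5
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
        if not 0.0 < self.p_init < 1.0:
            raise ConfigurationError("p_init must lie in (0, 1)")
        if self.switch_period is not None and self.switch_period <= 0:
            raise ConfigurationError("switch_period must be positive or None")

    @property
    def n_inputs(self) -> int:
        return len(self.rates)


@dataclass
class PreferenceState:
    """Abstract action-preference state: R_diff = R_bar_1 - R_bar_2."""

    R_diff: float = 0.0
    A_bar: int = 0  # +1 after A1, -1 after A2, 0 before any action


def value_rpe(R_star: float, R_bar: float) -> float:
    """Dopamine increment D_k = R* - R_bar (reward units = rate units)."""
    if R_bar < 0:
        raise ConfigurationError("R_bar must be non-negative")
    return R_star - R_bar


def preference_update(state: PreferenceState, D: float,
                      lambda_bar: float) -> PreferenceState:
    """One increment of the preference difference: R_diff += lb * D * A_bar.

    The per-variable factor of 1/2 in the underlying pair (R_bar_1, R_bar_2)
    cancels in the difference.
    """
    state.R_diff += lambda_bar * D * state.A_bar
    return state


def choice_probability(R_diff: float, beta: float) -> float:
    """p = logistic(beta * R_diff), overflow-safe at any magnitude."""
    return float(expit(beta * R_diff))


def _kernel_args(config: ValueEstimationConfig, grid: SimGrid):
    cycle_bins = grid.n_bins(1.0 / config.r_dop)
    win_bins = grid.n_bins(config.T_win)
    del_bins = grid.n_bins(config.T_del)
    return cycle_bins, win_bins, del_bins


def run_value_estimation(config: ValueEstimationConfig, rule: PlasticityRule,
                         grid: SimGrid = SimGrid(), seed: int = 0,
                         w_init=None) -> ValueTrajectory:
    """Simulate the full stochastic value-estimation task."""
    N = config.n_inputs
    cycle_bins, win_bins, del_bins = _kernel_args(config, grid)
    if w_init is None:
        w0 = np.full((config.n_trials, N), config.w_init)
    else:
        w0 = np.broadcast_to(
            np.asarray(w_init, float), (config.n_trials, N)
        ).copy()
    r_diff0 = float(logit(config.p_init)) / config.beta
    seeds = np.random.SeedSequence(seed).generate_state(config.n_trials)
    out = _kernels.value_kernel(
        seeds, w0, np.asarray(config.rates, float),
        config.R1_star, config.R2_star, config.beta,
        config.lambda_bar, r_diff0,
        int(config.switch_period or 0), config.n_steps,
        rule.rule_id, rule.alpha, rule.lambda_rate, rule.tau, rule.tau_eli,
        1.0,  # tau_dop
        grid.dt, grid.eps_bins, cycle_bins, win_bins, del_bins,
        0, False, np.empty(0),
    )
    (w_traj, p_traj, rbar, actions, rewards, pulses,
     w_final, r_diff_final, clips, _) = out
    time_s = (np.arange(config.n_steps) + 1) / config.r_dop
    return ValueTrajectory(time_s, w_traj, p_traj, rbar, actions, rewards,
                           pulses, w_final, r_diff_final, clips, seed)


def single_cycle_weight_change_value(
    config: ValueEstimationConfig, rule: PlasticityRule, w_frozen,
    p_frozen: float = 0.5, grid: SimGrid = SimGrid(), seed: int = 0,
    n_trials: int = 10_000, tail_s: float = 8.0,
):
    """Per-trial weight change after a single dopamine release.

    The preference is frozen at p_frozen (lambda_bar = 0) and the run covers
    one cycle plus a ``tail_s``-second tail with ongoing input so the
    dopamine transient is fully integrated.  Returns shape (n_trials, N).
    """
    N = config.n_inputs
    cycle_bins, win_bins, del_bins = _kernel_args(config, grid)
    w0 = np.broadcast_to(np.asarray(w_frozen, float), (n_trials, N)).copy()
    r_diff0 = float(logit(p_frozen)) / config.beta
    seeds = np.random.SeedSequence(seed).generate_state(n_trials)
    out = _kernels.value_kernel(
        seeds, w0, np.asarray(config.rates, float),
        config.R1_star, config.R2_star, config.beta,
        0.0, r_diff0, 0, 1,
        rule.rule_id, rule.alpha, rule.lambda_rate, rule.tau, rule.tau_eli,
        1.0,
        grid.dt, grid.eps_bins, cycle_bins, win_bins, del_bins,
        grid.n_bins(tail_s), False, np.empty(0),
    )
    w_final = out[6]
    return w_final - w0
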