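"""Stochastic simulation primitives for dopamine-modulated STDP.

This module defines the building blocks shared by the two task settings:
linear Poisson neurons on a fixed time grid, pre/post spike traces, dual
eligibility traces, an exponentially decaying dopamine signal, and the three
plasticity rules (additive, symmetric, corticostriatal).

The model is a linear Poisson neuron: N presynaptic units fire as independent
Poisson processes with rates r_i, and each presynaptic spike of unit i at time
t independently elicits a postsynaptic spike at t + eps with probability
w_i / N, so the postsynaptic rate is <w, r> / N.  Synaptic weights live in
[0, 1].  Each synapse carries a pre trace A_pre and shares a post trace A_post
(time constant tau); pre-before-post pairings feed an eligibility trace E_plus
and post-before-pre pairings feed E_minus (time constant tau_eli).  Weight
changes require a third factor: the dopamine level D relative to baseline,
which decays with tau_dop between pulses and may be negative.

The per-bin update rule for the additive and symmetric rules is

    dw_i = lambda * D * (f_plus(w_i) * E_plus_i - f_minus(w_i) * E_minus_i) * dt

with (f_plus, f_minus) = (1, alpha) for the additive rule and
(w(1-w), alpha*w(1-w)) for the symmetric rule.  The corticostriatal rule ties
the soft bound to the sign of the overall change instead of the sign of the
eligibility: for D >= 0 it uses (1-w) on E_plus and alpha*w on E_minus, and
for D < 0 it swaps them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RULES",
    "SimGrid",
    "PlasticityRule",
    "SpikeTrain",
    "ChannelState",
    "DopamineState",
    "ConfigurationError",
    "UnsupportedRuleQuery",
    "sample_input_spikes",
    "thin_postsynaptic",
    "decay",
    "deposit_spikes",
    "scaling_factors",
    "weight_update",
    "dopamine_step",
]

RULES = ("additive", "symmetric", "corticostriatal")


class ConfigurationError(ValueError):
    """Raised when parameters violate a model precondition."""


class UnsupportedRuleQuery(ValueError):
    """Raised when a query does not apply to the given plasticity rule."""


@dataclass(frozen=True)
class SimGrid:
    """Fixed simulation grid.

    dt : bin width in seconds.  Spikes are Bernoulli per bin; trace decays use
        exact exponential factors per bin, so there is no first-order Euler
        bias in the traces.
    epsilon : synaptic delay in seconds; constrained to a positive integer
        multiple of dt so a presynaptic spike in bin b elicits its caused
        postsynaptic spike exactly in bin b + epsilon/dt.
    """

    dt: float = 0.001
    epsilon: float = 0.001

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.epsilon < self.dt:
            raise ConfigurationError("epsilon must be at least one bin (dt)")
        if abs(self.epsilon / self.dt - round(self.epsilon / self.dt)) > 1e-9:
            raise ConfigurationError("epsilon must be an integer multiple of dt")

    @property
    def eps_bins(self) -> int:
        return int(round(self.epsilon / self.dt))

    def n_bins(self, duration: float) -> int:
        n = duration / self.dt
        if abs(n - round(n)) > 1e-6:
            raise ConfigurationError(
                f"duration {duration} is not a multiple of dt={self.dt}"
            )
        return int(round(n))


@dataclass(frozen=True)
class PlasticityRule:
    """A plasticity rule identity with its parameters.

    kind : 'additive' | 'symmetric' | 'corticostriatal'
    alpha : weighting of depression relative to potentiation (dimensionless).
    lambda_rate : learning rate (per unit eligibility x dopamine x time).
    tau : STDP pairing time constant, seconds.
    tau_eli : eligibility-trace time constant, seconds.
    """

    kind: str
    alpha: float = 1.0
    lambda_rate: float = 0.01
    tau: float = 0.02
    tau_eli: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in RULES:
            raise ConfigurationError(
                f"unknown rule kind {self.kind!r}; valid: {', '.join(RULES)}"
            )
        if self.tau <= 0 or self.tau_eli <= 0:
            raise ConfigurationError("tau and tau_eli must be positive")
        if self.lambda_rate < 0:
            raise ConfigurationError("lambda_rate must be non-negative")
        if self.alpha < 0:
            raise ConfigurationError("alpha must be non-negative")

    @property
    def rule_id(self) -> int:
        """Integer code used by the compiled kernels."""
        return RULES.index(self.kind)


@dataclass
class SpikeTrain:
    """Time-stamped point events on the simulation grid.

    times are in seconds, sorted ascending, with at most one event per grid
    bin, all strictly within [0, duration).
    """

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise ConfigurationError("spike times must be strictly increasing")
            if self.times[0] < 0 or self.times[-1] >= self.duration:
                raise ConfigurationError("spike times must lie in [0, duration)")

    def __len__(self) -> int:
        return int(self.times.size)

    def count_in(self, t0: float, t1: float) -> int:
        """Number of events in the half-open window [t0, t1)."""
        return int(np.searchsorted(self.times, t1, "left")
                   - np.searchsorted(self.times, t0, "left"))


@dataclass
class ChannelState:
    """Per-channel synaptic state: weights, spike traces, eligibility traces."""

    w: np.ndarray
    A_pre: np.ndarray = None
    A_post: float = 0.0
    E_plus: np.ndarray = None
    E_minus: np.ndarray = None
    clip_count: int = 0

    def __post_init__(self) -> None:
        self.w = np.atleast_1d(np.asarray(self.w, dtype=float)).copy()
        if np.any((self.w < 0) | (self.w > 1)):
            raise ConfigurationError("weights must lie in [0, 1]")
        n = self.w.size
        for name in ("A_pre", "E_plus", "E_minus"):
            v = getattr(self, name)
            setattr(
                self,
                name,
                np.zeros(n) if v is None else np.atleast_1d(np.asarray(v, float)).copy(),
            )

    @property
    def n(self) -> int:
        return int(self.w.size)


@dataclass
class DopamineState:
    """Dopamine level relative to baseline; decays toward 0 between pulses."""

    D: float = 0.0
    tau_dop: float = 1.0
    r_dop: float = 1.0 / 21.0

    def __post_init__(self) -> None:
        if self.tau_dop <= 0 or self.r_dop <= 0:
            raise ConfigurationError("tau_dop and r_dop must be positive")


def sample_input_spikes(rates, duration, grid: SimGrid, rng) -> list[SpikeTrain]:
    """Sample independent Poisson input trains, one per unit.

    Each grid bin of each unit fires independently with probability
    r_i * dt (Bernoulli thinning of the grid), so the expected count per unit
    over the run is r_i * duration.
    """
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    if np.any(rates < 0):
        raise ConfigurationError("rates must be non-negative")
    if np.any(rates * grid.dt > 1):
        raise ConfigurationError("r*dt must not exceed 1 (bin occupancy)")
    n_bins = grid.n_bins(duration)
    out = []
    for r in rates:
        hits = rng.random(n_bins) < r * grid.dt
        out.append(SpikeTrain(np.flatnonzero(hits) * grid.dt, duration))
    return out


def thin_postsynaptic(pre, w, N, grid: SimGrid, rng) -> SpikeTrain:
    """Thin presynaptic trains into the postsynaptic train.

    Each presynaptic spike of unit i at time t independently yields a
    postsynaptic event at t + epsilon with probability w_i / N, realizing the
    linear Poisson rate <w, r> / N.  Coincident candidates collapse into a
    single event (at most one spike per bin).
    """
    w = np.atleast_1d(np.asarray(w, dtype=float))
    if np.any((w < 0) | (w > 1)):
        raise ConfigurationError("weights must lie in [0, 1]")
    if len(pre) != N or w.size != N:
        raise ConfigurationError("pre, w and N must agree")
    events = []
    duration = pre[0].duration if pre else 0.0
    for i, train in enumerate(pre):
        keep = rng.random(len(train)) < w[i] / N
        events.append(train.times[keep] + grid.epsilon)
    times = np.unique(np.concatenate(events)) if events else np.array([])
    times = times[times < duration]
    # re-snap to grid to kill float drift from the epsilon shift
    times = np.round(times / grid.dt) * grid.dt
    return SpikeTrain(np.unique(times), duration)


def decay(x, tau, dt):
    """Exact exponential relaxation of a trace over dt: x * exp(-dt/tau)."""
    if tau <= 0:
        raise ConfigurationError("tau must be positive")
    if dt < 0:
        raise ConfigurationError("dt must be non-negative")
    return x * math.exp(-dt / tau)


def deposit_spikes(state: ChannelState, pre_events, post_event: bool,
                   tau: float = 0.02) -> ChannelState:
    """Deposit one bin's spike events into the traces (after decay).

    Pre events are processed before post events within a bin: for each
    presynaptic spike on unit i, E_minus_i += A_post then A_pre_i += 1; for a
    postsynaptic spike, E_plus_i += A_pre_i (for every i) then A_post += 1.
    The ordering means a coincident pre+post bin credits the pre->post pairing
    at zero lag.
    """
    pre_events = np.atleast_1d(np.asarray(pre_events, dtype=bool))
    if pre_events.size != state.n:
        raise ConfigurationError("pre_events length must equal the synapse count")
    state.E_minus = state.E_minus + pre_events * state.A_post
    state.A_pre = state.A_pre + pre_events.astype(float)
    if post_event:
        state.E_plus = state.E_plus + state.A_pre
        state.A_post += 1.0
    return state


def scaling_factors(rule: PlasticityRule, w):
    """Soft-bound scaling factors (f_plus, f_minus) at weight w.

    additive -> (1, alpha); symmetric -> (w(1-w), alpha*w(1-w)).  The
    corticostriatal rule has no dopamine-independent factorization (its
    factors depend on the sign of D), so querying it raises.
    """
    w = np.asarray(w, dtype=float)
    if np.any((w < 0) | (w > 1)):
        raise ConfigurationError("w must lie in [0, 1]")
    if rule.kind == "additive":
        one = np.ones_like(w)
        return one, rule.alpha * one
    if rule.kind == "symmetric":
        base = w * (1.0 - w)
        return base, rule.alpha * base
    raise UnsupportedRuleQuery(
        "the corticostriatal rule's scaling factors depend on the dopamine "
        "sign; use weight_update directly"
    )


def weight_update(rule: PlasticityRule, state: ChannelState, D: float,
                  dt: float) -> ChannelState:
    """Apply one bin's three-factor weight update and clip to [0, 1].

    additive / symmetric:
        dw = lambda * D * (f+(w) E_plus - f-(w) E_minus) * dt
    corticostriatal (sign of the change tracks the sign of D x eligibility):
        D >= 0:  dw = lambda * D * ((1-w) E_plus - alpha w E_minus) * dt
        D <  0:  dw = lambda * D * (alpha w E_plus - (1-w) E_minus) * dt

    All rules are clipped to [0, 1] after the update; clipping events are
    counted on the state (for the additive rule clipping is part of the model,
    for the soft-bounded rules it only guards finite-dt overshoot).
    """
    w = state.w
    if rule.kind == "corticostriatal":
        if D >= 0:
            dw = rule.lambda_rate * D * (
                (1.0 - w) * state.E_plus - rule.alpha * w * state.E_minus
            ) * dt
        else:
            dw = rule.lambda_rate * D * (
                rule.alpha * w * state.E_plus - (1.0 - w) * state.E_minus
            ) * dt
    else:
        f_plus, f_minus = scaling_factors(rule, w)
        dw = rule.lambda_rate * D * (
            f_plus * state.E_plus - f_minus * state.E_minus
        ) * dt
    new_w = w + dw
    clipped = np.clip(new_w, 0.0, 1.0)
    state.clip_count += int(np.sum(clipped != new_w))
    state.w = clipped
    return state


def dopamine_step(dop: DopamineState, pulse, dt: float) -> DopamineState:
    """Advance the dopamine level one bin: exact decay, then optional pulse.

    pulse is the reward-prediction-error increment D_k (may be negative) or
    None.  Pulses are assumed to arrive only at multiples of 1/r_dop.
    """
    D = decay(dop.D, dop.tau_dop, dt)
    if pulse is not None:
        D += float(pulse)
    return replace(dop, D=D)
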