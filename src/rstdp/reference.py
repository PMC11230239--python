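"""Slow reference engine built from the core primitives.

This module re-implements the task loops in plain Python on top of the
``rstdp.core`` operations, consuming uniforms from an explicit buffer in the
same order as the compiled kernels' draw contract.  It exists to validate the
kernels draw-for-draw on short runs; it is far too slow for production use.
"""

from __future__ import annotations

import math

import numpy as np

from ._kernels import DET_BETA
from .action import ActionSelectionConfig, expected_choice_probability_from_means
from .core import ChannelState, PlasticityRule, SimGrid, weight_update
from .value import ValueEstimationConfig


class _Draws:
    def __init__(self, uniforms):
        self.u = np.asarray(uniforms, float)
        self.cur = 0

    def __call__(self) -> float:
        v = self.u[self.cur]
        self.cur += 1
        return v


def reference_action_run(config: ActionSelectionConfig, rule: PlasticityRule,
                         grid: SimGrid, w_init, uniforms,
                         n_steps: int | None = None, tail_s: float = 0.0):
    """One action-selection trial driven by an explicit uniform buffer.

    Returns (per-step weight snapshots, actions, pulses, final weights,
    number of uniforms consumed).
    """
    draws = _Draws(uniforms)
    N = config.n_inputs
    rates = np.asarray(config.rates, float)
    n_steps = config.n_steps if n_steps is None else n_steps
    cycle_bins = grid.n_bins(1.0 / config.r_dop)
    win_bins = grid.n_bins(config.T_win)
    del_bins = grid.n_bins(config.T_del)
    ws = cycle_bins - win_bins - del_bins
    e = grid.eps_bins
    dt = grid.dt
    g_dop = math.exp(-dt / 1.0)

    chans = [ChannelState(np.broadcast_to(np.asarray(w_init, float)[j], (N,)))
             for j in range(2)]
    pending: list[dict] = [dict(), dict()]  # bin -> True
    counts = [0, 0]
    D = 0.0
    sel = -1
    rew = [config.R1_star, config.R2_star]
    w_traj = np.zeros((n_steps, 2, N))
    actions = np.zeros(n_steps, np.int8)
    pulses = np.zeros(n_steps)

    total_bins = n_steps * cycle_bins + grid.n_bins(tail_s)
    for b in range(total_bins):
        step = b // cycle_bins
        in_tail = step >= n_steps
        bc = cycle_bins if in_tail else b - step * cycle_bins
        in_win = (not in_tail) and (ws <= bc < ws + win_bins)
        if not in_tail and config.switch_period:
            swapped = (step // config.switch_period) % 2 == 1
            rew = ([config.R2_star, config.R1_star] if swapped
                   else [config.R1_star, config.R2_star])

        for ch in range(2):
            st = chans[ch]
            st.A_pre = st.A_pre * math.exp(-dt / rule.tau)
            st.A_post = st.A_post * math.exp(-dt / rule.tau)
            st.E_plus = st.E_plus * math.exp(-dt / rule.tau_eli)
            st.E_minus = st.E_minus * math.exp(-dt / rule.tau_eli)

        pre_flags = [np.zeros(N, bool), np.zeros(N, bool)]
        for ch in range(2):
            if in_win:
                scale = 1.0
            elif config.sustain and ch == sel:
                scale = config.a_sel
            else:
                scale = 0.0
            if scale > 0.0:
                for i in range(N):
                    if draws() < scale * rates[i] * dt:
                        pre_flags[ch][i] = True
                        if draws() < chans[ch].w[i] / N:
                            pending[ch][b + e] = True

        for ch in range(2):
            post = pending[ch].pop(b, False)
            st = chans[ch]
            # deposits via the core primitive (decay already applied above)
            st.E_minus = st.E_minus + pre_flags[ch] * st.A_post
            st.A_pre = st.A_pre + pre_flags[ch].astype(float)
            if post:
                st.E_plus = st.E_plus + st.A_pre
                st.A_post += 1.0
                if in_win:
                    counts[ch] += 1

        if (not in_tail) and bc == ws + win_bins - 1:
            if config.beta >= DET_BETA:
                if counts[0] > counts[1]:
                    sel = 0
                elif counts[1] > counts[0]:
                    sel = 1
                else:
                    sel = 0 if draws() < 0.5 else 1
            else:
                x = config.beta * (counts[0] - counts[1]) / config.T_win
                p1 = 1.0 / (1.0 + math.exp(-x)) if x >= 0 else (
                    math.exp(x) / (1.0 + math.exp(x)))
                sel = 0 if draws() < p1 else 1

        if abs(D) > 1e-18:
            for ch in range(2):
                weight_update(rule, chans[ch], D, dt)

        D *= g_dop
        if (not in_tail) and bc == cycle_bins - 1:
            n1 = config.T_win * float(chans[0].w @ rates) / N
            n2 = config.T_win * float(chans[1].w @ rates) / N
            ep = expected_choice_probability_from_means(
                n1, n2, config.T_win, config.beta)
            r_star = rew[sel]
            dk = r_star - (rew[0] * ep + rew[1] * (1.0 - ep))
            D += dk
            w_traj[step, 0] = chans[0].w
            w_traj[step, 1] = chans[1].w
            actions[step] = sel
            pulses[step] = dk
            counts = [0, 0]

    w_final = np.stack([chans[0].w, chans[1].w])
    return w_traj, actions, pulses, w_final, draws.cur


def reference_value_run(config: ValueEstimationConfig, rule: PlasticityRule,
                        grid: SimGrid, w_init, uniforms,
                        n_steps: int | None = None, tail_s: float = 0.0):
    """One value-estimation trial driven by an explicit uniform buffer."""
    from scipy.special import logit

    draws = _Draws(uniforms)
    N = config.n_inputs
    rates = np.asarray(config.rates, float)
    n_steps = config.n_steps if n_steps is None else n_steps
    cycle_bins = grid.n_bins(1.0 / config.r_dop)
    win_bins = grid.n_bins(config.T_win)
    del_bins = grid.n_bins(config.T_del)
    ws = cycle_bins - win_bins - del_bins
    e = grid.eps_bins
    dt = grid.dt
    g_dop = math.exp(-dt / 1.0)

    st = ChannelState(np.broadcast_to(np.asarray(w_init, float), (N,)))
    pending: dict = {}
    count = 0
    D = 0.0
    r_diff = float(logit(config.p_init)) / config.beta
    abar = 0.0
    rbar = 0.0
    sel = -1
    p_sel = 0.5
    rew = [config.R1_star, config.R2_star]
    w_traj = np.zeros((n_steps, N))
    p_traj = np.zeros(n_steps)
    pulses = np.zeros(n_steps)

    total_bins = n_steps * cycle_bins + grid.n_bins(tail_s)
    for b in range(total_bins):
        step = b // cycle_bins
        in_tail = step >= n_steps
        bc = cycle_bins if in_tail else b - step * cycle_bins
        in_win = (not in_tail) and (ws <= bc < ws + win_bins)
        if not in_tail and config.switch_period:
            swapped = (step // config.switch_period) % 2 == 1
            rew = ([config.R2_star, config.R1_star] if swapped
                   else [config.R1_star, config.R2_star])

        st.A_pre = st.A_pre * math.exp(-dt / rule.tau)
        st.A_post = st.A_post * math.exp(-dt / rule.tau)
        st.E_plus = st.E_plus * math.exp(-dt / rule.tau_eli)
        st.E_minus = st.E_minus * math.exp(-dt / rule.tau_eli)

        pre_flags = np.zeros(N, bool)
        for i in range(N):
            if draws() < rates[i] * dt:
                pre_flags[i] = True
                if draws() < st.w[i] / N:
                    pending[b + e] = True

        post = pending.pop(b, False)
        st.E_minus = st.E_minus + pre_flags * st.A_post
        st.A_pre = st.A_pre + pre_flags.astype(float)
        if post:
            st.E_plus = st.E_plus + st.A_pre
            st.A_post += 1.0
            if in_win:
                count += 1

        if (not in_tail) and bc == ws + win_bins - 1:
            x = config.beta * r_diff
            p_sel = 1.0 / (1.0 + math.exp(-x)) if x >= 0 else (
                math.exp(x) / (1.0 + math.exp(x)))
            sel = 0 if draws() < p_sel else 1
            abar = 1.0 if sel == 0 else -1.0
            rbar = count / config.T_win

        if abs(D) > 1e-18:
            weight_update(rule, st, D, dt)
            r_diff += config.lambda_bar * D * abar * dt

        D *= g_dop
        if (not in_tail) and bc == cycle_bins - 1:
            dk = rew[sel] - rbar
            D += dk
            w_traj[step] = st.w
            p_traj[step] = p_sel
            pulses[step] = dk
            count = 0

    return w_traj, p_traj, pulses, st.w.copy(), draws.cur
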