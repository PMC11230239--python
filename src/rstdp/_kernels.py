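"""Compiled per-bin simulation kernels.

These kernels realize, bin by bin, exactly the update scheme documented in
``rstdp.core`` (decay -> pre deposits -> post deposits -> action selection at
the window end -> weight update -> dopamine decay / pulse), vectorized only in
the sense of being compiled; each trial runs its own sequential loop with its
own RNG stream.  ``rstdp.reference`` re-implements the same contract in plain
Python on top of the core primitives and is used to verify the kernels
draw-for-draw in the test suite.

Random-draw order contract (per bin, per trial):
  1. for each channel, for each input unit with a nonzero rate: one uniform
     for the Bernoulli spike; if it fires, one uniform for the thinning
     decision (probability w_i/N, read at the pre-spike time);
  2. at the final bin of a counting window, after post deposits: one uniform
     for the action draw (only on ties when beta is in the deterministic
     regime).
Dopamine pulses land at the start of the bin containing k/r_dop, i.e. they
are added right after the decay step at the end of the preceding bin.

When ``use_uniforms`` is set the kernels consume pre-drawn uniforms from the
given buffer in contract order instead of the internal RNG (single trial
only); the number of consumed draws is returned for cross-validation.
"""

import numpy as np
from numba import njit

DET_BETA = 1.0e4  # above this, action choice is an exact count comparison

_D_SKIP = 1e-18  # |D| below this contributes nothing at double precision


@njit(cache=True)
def ep_expected(n1, n2, beta, t_win, tail_tol):
    """E[p]: probability that channel 1 wins the spike-count comparison.

    n1, n2 are the Poisson means of the two post counts.  For beta above the
    determinism threshold this is P(N1 > N2) + 0.5 P(N1 = N2); otherwise the
    double sum of the logistic choice function over the truncated supports.
    """
    mx = n1 if n1 > n2 else n2
    K = int(mx + 12.0 * np.sqrt(mx + 1.0)) + 20
    p1 = np.empty(K)
    p2 = np.empty(K)
    p1[0] = np.exp(-n1)
    p2[0] = np.exp(-n2)
    for k in range(1, K):
        p1[k] = p1[k - 1] * n1 / k
        p2[k] = p2[k - 1] * n2 / k
    if beta >= DET_BETA:
        # P(N1 > N2) + 0.5 * P(N1 == N2)
        c2 = 0.0
        acc = 0.0
        for i in range(K):
            acc += p1[i] * (c2 + 0.5 * p2[i])
            c2 += p2[i]
        return acc
    acc = 0.0
    for i in range(K):
        if p1[i] < tail_tol and i > n1:
            break
        for j in range(K):
            if p2[j] < tail_tol and j > n2:
                continue
            x = beta * (i - j) / t_win
            if x >= 0.0:
                logistic = 1.0 / (1.0 + np.exp(-x))
            else:
                e = np.exp(x)
                logistic = e / (1.0 + e)
            acc += logistic * p1[i] * p2[j]
    return acc


@njit(cache=True, inline="always")
def _dw_bin(rule_id, alpha, lam, D, w, ep_tr, em_tr, dt):
    """One bin's weight increment for a single synapse."""
    if rule_id == 0:  # additive
        return lam * D * (ep_tr - alpha * em_tr) * dt
    if rule_id == 1:  # symmetric
        b = w * (1.0 - w)
        return lam * D * b * (ep_tr - alpha * em_tr) * dt
    # corticostriatal: soft bound follows the sign of the change
    if D >= 0.0:
        return lam * D * ((1.0 - w) * ep_tr - alpha * w * em_tr) * dt
    return lam * D * (alpha * w * ep_tr - (1.0 - w) * em_tr) * dt


@njit(cache=True)
def action_kernel(
    seeds,            # (n_trials,) uint64-ish per-trial seeds
    w_init,           # (n_trials, 2, N)
    rates,            # (N,)
    R1_star, R2_star, beta, a_sel,
    sustain,          # bool
    switch_period,    # int, 0 = no contingency switching
    n_steps,
    rule_id, alpha, lam, tau, tau_eli, tau_dop,
    dt, eps_bins, cycle_bins, win_bins, del_bins,
    tail_bins,        # extra post-run bins (sustain continues, no pulses)
    tail_tol,
    use_uniforms, uniforms,
):
    n_trials = w_init.shape[0]
    N = rates.shape[0]
    ws = cycle_bins - win_bins - del_bins  # window start within a cycle

    g_tau = np.exp(-dt / tau)
    g_eli = np.exp(-dt / tau_eli)
    g_dop = np.exp(-dt / tau_dop)

    w_traj = np.zeros((n_trials, n_steps, 2, N))
    counts_traj = np.zeros((n_trials, n_steps, 2), np.int32)
    actions = np.zeros((n_trials, n_steps), np.int8)
    rewards = np.zeros((n_trials, n_steps))
    pulses = np.zeros((n_trials, n_steps))
    eps_rec = np.zeros((n_trials, n_steps))
    w_final = np.zeros((n_trials, 2, N))
    clip_counts = np.zeros(n_trials, np.int64)
    draws_used = 0

    ring_len = eps_bins + 1

    for tr in range(n_trials):
        if not use_uniforms:
            np.random.seed(seeds[tr])
        cur = 0

        w = w_init[tr].copy()
        a_pre = np.zeros((2, N))
        a_post = np.zeros(2)
        e_plus = np.zeros((2, N))
        e_minus = np.zeros((2, N))
        ring = np.zeros((2, ring_len), np.int8)
        counts = np.zeros(2, np.int64)
        D = 0.0
        sel = -1  # no action before the first window closes
        rew0 = R1_star
        rew1 = R2_star
        n_clip = 0

        total_bins = n_steps * cycle_bins + tail_bins
        for b in range(total_bins):
            step = b // cycle_bins
            bc = b - step * cycle_bins  # bin within cycle
            in_tail = step >= n_steps
            if in_tail:
                bc = cycle_bins  # force "outside window" segment logic
            in_win = (not in_tail) and (ws <= bc < ws + win_bins)

            if not in_tail and switch_period > 0:
                if (step // switch_period) % 2 == 1:
                    rew0 = R2_star
                    rew1 = R1_star
                else:
                    rew0 = R1_star
                    rew1 = R2_star

            # -- decay
            for ch in range(2):
                a_post[ch] *= g_tau
                for i in range(N):
                    a_pre[ch, i] *= g_tau
                    e_plus[ch, i] *= g_eli
                    e_minus[ch, i] *= g_eli

            # -- presynaptic Bernoulli draws + deposits + thinning
            wslot = (b + eps_bins) % ring_len
            for ch in range(2):
                if in_win:
                    scale = 1.0
                elif sustain and ch == sel:
                    scale = a_sel
                else:
                    scale = 0.0
                if scale > 0.0:
                    for i in range(N):
                        p_fire = scale * rates[i] * dt
                        if use_uniforms:
                            u = uniforms[cur]
                            cur += 1
                        else:
                            u = np.random.random()
                        if u < p_fire:
                            e_minus[ch, i] += a_post[ch]
                            a_pre[ch, i] += 1.0
                            if use_uniforms:
                                u2 = uniforms[cur]
                                cur += 1
                            else:
                                u2 = np.random.random()
                            if u2 < w[ch, i] / N:
                                ring[ch, wslot] = 1

            # -- postsynaptic deposits (candidates scheduled eps_bins ago)
            rslot = b % ring_len
            for ch in range(2):
                if ring[ch, rslot] > 0:
                    for i in range(N):
                        e_plus[ch, i] += a_pre[ch, i]
                    a_post[ch] += 1.0
                    if in_win:
                        counts[ch] += 1
                ring[ch, rslot] = 0

            # -- action selection at the window close
            if (not in_tail) and bc == ws + win_bins - 1:
                if beta >= DET_BETA:
                    if counts[0] > counts[1]:
                        sel = 0
                    elif counts[1] > counts[0]:
                        sel = 1
                    else:
                        if use_uniforms:
                            u = uniforms[cur]
                            cur += 1
                        else:
                            u = np.random.random()
                        sel = 0 if u < 0.5 else 1
                else:
                    x = beta * (counts[0] - counts[1]) / (win_bins * dt)
                    if x >= 0.0:
                        p1 = 1.0 / (1.0 + np.exp(-x))
                    else:
                        e = np.exp(x)
                        p1 = e / (1.0 + e)
                    if use_uniforms:
                        u = uniforms[cur]
                        cur += 1
                    else:
                        u = np.random.random()
                    sel = 0 if u < p1 else 1

            # -- weight update
            if D > _D_SKIP or D < -_D_SKIP:
                for ch in range(2):
                    for i in range(N):
                        nw = w[ch, i] + _dw_bin(
                            rule_id, alpha, lam, D, w[ch, i],
                            e_plus[ch, i], e_minus[ch, i], dt,
                        )
                        if nw < 0.0:
                            nw = 0.0
                            n_clip += 1
                        elif nw > 1.0:
                            nw = 1.0
                            n_clip += 1
                        w[ch, i] = nw

            # -- dopamine decay; pulse lands at the start of the next bin
            D *= g_dop
            if (not in_tail) and bc == cycle_bins - 1:
                n1 = 0.0
                n2 = 0.0
                for i in range(N):
                    n1 += w[0, i] * rates[i]
                    n2 += w[1, i] * rates[i]
                t_win = win_bins * dt
                ep = ep_expected(t_win * n1 / N, t_win * n2 / N,
                                 beta, t_win, tail_tol)
                r_star = rew0 if sel == 0 else rew1
                dk = r_star - (rew0 * ep + rew1 * (1.0 - ep))
                D += dk
                w_traj[tr, step] = w
                counts_traj[tr, step, 0] = counts[0]
                counts_traj[tr, step, 1] = counts[1]
                actions[tr, step] = sel
                rewards[tr, step] = r_star
                pulses[tr, step] = dk
                eps_rec[tr, step] = ep
                counts[0] = 0
                counts[1] = 0

        w_final[tr] = w
        clip_counts[tr] = n_clip
        draws_used = cur

    return (w_traj, counts_traj, actions, rewards, pulses, eps_rec,
            w_final, clip_counts, draws_used)


@njit(cache=True)
def value_kernel(
    seeds,
    w_init,           # (n_trials, N)
    rates,            # (N,)
    R1_star, R2_star, beta,
    lam_bar, r_diff_init,
    switch_period, n_steps,
    rule_id, alpha, lam, tau, tau_eli, tau_dop,
    dt, eps_bins, cycle_bins, win_bins, del_bins,
    tail_bins, use_uniforms, uniforms,
):
    n_trials = w_init.shape[0]
    N = rates.shape[0]
    ws = cycle_bins - win_bins - del_bins

    g_tau = np.exp(-dt / tau)
    g_eli = np.exp(-dt / tau_eli)
    g_dop = np.exp(-dt / tau_dop)

    w_traj = np.zeros((n_trials, n_steps, N))
    p_traj = np.zeros((n_trials, n_steps))
    rbar_traj = np.zeros((n_trials, n_steps))
    actions = np.zeros((n_trials, n_steps), np.int8)
    rewards = np.zeros((n_trials, n_steps))
    pulses = np.zeros((n_trials, n_steps))
    w_final = np.zeros((n_trials, N))
    r_diff_final = np.zeros(n_trials)
    clip_counts = np.zeros(n_trials, np.int64)
    draws_used = 0

    ring_len = eps_bins + 1

    for tr in range(n_trials):
        if not use_uniforms:
            np.random.seed(seeds[tr])
        cur = 0

        w = w_init[tr].copy()
        a_pre = np.zeros(N)
        a_post = 0.0
        e_plus = np.zeros(N)
        e_minus = np.zeros(N)
        ring = np.zeros(ring_len, np.int8)
        count = 0
        D = 0.0
        r_diff = r_diff_init
        abar = 0.0  # +1 after A1, -1 after A2, 0 before the first action
        rew0 = R1_star
        rew1 = R2_star
        rbar = 0.0
        sel = -1
        p_sel = 0.5
        n_clip = 0

        total_bins = n_steps * cycle_bins + tail_bins
        for b in range(total_bins):
            step = b // cycle_bins
            bc = b - step * cycle_bins
            in_tail = step >= n_steps
            if in_tail:
                bc = cycle_bins
            in_win = (not in_tail) and (ws <= bc < ws + win_bins)

            if not in_tail and switch_period > 0:
                if (step // switch_period) % 2 == 1:
                    rew0 = R2_star
                    rew1 = R1_star
                else:
                    rew0 = R1_star
                    rew1 = R2_star

            a_post *= g_tau
            for i in range(N):
                a_pre[i] *= g_tau
                e_plus[i] *= g_eli
                e_minus[i] *= g_eli

            # inputs fire continuously in this setting (no silencing)
            wslot = (b + eps_bins) % ring_len
            for i in range(N):
                if use_uniforms:
                    u = uniforms[cur]
                    cur += 1
                else:
                    u = np.random.random()
                if u < rates[i] * dt:
                    e_minus[i] += a_post
                    a_pre[i] += 1.0
                    if use_uniforms:
                        u2 = uniforms[cur]
                        cur += 1
                    else:
                        u2 = np.random.random()
                    if u2 < w[i] / N:
                        ring[wslot] = 1

            rslot = b % ring_len
            if ring[rslot] > 0:
                for i in range(N):
                    e_plus[i] += a_pre[i]
                a_post += 1.0
                if in_win:
                    count += 1
            ring[rslot] = 0

            if (not in_tail) and bc == ws + win_bins - 1:
                x = beta * r_diff
                if x >= 0.0:
                    p_sel = 1.0 / (1.0 + np.exp(-x))
                else:
                    e = np.exp(x)
                    p_sel = e / (1.0 + e)
                if use_uniforms:
                    u = uniforms[cur]
                    cur += 1
                else:
                    u = np.random.random()
                sel = 0 if u < p_sel else 1
                abar = 1.0 if sel == 0 else -1.0
                rbar = count / (win_bins * dt)

            if D > _D_SKIP or D < -_D_SKIP:
                for i in range(N):
                    nw = w[i] + _dw_bin(rule_id, alpha, lam, D, w[i],
                                        e_plus[i], e_minus[i], dt)
                    if nw < 0.0:
                        nw = 0.0
                        n_clip += 1
                    elif nw > 1.0:
                        nw = 1.0
                        n_clip += 1
                    w[i] = nw
                # preference difference integrates the same dopamine signal
                r_diff += lam_bar * D * abar * dt

            D *= g_dop
            if (not in_tail) and bc == cycle_bins - 1:
                r_star = rew0 if sel == 0 else rew1
                dk = r_star - rbar
                D += dk
                w_traj[tr, step] = w
                p_traj[tr, step] = p_sel
                rbar_traj[tr, step] = rbar
                actions[tr, step] = sel
                rewards[tr, step] = r_star
                pulses[tr, step] = dk
                count = 0

        w_final[tr] = w
        r_diff_final[tr] = r_diff
        clip_counts[tr] = n_clip
        draws_used = cur

    return (w_traj, p_traj, rbar_traj, actions, rewards, pulses,
            w_final, r_diff_final, clip_counts, draws_used)
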