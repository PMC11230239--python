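# Methods

## Model

The simulator implements three dopamine-modulated spike-timing-dependent
plasticity (STDP) rules acting on the synapses of linear Poisson neurons, and
embeds them in two reinforcement-learning task settings.

**Neuron.** N presynaptic units fire as independent Poisson processes with
constant rates `r_i`. Each presynaptic spike of unit `i` at time `t`
independently elicits a postsynaptic spike at `t + eps` with probability
`w_i / N`, so the postsynaptic neuron is itself a Poisson process with rate
`<w, r> / N`. Weights are confined to `[0, 1]`.

**Traces and eligibility.** Each synapse carries a presynaptic trace
`A_pre_i` and shares a postsynaptic trace `A_post`, both decaying with the
STDP time constant `tau`. Pre-before-post pairings increment a potentiation
eligibility `E+_i` (by the current `A_pre_i` at each postsynaptic spike) and
post-before-pre pairings increment a depression eligibility `E-_i` (by the
current `A_post` at each presynaptic spike); both eligibilities decay with
`tau_eli`. Using two traces keeps spike pairs from interacting, so pair
contributions sum independently.

**Dopamine.** The dopamine level `D` is measured relative to baseline, may be
negative, decays with `tau_dop`, and receives a pulse every `1/r_dop` seconds
whose size is a reward-prediction error (setting-dependent, below).

**The three rules.** Additive and symmetric rules update weights as
`dw_i = lambda * D * (f+(w_i) E+_i - f-(w_i) E-_i) dt` with
`(f+, f-) = (1, alpha)` (additive) or `(w(1-w), alpha w(1-w))` (symmetric).
The corticostriatal rule ties the soft bound to the sign of the overall
change rather than the sign of the eligibility: for `D >= 0` it uses `(1-w)`
on `E+` and `alpha w` on `E-`, and swaps them for `D < 0`. The multiplicative
rule `(1-w, alpha w)` is exposed only through its scaling factors; it fails
to bound weights once dopamine can change sign, and is not simulated.

**Action-selection setting.** Two channels with private input streams share
the rate vector `r`. Per dopamine cycle: postsynaptic spikes are counted over
a window `T_win`; the larger count wins (inverse temperature `beta`,
effectively deterministic at the default `beta = 1e6`, ties broken by a fair
coin); after a delay `T_del` the pulse `D_k = R* - (R1* Ep + R2* (1 - Ep))`
arrives, where `Ep` is the expected win probability of channel 1 under the
current weights (the "accurate state value" assumption), computed as a
truncated double Poisson sum. Between the end of one window and the start of
the next, input is silenced except in the selected channel, where it persists
at `a_sel * r` (sustained activity); a no-sustain variant silences both.

**Value-estimation setting.** A single neuron; inputs fire continuously. The
windowed rate `R_bar` is the value estimate and the pulse is
`D_k = R* - R_bar`. Action choice is abstract: a preference difference
`R_diff` sets `p = logistic(beta * R_diff)` and integrates the same dopamine
signal, `dR_diff/dt = lambda_bar * D(t) * A_bar(t)` with `A_bar = +1/-1`
after choosing action 1/2.

## Defaults

Per-setting defaults (action / value): `lambda` 0.01 / 0.001, `lambda_bar`
— / 0.0025, rewards (2, 1) / (7.5, 2.5), `T_del` 10 s / 3 s, `r_dop` 1/21 /
1/7 s^-1, `beta` 1e6 / 1, `a_sel` 0.7 / —; shared: `r` = 10 s^-1 per unit
(or (15, 5) for the two-input action variant), `tau` = 20 ms, `tau_eli` =
`tau_dop` = 1 s, `T_win` = 1 s, `eps` = 1 ms, `w_init` = `p_init` = 0.5,
`alpha` = 1, 100 trials x 1000 steps. Contingency-switching value runs
default to `lambda` = 1.5e-4 and `lambda_bar` = 5e-3, the values under which
all three rules cope at least moderately with switches.

## Discretization

Time is a fixed grid, `dt` = 1 ms. Spikes are Bernoulli per bin (at most one
per unit per bin); `eps` is constrained to a whole number of bins so a caused
postsynaptic spike lands exactly `eps` after its cause. All decays use exact
per-bin exponential factors, removing first-order Euler bias from the traces;
the weight and preference updates are explicit per-bin Euler steps, which is
adequate because per-bin weight increments are O(1e-6). Within a bin the
order is: decay, presynaptic deposits, postsynaptic deposits, action
selection (at a window's final bin), weight update, dopamine decay; pulses
are applied at the start of the bin containing `k/r_dop`. For exactly
coincident pre and post events the pre deposit is read first, so a same-bin
pairing credits `E+` at zero lag — a convention, as is uniform clipping of
all rules to `[0, 1]` (the soft-bounded rules clip only against finite-`dt`
overshoot; clipping events are counted and reported).

Production runs use compiled (numba) kernels, one sequential loop per trial;
`rstdp.reference` re-implements the identical contract in plain Python on
the core primitives and the test suite verifies the two agree draw-for-draw
on short runs with an injected uniform stream.

**RNG.** Each trial uses one Mersenne-Twister stream seeded from
`SeedSequence(base_seed)`, so trial `t` is reproducible independently of the
number of trials, and identical seeds give byte-identical outputs. The draw
order within a bin (per channel, per unit: spike draw, then a thinning draw
if it fired; then at a window close, at most one selection draw) is part of
the engine contract.

## Averaged dynamics

With the reward delay long relative to `tau_eli`, the pulse is independent of
the eligibility, and averaging over spike trains and pulses gives
deterministic drifts built from the steady-state eligibility expectations
`E[E+]/tau_eli = r_i (tau <w,r> + cs * w_i (1 - q_i)) / N` and
`E[E-]/tau_eli = r_i tau <w,r> / N`, where `cs = e^{-eps/tau}` attenuates
causal pairs. Two evaluation modes exist:

- the **continuum limit** (default: `cs = 1`, `dt = 0`), which matches the
  closed-form thresholds — the action-setting drift changes sign at
  `alpha* = 1 + 1/(a_sel tau sum_i r_i)` (8.14 at N=1, r=10; 4.57 at N=2,
  r=(15,5)) and the value-setting reward-matching equilibria destabilize at
  `alpha* = 1 + 1/(tau r_1)` (6 at defaults). The total-rate form of the
  action threshold is the one consistent with both worked values.
- the **exact-discrete mode** (`dt` = grid step, `cs = e^{-eps/tau}`), in
  which the pairing windows become the geometric-sum values
  `dt/(1 - e^{-dt/tau})` (for `E+`) and its one-bin-lagged counterpart (for
  `E-`), and causal pairs carry a `(1 - r dt)` bin-occupancy factor. This
  removes the O(dt) bias (~1% at defaults) when validating the drift
  equations against the simulator, so that test checks the averaging rather
  than the grid error.

The corticostriatal action drift branches on the sign of the conditional
mean dopamine per channel and has the interior fixed point (equal-weight
form, `rho = a_sel tau sum(r)`):
`W1* = (rho + cs)/(rho(1 + alpha) + cs)`,
`W2* = rho/(rho(1 + alpha) + alpha cs)` — (0.891, 0.109) at defaults. Both
coordinates were validated against the stochastic simulator (single-cycle
Monte-Carlo drift at frozen weights); convergence of the full task onto
`W2*` is slow because the `Ep(1-Ep)` prefactor collapses once the channels
separate (slowest eigenvalue ~ -1.7e-6 s^-1 at defaults), so finite runs sit
above `W2*`.

The corticostriatal value-setting weight drift cannot factor out the mean
dopamine (the rule branches on its sign). It is computed semi-analytically:
the pulse `D = R*_A - n/T_win` has its positive and negative parts
`E[D+], E[D-]` evaluated by truncated Poisson sums over the window count and
the two actions, each multiplying its branch of the update. This keeps the
field smooth for root finding; the stochastic single-cycle Monte-Carlo is
retained as an independent oracle in the tests. The `p` drift is common to
all rules.

## Equilibria, stability, critical points

`enumerate_equilibria` returns the analytic catalogue per setting and rule
(the origin; the symmetric rule's corners; the corticostriatal interior
points; in the value setting the `w = 0` family at
`p in {0, 1, R2*/(R1*+R2*)}`, the reward-matching hyperplanes, and the
symmetric rule's `w = 1` family including
`p = (R2* - nu)/(R1* + R2* - 2 nu)` with `nu = <1, r>/N`, i.e. 0.75 at
defaults). Stability comes from a central-difference Jacobian (step 1e-6,
one-sided at box faces). Eigendirections with near-zero real part are
resolved by probing the flow 1e-3 along the eigenvector from whichever sides
stay in the box — necessary because the symmetric rule's corner equilibria
are quadratically degenerate (`w(1-w)` vanishes with zero slope) yet
genuinely attract or repel. Reward-matching points, known analytically to
carry a center manifold in `p`, are always reported as `center-manifold`
with the transverse eigenvalue recorded; the flow direction along the
manifold is checked by integration from perturbed points rather than by
computing manifold coefficients.

`find_critical_points_numeric` multi-starts `scipy.optimize.root` from a
grid (default 21 per axis; 9 in the plotting pipeline), dedupes within 1e-4,
and accepts a candidate as a zero only if its residual is both below the
absolute tolerance (1e-8) and small relative to the field a probe step away
— an absolute test alone misclassifies the near-degenerate regions created
by the `Ep(1-Ep)` prefactor at deterministic `beta`. On 2-D boxes it also
reports boundary accumulation points of the clipped flow (outward normal
drift with attracting tangential flow on a face, or flow pushing into a
corner along every dimension); these are flagged `boundary-clipped` and never
reported as zeros. `integrate_averaged` runs `solve_ivp` on the field with
outward components masked at the boundary, realizing the same clipped flow.

## Validation statistics and problem sizes

The drift-oracle check compares single-cycle `E[dw]` (10^4 trials per state,
25 random states per setting, both additive and symmetric rules) with the
averaged prediction in exact-discrete mode. Runs use a long delay
(`T_del`/`tau_eli` >= 5, with shortened idle segments to keep the cycle
cheap) and a post-pulse tail of 6 `tau_dop` so the pulse integrates fully.
Each comparison yields a z-score against the Monte-Carlo standard error; a
wrong drift term produces |z| in the tens to hundreds, while correct
agreement leaves z approximately standard normal. Because a per-comparison
2-SE criterion fails ~5% of the time by construction, the suite asserts
aggregates: >= 80% of comparisons within 2 SE, median |z| <= 1.5, max
|z| <= 6.

Stochastic task-level checks run at reduced scale — 20 trials with 400–1500
steps depending on the design (contingency blocks of 500 steps instead of
1000, three blocks), and 10^3 samples per point for single-pulse drift
curves — sizes at which every qualitative contrast tested (channel
preference below vs above threshold, switch recovery vs sticking, delay
collapse without sustain, the zero crossing near `w = 0.5`) is separated
from its alternative by far more than the Monte-Carlo noise. Experiment
pipelines default to full scale (100 trials, 1000 steps, 10^4
pulse samples) with a `fast` flag applying the reduction.

## What the generator does and does not emulate

Inputs are homogeneous Poisson with no cross-correlation; dopamine pulses
are instantaneous and perfectly periodic; value estimates in the action
setting are exact by construction. Real cortical inputs are correlated and
nonstationary, dopamine ramps rather than jumps, and value estimates are
themselves learned — so passing tests show the rules' behavior under the
model's idealizations, not robustness to those features. Within the model,
the simulator is exact up to the stated O(dt) discretization.

## Known limitations

- The corticostriatal closed-form fixed points use the equal-weight ansatz;
  for N > 1 with unequal rates they are exact only when all synapses share
  the same root of the per-synapse quadratic.
- Boundary-clipped detection is implemented for 2-D state spaces (N = 1 per
  channel), which covers every catalogued case; higher-dimensional searches
  return interior zeros only.
- The symmetric rule's additional N > 1 equilibria are found numerically but
  not classified analytically.
- Averaged drifts assume the delay decorrelates pulse and eligibility; at
  `T_del = 0` the simulator shows the expected small, predominantly
  downward, deviation from the prediction, and no averaged model is provided
  for that regime.
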