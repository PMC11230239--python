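"""Averaged (mean-field) dynamics: drift fields, thresholds, equilibria.

Averaging the stochastic three-factor update over spike trains and dopamine
pulses — valid when the reward delay is long relative to the eligibility
time constant, so the pulse is statistically independent of the eligibility —
gives deterministic drift fields for the synaptic weights (and, in the
value-estimation setting, the choice probability p).  The key ingredients are
the steady-state eligibility expectations per synapse,

    E[E_plus]  = tau_eli * r_i * (tau * <w, r> + cs * w_i) / N
    E[E_minus] = tau_eli * r_i *  tau * <w, r>            / N

(chance pairings at rate r_pre * r_post within the pairing window tau, plus
causal pairings at rate r_i w_i / N attenuated by cs = e^{-eps/tau}, taken as
1 in the idealized limit), and the mean dopamine conditioned on the action
taken.  This module evaluates those drifts, the closed-form stability
thresholds in alpha, the catalogue of analytic equilibria with their
stability, numerical critical-point searches (including boundary accumulation
points created by weight clipping, which are not zeros of the field), and
trajectory integration for phase portraits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from scipy.integrate import solve_ivp

from .action import ActionSelectionConfig, expected_choice_probability
from .core import ConfigurationError, PlasticityRule
from .value import ValueEstimationConfig

__all__ = [
    "AveragedParams",
    "Equilibrium",
    "action_drift",
    "value_drift",
    "alpha_threshold_action",
    "alpha_threshold_value",
    "stability_condition_value",
    "corticostriatal_action_fixed_points",
    "symmetric_w1_boundary_p",
    "enumerate_equilibria",
    "find_critical_points_numeric",
    "integrate_averaged",
    "classify_equilibrium",
    "monte_carlo_action_drift",
    "monte_carlo_value_drift",
]


@dataclass(frozen=True)
class AveragedParams:
    """Parameters of the averaged dynamics (both settings).

    causal_scale is the attenuation e^{-eps/tau} of the causal-pair term; the
    default 1.0 is the idealized limit the closed-form thresholds assume.
    dt > 0 switches the eligibility expectations to their exact values on a
    discrete grid of that step (the pairing windows become the geometric sums
    dt/(1-e^{-dt/tau}) and its one-bin-lagged counterpart, and causal pairs
    carry a (1 - r dt) factor); the default 0.0 is the continuum limit.
    """

    rates: tuple = (10.0,)
    R1_star: float = 2.0
    R2_star: float = 1.0
    alpha: float = 1.0
    tau: float = 0.02
    tau_eli: float = 1.0
    tau_dop: float = 1.0
    r_dop: float = 1.0 / 21.0
    lambda_rate: float = 0.01
    lambda_bar: float = 0.0025
    beta: float = 1.0e6
    a_sel: float = 0.7
    T_win: float = 1.0
    causal_scale: float = 1.0
    dt: float = 0.0

    @property
    def n_inputs(self) -> int:
        return len(self.rates)

    @property
    def r(self) -> np.ndarray:
        return np.asarray(self.rates, float)

    @classmethod
    def from_action_config(cls, config: ActionSelectionConfig,
                           rule: PlasticityRule,
                           causal_scale: float = 1.0) -> "AveragedParams":
        return cls(rates=tuple(config.rates), R1_star=config.R1_star,
                   R2_star=config.R2_star, alpha=rule.alpha, tau=rule.tau,
                   tau_eli=rule.tau_eli, r_dop=config.r_dop,
                   lambda_rate=rule.lambda_rate, beta=config.beta,
                   a_sel=config.a_sel, T_win=config.T_win,
                   causal_scale=causal_scale)

    @classmethod
    def from_value_config(cls, config: ValueEstimationConfig,
                          rule: PlasticityRule,
                          causal_scale: float = 1.0) -> "AveragedParams":
        return cls(rates=tuple(config.rates), R1_star=config.R1_star,
                   R2_star=config.R2_star, alpha=rule.alpha, tau=rule.tau,
                   tau_eli=rule.tau_eli, r_dop=config.r_dop,
                   lambda_rate=rule.lambda_rate, lambda_bar=config.lambda_bar,
                   beta=config.beta, T_win=config.T_win,
                   causal_scale=causal_scale)


@dataclass
class Equilibrium:
    """A critical point (or clipping accumulation point) with its stability."""

    location: np.ndarray
    kind: str          # 'analytic' | 'numeric' | 'boundary-clipped'
    stability: str     # 'attractor' | 'repeller' | 'saddle' |
                       # 'center-manifold' | 'undetermined'
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))
    label: str = ""

    def __post_init__(self) -> None:
        self.location = np.atleast_1d(np.asarray(self.location, float))


def _f_plus(kind: str, w, alpha: float):
    if kind == "additive":
        return np.ones_like(np.asarray(w, float))
    if kind == "symmetric":
        w = np.asarray(w, float)
        return w * (1.0 - w)
    raise ConfigurationError(f"no dopamine-independent f+ for rule {kind!r}")


def _delta_f(kind: str, w, alpha: float):
    # f+ - f- ; both rules share a common factor so delta_f = (1-alpha) f+
    return (1.0 - alpha) * _f_plus(kind, w, alpha)


def _eligibility_means(w, r, N, tau, a_scale, causal_scale, dt=0.0,
                       tau_eli=None):
    """(E+, E-)/tau_eli per synapse for input rates a_scale * r.

    With dt > 0 the continuum pairing windows (tau for both traces) are
    replaced by their exact discrete-grid counterparts: the pre-trace read at
    post times sums over lags k >= 0 (window dt/(1-e^{-dt/tau}) = tau + dt/2
    + O(dt^2)) while the post-trace read at pre times sums over k >= 1
    (window smaller by the factor e^{-dt/tau}); causal pairs acquire a
    (1 - q_i) factor from Bernoulli bin occupancy, and the eligibility decay
    itself contributes the ratio dt/(tau_eli (1 - e^{-dt/tau_eli})).
    """
    w = np.asarray(w, float)
    post = a_scale * float(w @ r) / N
    if dt > 0.0:
        tau_p = dt / (1.0 - math.exp(-dt / tau))
        tau_m = tau_p * math.exp(-dt / tau)
        eli_ratio = (dt / (1.0 - math.exp(-dt / tau_eli))) / tau_eli
        occ = 1.0 - a_scale * r * dt
    else:
        tau_p = tau_m = tau
        eli_ratio = 1.0
        occ = 1.0
    chance_p = a_scale * r * tau_p * post
    chance_m = a_scale * r * tau_m * post
    causal = a_scale * r * w * causal_scale * occ / N
    return (chance_p + causal) * eli_ratio, chance_m * eli_ratio


def _cort_bracket(w, e_plus, e_minus, alpha, d_sign):
    """Corticostriatal per-synapse update bracket for dopamine of sign d_sign."""
    w = np.asarray(w, float)
    if d_sign >= 0:
        return (1.0 - w) * e_plus - alpha * w * e_minus
    return alpha * w * e_plus - (1.0 - w) * e_minus


def action_drift(kind: str, w1, w2, params: AveragedParams, Ep=None):
    """Average weight drift (dw1/dt, dw2/dt) in the action-selection setting.

    Both channels' drifts are obtained by conditioning on which action is
    selected: channel j changes only on trials where A_j is chosen
    (probability Ep or 1-Ep), its inputs then run at a_sel * r, and the mean
    dopamine conditioned on A_j is R_j* - (R1* Ep + R2* (1 - Ep)).  For the
    additive and symmetric rules this reduces to the closed form
    (-1)^(j-1) (R1*-R2*) Ep (1-Ep) r_dop tau_dop tau_eli lambda/N *
    [a_sel^2 tau <w_j,r> delta_f(w_ij) r_i + a_sel f+(w_ij) w_ij r_i];
    the corticostriatal rule additionally branches on the sign of the
    conditional mean dopamine.
    """
    w1 = np.atleast_1d(np.asarray(w1, float))
    w2 = np.atleast_1d(np.asarray(w2, float))
    r = params.r
    N = params.n_inputs
    if Ep is None:
        Ep = expected_choice_probability(
            np.clip(w1, 0, 1), np.clip(w2, 0, 1), r, params.T_win, params.beta)
    scale = params.r_dop * params.tau_dop * params.tau_eli * params.lambda_rate
    out = []
    for j, w in enumerate((w1, w2)):
        p_sel = Ep if j == 0 else 1.0 - Ep
        r_star = params.R1_star if j == 0 else params.R2_star
        d_bar = r_star - (params.R1_star * Ep + params.R2_star * (1.0 - Ep))
        e_plus, e_minus = _eligibility_means(
            w, r, N, params.tau, params.a_sel, params.causal_scale,
            dt=params.dt, tau_eli=params.tau_eli)
        if kind == "corticostriatal":
            bracket = _cort_bracket(w, e_plus, e_minus, params.alpha,
                                    1.0 if d_bar >= 0 else -1.0)
        else:
            f_p = _f_plus(kind, w, params.alpha)
            f_m = params.alpha * f_p
            bracket = f_p * e_plus - f_m * e_minus
        out.append(scale * p_sel * d_bar * bracket)
    return out[0], out[1]


def _dopamine_halves(w, p, params: AveragedParams, tail_tol=1e-12):
    """(E[D+], E[D-]) of the value-setting pulse D = R*_A - n/T_win.

    n is the Poisson window count with mean T_win <w, r>/N and the action is
    A1 with probability p.  Used by the corticostriatal value drift, whose
    update branches on the dopamine sign.
    """
    nu = float(np.asarray(w, float) @ params.r) / params.n_inputs
    mu = params.T_win * max(nu, 0.0)
    hi = int(stats.poisson.ppf(1.0 - tail_tol, max(mu, 1e-12))) + 1
    k = np.arange(hi + 1)
    pmf = stats.poisson.pmf(k, mu)
    m_plus = 0.0
    mean = 0.0
    for r_star, p_a in ((params.R1_star, p), (params.R2_star, 1.0 - p)):
        d = r_star - k / params.T_win
        m_plus += p_a * float(pmf @ np.maximum(d, 0.0))
        mean += p_a * (r_star - mu / params.T_win)
    return m_plus, m_plus - mean


def value_drift(kind: str, w, p: float, params: AveragedParams):
    """Average drift (dw/dt, dp/dt) in the value-estimation setting.

    For the additive and symmetric rules the mean dopamine
    p R1* + (1-p) R2* - <w,r>/N factors out of the weight drift.  For the
    corticostriatal rule it cannot (the update branches on the dopamine
    sign), so the positive and negative parts of the pulse distribution are
    taken separately; with a long reward delay the eligibility is independent
    of the pulse, making this expectation semi-analytic (truncated Poisson
    sums), which keeps the field smooth enough for root finding.
    The p drift is the same for all three rules.
    """
    w = np.atleast_1d(np.asarray(w, float))
    r = params.r
    N = params.n_inputs
    nu = float(w @ r) / N
    scale = params.r_dop * params.tau_dop * params.tau_eli * params.lambda_rate
    e_plus, e_minus = _eligibility_means(
        w, r, N, params.tau, 1.0, params.causal_scale,
        dt=params.dt, tau_eli=params.tau_eli)
    if kind == "corticostriatal":
        m_plus, m_minus = _dopamine_halves(np.clip(w, 0, 1), np.clip(p, 0, 1),
                                           params)
        dw = scale * (
            m_plus * _cort_bracket(w, e_plus, e_minus, params.alpha, +1.0)
            - m_minus * _cort_bracket(w, e_plus, e_minus, params.alpha, -1.0)
        )
    else:
        d_bar = p * params.R1_star + (1.0 - p) * params.R2_star - nu
        f_p = _f_plus(kind, w, params.alpha)
        f_m = params.alpha * f_p
        dw = scale * d_bar * (f_p * e_plus - f_m * e_minus)
    dp = (params.lambda_bar * params.beta * params.r_dop * params.tau_dop
          * p * (1.0 - p)
          * (p * (params.R1_star - nu) - (1.0 - p) * (params.R2_star - nu)))
    return dw, dp


def alpha_threshold_action(a_sel: float, tau: float, rates) -> float:
    """Critical alpha above which the additive/symmetric action drift flips.

    alpha* = 1 + 1 / (a_sel * tau * sum_i r_i).  Below alpha* the averaged
    flow moves the more-rewarded channel's weights up and the other's down;
    above it the signs reverse and the task is unlearnable for these rules.
    """
    total = float(np.sum(np.asarray(rates, float)))
    if a_sel <= 0 or tau <= 0 or total <= 0:
        return math.inf
    return 1.0 + 1.0 / (a_sel * tau * total)


def alpha_threshold_value(tau: float, r1: float) -> float:
    """Critical alpha at which the reward-matching value equilibria
    (<w,r>/N = R*) lose transverse stability: alpha* = 1 + 1/(tau r1)."""
    if tau <= 0 or r1 <= 0:
        return math.inf
    return 1.0 + 1.0 / (tau * r1)


def stability_condition_value(kind: str, w, R_star: float,
                              params: AveragedParams) -> bool:
    """Transverse stability of a reward-matching equilibrium (value setting).

    The single nonzero eigenvalue at a point with <w,r>/N = R* is negative
    iff 0 < sum_i r_i^2 (tau N R* delta_f(w_i) + f+(w_i) w_i), evaluated for
    the additive or symmetric rule (the grouping reduces to
    tau (alpha - 1) < 1/r1 for the additive rule at N = 1).
    """
    w = np.atleast_1d(np.asarray(w, float))
    r = params.r
    N = params.n_inputs
    total = float(np.sum(
        r ** 2 * (params.tau * N * R_star * _delta_f(kind, w, params.alpha)
                  + _f_plus(kind, w, params.alpha) * w)
    ))
    return total > 0.0


def corticostriatal_action_fixed_points(params: AveragedParams):
    """Closed-form interior fixed points (W1*, W2*) of the corticostriatal
    action drift (equal-weight solution; exact for N = 1).

    With rho = a_sel * tau * sum(r) and cs the causal attenuation:
        W1* = (rho + 1) / (rho (1 + alpha) + 1)     [selected-channel form]
        W2* = rho / (rho (1 + alpha) + alpha * cs)  [unselected-channel form]
    assuming R1* > R2*; the roles swap otherwise.
    """
    rho = params.a_sel * params.tau * float(np.sum(params.r))
    cs = params.causal_scale
    w1 = (rho + cs) / (rho * (1.0 + params.alpha) + cs)
    w2 = rho / (rho * (1.0 + params.alpha) + params.alpha * cs)
    if params.R1_star >= params.R2_star:
        return w1, w2
    return w2, w1


def symmetric_w1_boundary_p(params: AveragedParams) -> float:
    """p-coordinate of the symmetric rule's w = 1 critical point in the
    value setting: p = (R2* - nu) / (R1* + R2* - 2 nu), nu = <1, r>/N."""
    nu = float(np.sum(params.r)) / params.n_inputs
    return (params.R2_star - nu) / (params.R1_star + params.R2_star - 2.0 * nu)


# --------------------------------------------------------------------------
# numerical machinery


def numerical_jacobian(f, x, box=None, h: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian; one-sided at box boundaries."""
    x = np.asarray(x, float)
    n = x.size
    J = np.zeros((n, n))
    lo = np.zeros(n) if box is None else np.asarray(box[0], float)
    hi = np.ones(n) if box is None else np.asarray(box[1], float)
    for j in range(n):
        hj_up = min(h, (hi[j] - x[j]))
        hj_dn = min(h, (x[j] - lo[j]))
        if hj_up <= 0 and hj_dn <= 0:
            continue
        xp = x.copy()
        xm = x.copy()
        xp[j] += hj_up
        xm[j] -= hj_dn
        J[:, j] = (np.asarray(f(xp)) - np.asarray(f(xm))) / (hj_up + hj_dn)
    return J


def classify_equilibrium(f, x, box=None, zero_tol_rel: float = 1e-5,
                         probe: float = 1e-3,
                         center_hint: bool = False) -> tuple[str, np.ndarray]:
    """Classify a critical point of the field f from its Jacobian.

    Eigenvalues with |Re| below zero_tol_rel * max|Re| (or an absolute floor)
    are treated as degenerate; those directions are resolved by probing the
    flow a distance ``probe`` along the eigenvector (inward only at box
    faces): flow toward the point on every available side counts as
    attracting, away as repelling, flow-through or negligible flow as a
    center direction.  ``center_hint`` marks points known analytically to sit
    on an equilibrium continuum / center manifold; they are always reported
    as 'center-manifold' (with the transverse eigenvalues still recorded).
    """
    x = np.asarray(x, float)
    n = x.size
    lo = np.zeros(n) if box is None else np.asarray(box[0], float)
    hi = np.ones(n) if box is None else np.asarray(box[1], float)
    J = numerical_jacobian(f, x, box=(lo, hi))
    eig, vec = np.linalg.eig(J)
    re = eig.real
    scale = max(np.max(np.abs(re)), 1e-300)
    ztol = max(zero_tol_rel * scale, 1e-12)
    if center_hint:
        return "center-manifold", eig

    signs = []
    for k in range(n):
        if abs(re[k]) > ztol:
            signs.append(-1 if re[k] < 0 else 1)
            continue
        v = np.real(vec[:, k])
        nv = np.linalg.norm(v)
        if nv == 0:
            signs.append(0)
            continue
        v = v / nv
        verdicts = []
        for s in (+1.0, -1.0):
            xp = x + s * probe * v
            if np.any(xp < lo - 1e-12) or np.any(xp > hi + 1e-12):
                continue
            g = float(np.asarray(f(xp)) @ v) * s  # >0: away, <0: toward
            if abs(g) < 1e-14:
                verdicts.append(0)
            else:
                verdicts.append(-1 if g < 0 else 1)
        if not verdicts or 0 in verdicts:
            signs.append(0)
        elif all(v_ == -1 for v_ in verdicts):
            signs.append(-1)
        elif all(v_ == 1 for v_ in verdicts):
            signs.append(1)
        else:
            signs.append(0)  # flow-through: genuine center direction

    if 0 in signs:
        return ("center-manifold" if all(s <= 0 for s in signs)
                else "undetermined"), eig
    if all(s < 0 for s in signs):
        return "attractor", eig
    if all(s > 0 for s in signs):
        return "repeller", eig
    return "saddle", eig


def _dedupe(points, radius):
    kept = []
    for p in points:
        if all(np.linalg.norm(p - q) > radius for q in kept):
            kept.append(p)
    return kept


def find_critical_points_numeric(drift, ndim: int, grid_density: int = 21,
                                 tol: float = 1e-8,
                                 dedupe_radius: float = 1e-4,
                                 box=None) -> list[Equilibrium]:
    """Multi-start root finding on the closed unit box, plus detection of
    boundary accumulation points created by clipping.

    drift : callable mapping an ndim vector to an ndim drift vector.
    Interior (and face) zeros of the field are returned as kind='numeric'.
    For 2-dimensional fields, points on the faces where the tangential flow
    vanishes attractively while the normal flow pushes outward — so the
    clipped stochastic flow accumulates there without the field being zero —
    are returned flagged kind='boundary-clipped'.
    """
    lo = np.zeros(ndim) if box is None else np.asarray(box[0], float)
    hi = np.ones(ndim) if box is None else np.asarray(box[1], float)
    axes = [np.linspace(lo[d], hi[d], grid_density) for d in range(ndim)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, ndim)

    def is_true_zero(x):
        """Zero of the field, judged against the local field scale.

        An absolute residual alone misclassifies regions where a prefactor
        (e.g. Ep(1-Ep) at near-deterministic choice) collapses the whole
        field; a genuine zero must be small relative to the drift a probe
        step away.
        """
        r0 = np.linalg.norm(np.asarray(drift(x), float))
        if r0 >= tol:
            return False
        if r0 < 1e-14:
            return True
        nbhd = 0.0
        for d in range(ndim):
            for s in (+1.0, -1.0):
                xp = x.copy()
                xp[d] = min(max(xp[d] + s * 1e-3, lo[d]), hi[d])
                nbhd = max(nbhd,
                           np.linalg.norm(np.asarray(drift(xp), float)))
        return r0 <= 0.02 * nbhd

    roots = []
    for x0 in grid:
        sol = optimize.root(lambda x: np.asarray(drift(x), float), x0,
                            method="hybr", tol=1e-12)
        x = np.clip(sol.x, lo, hi)
        if (np.all(sol.x >= lo - 1e-9) and np.all(sol.x <= hi + 1e-9)
                and is_true_zero(x)):
            roots.append(x)
    out = [Equilibrium(p, "numeric", "undetermined")
           for p in _dedupe(roots, dedupe_radius)]

    if ndim == 2:
        out.extend(_boundary_clipped_2d(drift, lo, hi, dedupe_radius,
                                        [e.location for e in out],
                                        is_true_zero))
    return out


def _boundary_clipped_2d(drift, lo, hi, dedupe_radius, known, is_true_zero):
    """Accumulation points of the clipped flow on the box boundary (2-D).

    A face point accumulates trajectories when the normal drift pushes
    outward while the tangential drift vanishes attractively; a corner
    accumulates when the flow just inside pushes toward the corner along
    every dimension.  True zeros of the field are never flagged.
    """
    found = []
    probe = 1e-3
    ntol = 1e-14

    def is_known(p):
        return any(np.linalg.norm(p - q) < 10 * dedupe_radius for q in known)

    # faces: fix dim d at a bound, scan the other dim for tangential zeros
    for d in range(2):
        t = 1 - d
        for bound, outward in ((lo[d], -1.0), (hi[d], +1.0)):
            def tang(s):
                x = np.empty(2)
                x[d] = bound
                x[t] = s
                return float(np.asarray(drift(x))[t])

            ss = np.linspace(lo[t] + 1e-6, hi[t] - 1e-6, 41)
            vals = [tang(s) for s in ss]
            for k in range(len(ss) - 1):
                if vals[k] == 0.0 or vals[k] * vals[k + 1] < 0:
                    s_root = optimize.brentq(tang, ss[k], ss[k + 1])
                    x = np.empty(2)
                    x[d] = bound
                    x[t] = s_root
                    fx = np.asarray(drift(x), float)
                    # outward normal push, attracting tangentially
                    d_tan = (tang(s_root + probe) - tang(s_root - probe)) / (
                        2 * probe) if lo[t] + probe < s_root < hi[t] - probe \
                        else -1.0
                    if (fx[d] * outward > ntol and d_tan < 0
                            and not is_known(x) and not is_true_zero(x)):
                        found.append(x)

    # corners: flow just inside pushes toward the corner in every dimension
    for c0 in (lo[0], hi[0]):
        for c1 in (lo[1], hi[1]):
            x = np.array([c0, c1])
            if is_known(x) or is_true_zero(x):
                continue
            ok = True
            strength = 0.0
            for d in range(2):
                outward = -1.0 if x[d] == lo[d] else 1.0
                fd = float(np.asarray(drift(x))[d]) * outward
                xp = x.copy()
                xp[d] -= outward * probe
                fd_in = float(np.asarray(drift(xp))[d]) * outward
                if fd < -ntol or fd_in < -ntol:  # flows away from the corner
                    ok = False
                    break
                strength = max(strength, fd, fd_in)
            if ok and strength > ntol:
                found.append(x)

    return [Equilibrium(p, "boundary-clipped", "undetermined")
            for p in _dedupe(found, dedupe_radius)]


def integrate_averaged(drift, init, horizon: float, rtol: float = 1e-8,
                       atol: float = 1e-10, max_step: float = math.inf,
                       n_samples: int = 200, box=None):
    """Integrate the averaged flow, keeping the state inside the unit box.

    The field is evaluated at the clipped state and outward components are
    zeroed on the boundary, which realizes the clipped flow whose
    accumulation points the stochastic system exhibits.  Returns
    (times, path) with path of shape (n_samples, ndim).
    """
    init = np.atleast_1d(np.asarray(init, float))
    n = init.size
    lo = np.zeros(n) if box is None else np.asarray(box[0], float)
    hi = np.ones(n) if box is None else np.asarray(box[1], float)

    def masked(t, x):
        xc = np.clip(x, lo, hi)
        f = np.asarray(drift(xc), float)
        f = np.where((xc <= lo) & (f < 0), 0.0, f)
        f = np.where((xc >= hi) & (f > 0), 0.0, f)
        return f

    ts = np.linspace(0.0, horizon, n_samples)
    sol = solve_ivp(masked, (0.0, horizon), init, t_eval=ts, rtol=rtol,
                    atol=atol, max_step=max_step, method="RK45")
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol.t, np.clip(sol.y.T, lo, hi)


# --------------------------------------------------------------------------
# equilibrium catalogue


def _action_field(kind, params, N):
    def f(x):
        w1, w2 = x[:N], x[N:]
        d1, d2 = action_drift(kind, w1, w2, params)
        return np.concatenate([np.atleast_1d(d1), np.atleast_1d(d2)])
    return f


def _value_field(kind, params, N):
    def f(x):
        dw, dp = value_drift(kind, x[:N], x[N], params)
        return np.concatenate([np.atleast_1d(dw), [dp]])
    return f


def enumerate_equilibria(setting: str, kind: str,
                         params: AveragedParams) -> list[Equilibrium]:
    """All analytic equilibria of the averaged dynamics, classified.

    setting is 'action' or 'value'.  Locations are stacked state vectors:
    (w1_1..w1_N, w2_1..w2_N) for the action setting and (w_1..w_N, p) for the
    value setting.  Reward-matching hyperplane points in the value setting
    (which carry a center manifold in p) are reported at the equal-weight
    representative and marked 'center-manifold'.  The corticostriatal
    value-setting interior points have no closed form and are found by
    ``find_critical_points_numeric`` instead.
    """
    N = params.n_inputs
    pts: list[tuple[np.ndarray, str, bool]] = []  # (location, label, cm hint)
    if setting == "action":
        zeros = np.zeros(N)
        ones = np.ones(N)
        pts.append((np.concatenate([zeros, zeros]), "origin", False))
        if kind == "symmetric":
            pts.append((np.concatenate([ones, zeros]), "w1=1,w2=0", False))
            pts.append((np.concatenate([zeros, ones]), "w1=0,w2=1", False))
            pts.append((np.concatenate([ones, ones]), "w1=1,w2=1", False))
        if kind == "corticostriatal":
            w1s, w2s = corticostriatal_action_fixed_points(params)
            pts.append((np.concatenate([np.full(N, w1s), np.full(N, w2s)]),
                        "(w1*,w2*)", False))
            pts.append((np.concatenate([zeros, np.full(N, w2s)]),
                        "(0,w2*)", False))
            pts.append((np.concatenate([np.full(N, w1s), zeros]),
                        "(w1*,0)", False))
        field_fn = _action_field(kind, params, N)
    elif setting == "value":
        nu1 = float(np.sum(params.r)) / N  # <1, r>/N
        p_mid = params.R2_star / (params.R1_star + params.R2_star)
        for p0 in (0.0, 1.0, p_mid):
            pts.append((np.concatenate([np.zeros(N), [p0]]),
                        f"w=0,p={p0:g}", False))
        if kind != "corticostriatal":
            # reward-matching hyperplanes (equal-weight representative)
            for p0, r_star in ((0.0, params.R2_star), (1.0, params.R1_star)):
                c = N * r_star / float(np.sum(params.r))
                if 0.0 <= c <= 1.0:
                    pts.append((np.concatenate([np.full(N, c), [p0]]),
                                f"<w,r>/N={r_star:g},p={p0:g}", True))
        if kind == "symmetric":
            p_b = symmetric_w1_boundary_p(params)
            for p0 in (0.0, 1.0, p_b):
                if 0.0 <= p0 <= 1.0:
                    pts.append((np.concatenate([np.ones(N), [p0]]),
                                f"w=1,p={p0:g}", False))
        field_fn = _value_field(kind, params, N)
    else:
        raise ConfigurationError("setting must be 'action' or 'value'")

    out = []
    for loc, label, hint in pts:
        stab, eig = classify_equilibrium(field_fn, loc, center_hint=hint)
        out.append(Equilibrium(loc, "analytic", stab, eig, label))
    return out


# --------------------------------------------------------------------------
# Monte-Carlo oracles (single-cycle expectations of the stochastic system)


def monte_carlo_action_drift(kind: str, w1, w2, config: ActionSelectionConfig,
                             rule: PlasticityRule, grid=None, seed: int = 0,
                             n_trials: int = 10_000, tail_s: float = 8.0):
    """Empirical E[dw/dt] and its standard error from single-cycle trials.

    Returns ((d1, d2), (se1, se2)) per synapse, on the same per-unit-time
    scale as ``action_drift`` (the per-cycle change times r_dop).
    """
    from .action import single_cycle_weight_change_action
    from .core import SimGrid

    grid = grid or SimGrid()
    N = config.n_inputs
    w0 = np.stack([np.broadcast_to(np.asarray(w1, float), (N,)),
                   np.broadcast_to(np.asarray(w2, float), (N,))])
    dw = single_cycle_weight_change_action(
        config, rule, w0, grid=grid, seed=seed, n_trials=n_trials,
        tail_s=tail_s)
    mean = dw.mean(axis=0) * config.r_dop
    se = dw.std(axis=0, ddof=1) / math.sqrt(n_trials) * config.r_dop
    return (mean[0], mean[1]), (se[0], se[1])


def monte_carlo_value_drift(kind: str, w, p: float,
                            config: ValueEstimationConfig,
                            rule: PlasticityRule, grid=None, seed: int = 0,
                            n_trials: int = 10_000, tail_s: float = 8.0):
    """Empirical E[dw/dt] and standard error in the value setting (p frozen)."""
    from .core import SimGrid
    from .value import single_cycle_weight_change_value

    grid = grid or SimGrid()
    dw = single_cycle_weight_change_value(
        config, rule, np.broadcast_to(np.asarray(w, float),
                                      (config.n_inputs,)),
        p_frozen=p, grid=grid, seed=seed, n_trials=n_trials, tail_s=tail_s)
    mean = dw.mean(axis=0) * config.r_dop
    se = dw.std(axis=0, ddof=1) / math.sqrt(n_trials) * config.r_dop
    return mean, se
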