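"""Figure-level experiment pipelines.

Each pipeline runs one standard experiment design at configurable scale —
weight clouds over phase portraits, contingency-switching performance, the
reward-delay sweep with and without sustained activity, and single-pulse
weight-drift curves against the averaged predictions — and returns tidy
DataFrames (optionally written as CSV next to a JSON manifest, with optional
PNG panels).  Identical spec + seed gives byte-identical outputs.

Default scales are 100 trials for trajectory
experiments and 10^4 samples for single-pulse drift curves; ``fast=True``
reduces these to 20 and 10^3 for quick runs.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .action import ActionSelectionConfig, run_action_selection
from .core import ConfigurationError, PlasticityRule, SimGrid
from .meanfield import (
    AveragedParams,
    action_drift,
    enumerate_equilibria,
    find_critical_points_numeric,
    integrate_averaged,
    value_drift,
)
from .value import (
    ValueEstimationConfig,
    run_value_estimation,
    single_cycle_weight_change_value,
)

__all__ = [
    "ExperimentSpec",
    "phase_cloud",
    "contingency_experiment",
    "delay_sweep",
    "single_pulse_drift",
]


@dataclass(frozen=True)
class ExperimentSpec:
    """Scale and sweep parameters shared by the experiment pipelines."""

    name: str = "experiment"
    setting: str = "action"
    rules: tuple = ("additive", "symmetric", "corticostriatal")
    alphas: tuple = (1.0,)
    n_trials: int = 100
    n_steps: int = 1000
    seed: int = 0
    sweep: tuple = ()          # T_del grid, epsilon grid, or winit grid
    sustain: tuple = (True,)
    switch_period: int | None = None
    out_dir: str | None = None
    fast: bool = False

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if self.setting not in ("action", "value"):
            raise ConfigurationError("setting must be 'action' or 'value'")

    def scaled(self, heavy: bool = False) -> "ExperimentSpec":
        """Apply the --fast reduction (20 trials, or 10^3 for pulse curves)."""
        if not self.fast:
            return self
        n = 1000 if heavy else 20
        return dataclasses.replace(self, n_trials=min(self.n_trials, n))


def _default_rule(kind: str, alpha: float, setting: str) -> PlasticityRule:
    lam = 0.01 if setting == "action" else 0.001
    return PlasticityRule(kind, alpha=alpha, lambda_rate=lam)


def _write(spec: ExperimentSpec, tables: dict[str, pd.DataFrame]) -> None:
    if spec.out_dir is None:
        return
    os.makedirs(spec.out_dir, exist_ok=True)
    manifest = dataclasses.asdict(spec)
    manifest["package_version"] = __version__
    manifest["tables"] = sorted(tables)
    for key, df in tables.items():
        df.to_csv(os.path.join(spec.out_dir, f"{spec.name}_{key}.csv"),
                  index=False, float_format="%.10g")
    with open(os.path.join(spec.out_dir, f"{spec.name}_manifest.json"),
              "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def _snapshot_steps(n_steps: int, k: int = 20) -> np.ndarray:
    if n_steps == 0:
        return np.array([], int)
    return np.unique(np.linspace(0, n_steps - 1, min(k, n_steps)).astype(int))


def phase_cloud(spec: ExperimentSpec, grid: SimGrid = SimGrid()) -> dict:
    """Weight clouds over time with the averaged path and equilibria.

    For each (rule, alpha): n_trials stochastic trajectories from the default
    initial point (w = 0.5, and p = 0.5 in the value setting), the integrated
    averaged trajectory from the same point, and the catalogue of analytic
    plus numerically found critical points (boundary accumulation points from
    clipping flagged separately).
    """
    spec = spec.scaled()
    snap = _snapshot_steps(spec.n_steps)
    cloud_rows, path_rows, eq_rows = [], [], []
    for kind in spec.rules:
        for alpha in spec.alphas:
            rule = _default_rule(kind, alpha, spec.setting)
            if spec.setting == "action":
                cfg = ActionSelectionConfig(n_steps=max(spec.n_steps, 1),
                                            n_trials=spec.n_trials)
                params = AveragedParams.from_action_config(cfg, rule)
                if spec.n_steps == 0:  # point mass at the initial condition
                    for tr in range(spec.n_trials):
                        cloud_rows.append((kind, alpha, tr, 0, cfg.w_init,
                                           cfg.w_init, np.nan))
                if spec.n_steps > 0:
                    traj = run_action_selection(cfg, rule, grid,
                                                seed=spec.seed)
                    for s in snap:
                        for tr in range(spec.n_trials):
                            cloud_rows.append(
                                (kind, alpha, tr, int(s),
                                 traj.weights[tr, s, 0, 0],
                                 traj.weights[tr, s, 1, 0], np.nan))

                def field(x, k=kind, p=params):
                    d1, d2 = action_drift(k, x[:1], x[1:], p)
                    return np.concatenate([d1, d2])

                init = np.array([cfg.w_init, cfg.w_init])
            else:
                cfg = ValueEstimationConfig(n_steps=max(spec.n_steps, 1),
                                            n_trials=spec.n_trials)
                params = AveragedParams.from_value_config(cfg, rule)
                if spec.n_steps == 0:
                    for tr in range(spec.n_trials):
                        cloud_rows.append((kind, alpha, tr, 0, cfg.w_init,
                                           np.nan, cfg.p_init))
                if spec.n_steps > 0:
                    traj = run_value_estimation(cfg, rule, grid,
                                                seed=spec.seed)
                    for s in snap:
                        for tr in range(spec.n_trials):
                            cloud_rows.append(
                                (kind, alpha, tr, int(s),
                                 traj.weights[tr, s, 0], np.nan,
                                 traj.p[tr, s]))

                def field(x, k=kind, p=params):
                    dw, dp = value_drift(k, x[:1], x[1], p)
                    return np.concatenate([np.atleast_1d(dw), [dp]])

                init = np.array([cfg.w_init, cfg.p_init])

            horizon = max(spec.n_steps, 1) / cfg.r_dop
            ts, path = integrate_averaged(field, init, horizon)
            for t, x in zip(ts, path):
                path_rows.append((kind, alpha, t, x[0], x[1]))
            eqs = enumerate_equilibria(spec.setting, kind, params)
            eqs += [e for e in find_critical_points_numeric(
                        field, 2, grid_density=9)
                    if e.kind == "boundary-clipped"
                    or all(np.linalg.norm(e.location - q.location) > 1e-3
                           for q in eqs)]
            for e in eqs:
                eq_rows.append((kind, alpha, e.location[0], e.location[1],
                                e.kind, e.stability, e.label))

    xcol = "w1" if spec.setting == "action" else "w"
    ycol = "w2" if spec.setting == "action" else "p"
    tables = {
        "cloud": pd.DataFrame(
            cloud_rows,
            columns=["rule", "alpha", "trial", "step", "w1", "w2", "p"]),
        "averaged_path": pd.DataFrame(
            path_rows, columns=["rule", "alpha", "time_s", xcol, ycol]),
        "equilibria": pd.DataFrame(
            eq_rows,
            columns=["rule", "alpha", xcol, ycol, "kind", "stability",
                     "label"]),
    }
    _write(spec, tables)
    return tables


def contingency_experiment(spec: ExperimentSpec,
                           grid: SimGrid = SimGrid()) -> dict:
    """Contingency switching: the higher reward swaps actions periodically.

    Emits per-step mean and sd of the weights and the proportion of trials
    selecting A1, across trials, with the switch schedule recorded.
    """
    spec = spec.scaled()
    if spec.switch_period is None:
        raise ConfigurationError("contingency_experiment needs switch_period")
    agg_rows = []
    raw = []
    for kind in spec.rules:
        for alpha in spec.alphas:
            rule = _default_rule(kind, alpha, spec.setting)
            if spec.setting == "action":
                cfg = ActionSelectionConfig(
                    n_steps=spec.n_steps, n_trials=spec.n_trials,
                    switch_period=spec.switch_period)
                traj = run_action_selection(cfg, rule, grid, seed=spec.seed)
                w1 = traj.weights[:, :, 0, :].mean(-1)
                w2 = traj.weights[:, :, 1, :].mean(-1)
                p_like = np.full_like(w1, np.nan)
            else:
                cfg = ValueEstimationConfig(
                    n_steps=spec.n_steps, n_trials=spec.n_trials,
                    switch_period=spec.switch_period)
                # contingency runs need a slower weight / faster preference
                # learning-rate balance to track the switches
                rule = PlasticityRule(kind, alpha=alpha, lambda_rate=0.00015,
                                      tau=rule.tau, tau_eli=rule.tau_eli)
                cfg = dataclasses.replace(cfg, lambda_bar=0.005)
                traj = run_value_estimation(cfg, rule, grid, seed=spec.seed)
                w1 = traj.weights.mean(-1)
                w2 = np.full_like(w1, np.nan)
                p_like = traj.p
            a1 = (traj.actions == 0).astype(float)
            for s in range(spec.n_steps):
                agg_rows.append((
                    kind, alpha, s,
                    (s // spec.switch_period) % 2,
                    w1[:, s].mean(), w1[:, s].std(),
                    np.nanmean(w2[:, s]), np.nanstd(w2[:, s]),
                    a1[:, s].mean(),
                    np.nanmean(p_like[:, s]),
                ))
            df = pd.DataFrame({
                "rule": kind, "alpha": alpha,
                "trial": np.repeat(np.arange(spec.n_trials), spec.n_steps),
                "step": np.tile(np.arange(spec.n_steps), spec.n_trials),
                "chose_A1": a1.ravel(),
                "w1": w1.ravel(),
            })
            raw.append(df)
    tables = {
        "aggregate": pd.DataFrame(
            agg_rows,
            columns=["rule", "alpha", "step", "contingency", "w1_mean",
                     "w1_sd", "w2_mean", "w2_sd", "prop_A1", "p_mean"]),
        "raw": pd.concat(raw, ignore_index=True),
    }
    _write(spec, tables)
    return tables


def delay_sweep(spec: ExperimentSpec, grid: SimGrid = SimGrid()) -> dict:
    """Final-weight distributions vs the reward delay T_del.

    For each T_del in ``spec.sweep`` and each sustained-activity flag in
    ``spec.sustain``: mean and sd over trials of the final channel weights
    after n_steps (action setting only).
    """
    spec = spec.scaled()
    if not spec.sweep:
        raise ConfigurationError("delay_sweep needs a T_del grid in spec.sweep")
    rows, raw = [], []
    for kind in spec.rules:
        for alpha in spec.alphas:
            rule = _default_rule(kind, alpha, "action")
            for t_del in spec.sweep:
                for sus in spec.sustain:
                    cfg = ActionSelectionConfig(
                        T_del=float(t_del), sustain=bool(sus),
                        n_steps=spec.n_steps, n_trials=spec.n_trials)
                    traj = run_action_selection(cfg, rule, grid,
                                                seed=spec.seed)
                    w1 = traj.final_weights[:, 0, :].mean(-1)
                    w2 = traj.final_weights[:, 1, :].mean(-1)
                    rows.append((kind, alpha, float(t_del), bool(sus),
                                 w1.mean(), w1.std(), w2.mean(), w2.std(),
                                 np.abs(w1 - w2).mean()))
                    raw.append(pd.DataFrame({
                        "rule": kind, "alpha": alpha, "T_del": float(t_del),
                        "sustain": bool(sus),
                        "trial": np.arange(spec.n_trials),
                        "w1_final": w1, "w2_final": w2,
                    }))
    tables = {
        "aggregate": pd.DataFrame(
            rows, columns=["rule", "alpha", "T_del", "sustain", "w1_mean",
                           "w1_sd", "w2_mean", "w2_sd", "gap_mean"]),
        "raw": pd.concat(raw, ignore_index=True),
    }
    _write(spec, tables)
    return tables


def single_pulse_drift(spec: ExperimentSpec, grid: SimGrid = SimGrid(),
                       t_dels: tuple = (3.0,), winit_grid=None,
                       epsilons: tuple = (0.001,)) -> dict:
    """E[dw] after a single dopamine release vs the initial weight.

    Value-estimation setting with the preference frozen at p = 0.5.  For each
    initial weight on the grid and each (rule, T_del, epsilon) condition:
    mean and sd of the weight change over n_trials single-cycle runs, plus
    the averaged-model prediction (per-cycle drift, evaluated with the
    exact-discrete eligibility windows and the causal attenuation
    e^{-eps/tau} of the simulated grid).
    """
    spec = spec.scaled(heavy=True)
    if winit_grid is None:
        winit_grid = np.round(np.linspace(0.1, 0.9, 9), 3)
    rows = []
    for kind in spec.rules:
        for alpha in spec.alphas:
            rule = _default_rule(kind, alpha, "value")
            for eps in epsilons:
                g = SimGrid(dt=grid.dt, epsilon=float(eps))
                for t_del in t_dels:
                    cfg = ValueEstimationConfig(T_del=float(t_del), n_steps=1,
                                                n_trials=1)
                    params = AveragedParams.from_value_config(
                        cfg, rule,
                        causal_scale=math.exp(-g.epsilon / rule.tau))
                    params = dataclasses.replace(params, dt=g.dt)
                    for k, w0 in enumerate(winit_grid):
                        dw = single_cycle_weight_change_value(
                            cfg, rule, [float(w0)], p_frozen=0.5, grid=g,
                            seed=spec.seed + 1000 * k,
                            n_trials=spec.n_trials)
                        pred = value_drift(kind, [float(w0)], 0.5,
                                           params)[0][0] / cfg.r_dop
                        rows.append((kind, alpha, float(t_del), float(eps),
                                     float(w0), dw.mean(), dw.std(),
                                     dw.std() / math.sqrt(spec.n_trials),
                                     pred))
    tables = {
        "drift": pd.DataFrame(
            rows, columns=["rule", "alpha", "T_del", "epsilon", "w_init",
                           "dw_mean", "dw_sd", "dw_se", "dw_pred"]),
    }
    _write(spec, tables)
    return tables
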