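"""Trajectory containers for task runs, with tidy-frame export."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ActionTrajectory:
    """Per-step record of an action-selection run (all trials).

    Arrays are indexed (trial, step, ...).  ``weights`` has shape
    (trials, steps, 2, N); ``actions`` holds 0 for A1 and 1 for A2;
    ``rewards`` is the reward actually received; ``pulses`` the dopamine
    increment (the reward-prediction error); ``expected_p`` the model's
    expected probability of choosing A1 at the pulse time.
    """

    time_s: np.ndarray
    weights: np.ndarray
    counts: np.ndarray
    actions: np.ndarray
    rewards: np.ndarray
    pulses: np.ndarray
    expected_p: np.ndarray
    final_weights: np.ndarray
    clip_counts: np.ndarray
    seed: int

    @property
    def n_trials(self) -> int:
        return self.weights.shape[0]

    @property
    def n_steps(self) -> int:
        return self.weights.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: one row per (trial, step, channel, synapse)."""
        nt, ns, nc, n = self.weights.shape
        trial, step, ch, syn = np.meshgrid(
            np.arange(nt), np.arange(ns), np.arange(nc), np.arange(n),
            indexing="ij",
        )
        df = pd.DataFrame(
            {
                "trial": trial.ravel(),
                "step": step.ravel(),
                "time_s": self.time_s[step.ravel()],
                "channel": ch.ravel() + 1,
                "synapse": syn.ravel(),
                "weight": self.weights.ravel(),
            }
        )
        per_step = pd.DataFrame(
            {
                "trial": np.repeat(np.arange(nt), ns),
                "step": np.tile(np.arange(ns), nt),
                "action": np.where(self.actions.ravel() == 0, "A1", "A2"),
                "reward": self.rewards.ravel(),
                "dopamine": self.pulses.ravel(),
                "expected_p": self.expected_p.ravel(),
            }
        )
        return df.merge(per_step, on=["trial", "step"])


@dataclass
class ValueTrajectory:
    """Per-step record of a value-estimation run (all trials).

    ``weights`` has shape (trials, steps, N); ``p`` is the choice probability
    derived from the preference difference at each selection; ``value_est``
    the windowed postsynaptic rate (the value estimate, reward units).
    """

    time_s: np.ndarray
    weights: np.ndarray
    p: np.ndarray
    value_est: np.ndarray
    actions: np.ndarray
    rewards: np.ndarray
    pulses: np.ndarray
    final_weights: np.ndarray
    final_r_diff: np.ndarray
    clip_counts: np.ndarray
    seed: int

    @property
    def n_trials(self) -> int:
        return self.weights.shape[0]

    @property
    def n_steps(self) -> int:
        return self.weights.shape[1]

    def to_frame(self) -> pd.DataFrame:
        nt, ns, n = self.weights.shape
        trial, step, syn = np.meshgrid(
            np.arange(nt), np.arange(ns), np.arange(n), indexing="ij"
        )
        df = pd.DataFrame(
            {
                "trial": trial.ravel(),
                "step": step.ravel(),
                "time_s": self.time_s[step.ravel()],
                "synapse": syn.ravel(),
                "weight": self.weights.ravel(),
            }
        )
        per_step = pd.DataFrame(
            {
                "trial": np.repeat(np.arange(nt), ns),
                "step": np.tile(np.arange(ns), nt),
                "p": self.p.ravel(),
                "action": np.where(self.actions.ravel() == 0, "A1", "A2"),
                "reward": self.rewards.ravel(),
                "dopamine": self.pulses.ravel(),
                "value_estimate": self.value_est.ravel(),
            }
        )
        return df.merge(per_step, on=["trial", "step"])
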