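"""Episodic classification environment over a feature table.

Each state is one sample's feature vector; the agent's action is its class
prediction; the reward is +1 for a correct prediction and −1 otherwise; an
episode is one full traversal of the table.  The reset/step contract
mirrors standard episodic-environment APIs (gym-style) so third-party
agents can plug in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .table import SampleTable

__all__ = ["ClassificationEnv", "episode_accuracy"]


class ClassificationEnv:
    """One-sample-per-step environment with ±1 prediction rewards.

    Parameters
    ----------
    table
        Labeled sample table; its feature vectors are the states.
    shuffle
        Draw a fresh traversal permutation at every reset (decorrelates
        replay without changing episode semantics).
    seed
        Seeds the permutation stream.
    """

    def __init__(self, table: SampleTable, shuffle: bool = True, seed: int = 0):
        if len(table) == 0:
            raise ValueError("empty table")
        self._x = table.features
        if not np.isfinite(self._x).all():
            raise ValueError("feature vectors must be finite")
        self._y = table.labels
        self.n_actions = int(self._y.max()) + 1
        self.n_features = self._x.shape[1]
        self.shuffle = shuffle
        self._rng = np.random.default_rng(seed)
        self._order = np.arange(len(table))
        self._cursor = 0
        self._done = True  # must reset before stepping

    def __len__(self) -> int:
        return len(self._y)

    @property
    def done(self) -> bool:
        return self._done

    @property
    def current_label(self) -> int:
        return int(self._y[self._order[self._cursor]])

    def reset(self, seed: int | None = None) -> np.ndarray:
        """Start a new episode; returns the first sample's feature vector."""
        if seed is not None:
            self._rng = np.random.default_rng(seed)
        self._order = (
            self._rng.permutation(len(self._y)) if self.shuffle else np.arange(len(self._y))
        )
        self._cursor = 0
        self._done = False
        return self._x[self._order[0]].copy()

    def step(self, action: int) -> tuple[np.ndarray, float, bool]:
        """Advance one sample; returns (next state, reward, done).

        The reward is +1 iff ``action`` equals the current sample's label,
        −1 otherwise.  The cursor advances regardless of the action taken —
        the transition depends only on the traversal position.  The terminal
        "next state" is a zero vector; its value is never bootstrapped
        because TD targets reduce to the reward at terminals.
        """
        if self._done:
            raise RuntimeError("step() called on a finished episode; reset() first")
        if not 0 <= action < self.n_actions:
            raise ValueError(f"action {action} outside [0, {self.n_actions})")
        reward = 1.0 if action == self.current_label else -1.0
        self._cursor += 1
        self._done = self._cursor >= len(self._y)
        if self._done:
            next_state = np.zeros(self.n_features)
        else:
            next_state = self._x[self._order[self._cursor]].copy()
        return next_state, reward, self._done


def episode_accuracy(rewards: list[float] | np.ndarray) -> float:
    """Fraction of correct predictions from a ±1 reward sequence.

    With c correct among n, Σreward = 2c − n, so accuracy = (Σr + n) / 2n.
    """
    r = np.asarray(rewards, dtype=float)
    if r.size == 0:
        raise ValueError("empty reward sequence")
    return float((r.sum() + r.size) / (2 * r.size))
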