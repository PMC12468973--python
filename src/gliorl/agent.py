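"""Dueling deep Q-network agent family with context-attention fusion.

The agent learns classification as an episodic reward task: states are
feature vectors, actions are class predictions, and Q-values are regressed
against TD targets from a periodically synced target network, with uniform
experience replay and an ε-greedy behaviour policy.

Six architecture variants form the ablation lattice:

``dqn``
    Plain Q head on the shared trunk.
``double``
    Same network; TD targets evaluate the online argmax action under the
    target network (decoupled selection/evaluation).
``dueling`` / ``dueling_double``
    Separate state-value V(s) and advantage A(s,·) streams fused as
    Q = V + (A − mean A).
``dueling_double_attn``
    Dueling double with an elementwise sigmoid gate on the trunk
    representation (additive attention) feeding both streams.
``context_attn``
    The full model: a learnable scalar attention weight w(s) ∈ (0,1) forms
    a convex combination Q = w·V + (1−w)·(A − mean A), letting the network
    modulate the value/advantage balance per state.

The networks are small multilayer perceptrons implemented directly in numpy
(forward, analytic backward, Adam), sized for radiomics feature vectors of
at most a few hundred dimensions.
"""

from __future__ import annotations

import hashlib
import json
from collections import deque
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .env import ClassificationEnv, episode_accuracy
from .table import SampleTable

__all__ = [
    "VARIANTS",
    "AgentConfig",
    "Transition",
    "ReplayBuffer",
    "QNetwork",
    "EpisodeLog",
    "DQNPolicy",
    "fuse_q_values",
    "dueling_q",
    "td_target",
    "epsilon_greedy",
    "decay_epsilon",
    "replay_update",
    "sync_target",
    "train",
    "predict",
]

VARIANTS = ("dqn", "double", "dueling", "dueling_double", "dueling_double_attn", "context_attn")
_DUELING = {"dueling", "dueling_double", "dueling_double_attn", "context_attn"}
_DOUBLE = {"double", "dueling_double", "dueling_double_attn", "context_attn"}


@dataclass
class AgentConfig:
    """Training hyperparameters of the Q-learning agent.

    Defaults are the configuration found to perform best for radiomics
    classification: γ=0.99, ε decaying from 0.5 to 0.01 by factor 0.995,
    50 episodes, batch size 16, Adam with learning rate 0.001, MSE loss.
    ``epsilon_decay_mode`` applies the decay once per environment step
    (default — with 50 episodes a per-episode decay never approaches the
    0.01 floor, which would make that parameter vacuous) or once per
    episode.
    """

    gamma: float = 0.99
    epsilon: float = 0.5
    epsilon_min: float = 0.01
    epsilon_decay: float = 0.995
    episodes: int = 50
    batch_size: int = 16
    learning_rate: float = 0.001
    variant: str = "context_attn"
    target_update: int = 100
    replay_capacity: int = 10_000
    hidden: tuple[int, int] = (64, 64)
    epsilon_decay_mode: str = "step"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.gamma <= 1:
            raise ValueError("gamma must be in [0, 1]")
        if not 0 < self.epsilon_decay <= 1:
            raise ValueError("epsilon decay must be in (0, 1]")
        if self.epsilon_min > self.epsilon:
            raise ValueError("epsilon_min must not exceed initial epsilon")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.epsilon_decay_mode not in ("step", "episode"):
            raise ValueError("epsilon_decay_mode must be 'step' or 'episode'")


@dataclass(frozen=True)
class Transition:
    """One replay record (s, a, r, s', terminal)."""

    state: np.ndarray
    action: int
    reward: float
    next_state: np.ndarray
    terminal: bool


class ReplayBuffer:
    """FIFO transition store with uniform without-replacement batch sampling."""

    def __init__(self, capacity: int):
        self._buf: deque[Transition] = deque(maxlen=capacity)
        self.capacity = capacity

    def push(self, t: Transition) -> None:
        self._buf.append(t)

    def __len__(self) -> int:
        return len(self._buf)

    def sample(self, batch_size: int, rng: np.random.Generator) -> list[Transition]:
        idx = rng.choice(len(self._buf), size=min(batch_size, len(self._buf)), replace=False)
        return [self._buf[i] for i in idx]


# -- fusion arithmetic (scalar reference forms) ----------------------------


def dueling_q(value: float, advantages: np.ndarray) -> np.ndarray:
    """Q_a = V + A_a − mean(A): the standard dueling stream fusion."""
    a = np.asarray(advantages, dtype=float)
    return value + a - a.mean()


def fuse_q_values(value: float, advantages: np.ndarray, weight: float) -> np.ndarray:
    """Convex value/advantage fusion Q_a = w·V + (1−w)·(A_a − mean A).

    ``weight`` must lie strictly inside (0,1) — it is produced by a sigmoid
    attention head, so the boundary values are unreachable.
    """
    if not 0 < weight < 1:
        raise ValueError("fusion weight must be in the open interval (0, 1)")
    a = np.asarray(advantages, dtype=float)
    return weight * value + (1 - weight) * (a - a.mean())


# -- network ---------------------------------------------------------------


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class QNetwork:
    """Two-hidden-layer MLP with variant-dependent output heads.

    Trunk: two rectified layers (default width 64).  Heads by variant:
    a plain Q head; or value + advantage streams, optionally behind an
    elementwise sigmoid gate on the trunk output, optionally fused by the
    scalar context-attention weight.
    """

    def __init__(self, n_features: int, n_actions: int, variant: str, hidden=(64, 64), seed: int = 0):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        self.variant = variant
        self.n_features = n_features
        self.n_actions = n_actions
        self.hidden = tuple(hidden)
        rng = np.random.default_rng(seed)
        h1, h2 = self.hidden
        p: dict[str, np.ndarray] = {}

        def init(fan_in: int, shape) -> np.ndarray:
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        p["W1"], p["b1"] = init(n_features, (n_features, h1)), np.zeros(h1)
        p["W2"], p["b2"] = init(h1, (h1, h2)), np.zeros(h2)
        if self.gated:
            p["Wg"], p["bg"] = init(h2, (h2, h2)), np.zeros(h2)
        if self.dueling:
            p["Wv"], p["bv"] = init(h2, (h2, 1)), np.zeros(1)
            p["Wa"], p["ba"] = init(h2, (h2, n_actions)), np.zeros(n_actions)
        else:
            p["Wq"], p["bq"] = init(h2, (h2, n_actions)), np.zeros(n_actions)
        if self.contextual:
            p["Ww"], p["bw"] = init(h2, (h2, 1)), np.zeros(1)
        self.params = p

    @property
    def dueling(self) -> bool:
        return self.variant in _DUELING

    @property
    def gated(self) -> bool:
        return self.variant == "dueling_double_attn"

    @property
    def contextual(self) -> bool:
        return self.variant == "context_attn"

    # forward --------------------------------------------------------------

    def forward(self, x: np.ndarray, detail: bool = False):
        """Batch Q-values; with ``detail`` also the cache and stream values."""
        p = self.params
        x = np.atleast_2d(np.asarray(x, dtype=float))
        z1 = x @ p["W1"] + p["b1"]
        h1 = _relu(z1)
        z2 = h1 @ p["W2"] + p["b2"]
        h2 = _relu(z2)
        cache = {"x": x, "z1": z1, "h1": h1, "z2": z2, "h2": h2}
        rep = h2
        if self.gated:
            zg = h2 @ p["Wg"] + p["bg"]
            g = _sigmoid(zg)
            rep = h2 * g
            cache.update(g=g)
        cache["rep"] = rep
        if not self.dueling:
            q = rep @ p["Wq"] + p["bq"]
            cache.update(v=None, a=None, w=None)
        else:
            v = rep @ p["Wv"] + p["bv"]  # (N, 1)
            a = rep @ p["Wa"] + p["ba"]  # (N, K)
            c = a - a.mean(axis=1, keepdims=True)
            if self.contextual:
                w = _sigmoid(rep @ p["Ww"] + p["bw"])  # (N, 1)
                q = w * v + (1 - w) * c
            else:
                w = None
                q = v + c
            cache.update(v=v, a=a, c=c, w=w)
        if detail:
            return q, cache
        return q

    def q_values(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    # backward -------------------------------------------------------------

    def backward(self, cache: dict, dq: np.ndarray) -> dict[str, np.ndarray]:
        """Analytic gradients of a scalar loss given dL/dQ for the batch."""
        p = self.params
        grads: dict[str, np.ndarray] = {}
        rep, h2 = cache["rep"], cache["h2"]
        if not self.dueling:
            grads["Wq"] = rep.T @ dq
            grads["bq"] = dq.sum(axis=0)
            drep = dq @ p["Wq"].T
        else:
            v, c, w = cache["v"], cache["c"], cache["w"]
            if self.contextual:
                # Q = w V + (1-w) C ; dQ/dw_a = V - C_a
                dw = (dq * (v - c)).sum(axis=1, keepdims=True)
                dv = (dq.sum(axis=1, keepdims=True)) * w
                dc = dq * (1 - w)
                sw = w * (1 - w)
                dzw = dw * sw
                grads["Ww"] = rep.T @ dzw
                grads["bw"] = dzw.sum(axis=0)
                drep_ctx = dzw @ p["Ww"].T
            else:
                dv = dq.sum(axis=1, keepdims=True)
                dc = dq
                drep_ctx = 0.0
            # C = A - mean(A) => dA = dC - mean(dC)
            da = dc - dc.mean(axis=1, keepdims=True)
            grads["Wv"] = rep.T @ dv
            grads["bv"] = dv.sum(axis=0)
            grads["Wa"] = rep.T @ da
            grads["ba"] = da.sum(axis=0)
            drep = dv @ p["Wv"].T + da @ p["Wa"].T + drep_ctx
        if self.gated:
            g = cache["g"]
            dh2 = drep * g
            dzg = (drep * h2) * g * (1 - g)
            grads["Wg"] = h2.T @ dzg
            grads["bg"] = dzg.sum(axis=0)
            dh2 = dh2 + dzg @ p["Wg"].T
        else:
            dh2 = drep
        dz2 = dh2 * (cache["z2"] > 0)
        grads["W2"] = cache["h1"].T @ dz2
        grads["b2"] = dz2.sum(axis=0)
        dh1 = dz2 @ p["W2"].T
        dz1 = dh1 * (cache["z1"] > 0)
        grads["W1"] = cache["x"].T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        return grads

    def copy_from(self, other: "QNetwork") -> None:
        for k, v in other.params.items():
            self.params[k] = v.copy()

    def clone(self) -> "QNetwork":
        net = QNetwork(self.n_features, self.n_actions, self.variant, self.hidden, seed=0)
        net.copy_from(self)
        return net


class Adam:
    """Standard Adam optimizer over a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# -- TD machinery ----------------------------------------------------------


def td_target(
    reward: float,
    next_state: np.ndarray,
    terminal: bool,
    gamma: float,
    target_net: QNetwork,
    online_net: QNetwork | None = None,
    double: bool = False,
) -> float:
    """Bootstrapped regression target: r at terminals, else r + γ·(next value).

    Plain targets take max_a' Q_target(s',a'); double targets evaluate the
    online network's argmax action under the target network, decoupling
    action selection from value estimation.
    """
    if terminal:
        return float(reward)
    q_t = target_net.q_values(next_state)[0]
    if double:
        if online_net is None:
            raise ValueError("double targets require the online network")
        a_star = int(np.argmax(online_net.q_values(next_state)[0]))
        nxt = q_t[a_star]
    else:
        nxt = q_t.max()
    return float(reward + gamma * nxt)


def _batch_targets(
    batch: Sequence[Transition], gamma: float, target_net: QNetwork,
    online_net: QNetwork, double: bool,
) -> np.ndarray:
    next_states = np.stack([t.next_state for t in batch])
    rewards = np.array([t.reward for t in batch])
    terminal = np.array([t.terminal for t in batch])
    q_t = target_net.q_values(next_states)
    if double:
        a_star = np.argmax(online_net.q_values(next_states), axis=1)
        nxt = q_t[np.arange(len(batch)), a_star]
    else:
        nxt = q_t.max(axis=1)
    return np.where(terminal, rewards, rewards + gamma * nxt)


def epsilon_greedy(q: np.ndarray, epsilon: float, rng: np.random.Generator) -> int:
    """ε-greedy action: uniform with probability ε, else argmax (ties → 0)."""
    q = np.asarray(q).ravel()
    if rng.random() < epsilon:
        return int(rng.integers(len(q)))
    return int(np.argmax(q))


def decay_epsilon(epsilon: float, config: AgentConfig) -> float:
    """Multiplicative decay with floor: max(ε·decay, ε_min)."""
    return max(epsilon * config.epsilon_decay, config.epsilon_min)


def replay_update(
    online_net: QNetwork,
    batch: Sequence[Transition],
    target_net: QNetwork,
    config: AgentConfig,
    optimizer: Adam,
) -> float:
    """One MSE gradient step on the taken-action Q-values of a batch.

    Only the Q-outputs of the actions actually taken contribute; the
    returned value is the batch MSE before the step.
    """
    if not batch:
        raise ValueError("empty batch")
    states = np.stack([t.state for t in batch])
    actions = np.array([t.action for t in batch])
    y = _batch_targets(batch, config.gamma, target_net, online_net,
                       double=config.variant in _DOUBLE)
    q, cache = online_net.forward(states, detail=True)
    n = len(batch)
    pred = q[np.arange(n), actions]
    err = pred - y
    loss = float(np.mean(err ** 2))
    dq = np.zeros_like(q)
    dq[np.arange(n), actions] = 2.0 * err / n
    grads = online_net.backward(cache, dq)
    optimizer.step(online_net.params, grads)
    return loss


def sync_target(online_net: QNetwork, target_net: QNetwork) -> None:
    """Hard copy: target parameters become an exact copy of the online ones."""
    target_net.copy_from(online_net)


# -- training loop ---------------------------------------------------------


@dataclass
class EpisodeLog:
    """Per-episode traces: cumulative reward, accuracy, mean replay loss."""

    rewards: list[float] = field(default_factory=list)
    accuracies: list[float] = field(default_factory=list)
    losses: list[float] = field(default_factory=list)


@dataclass
class DQNPolicy:
    """A trained Q-network bound to its config and feature namespace."""

    network: QNetwork
    config: AgentConfig
    namespace_hash: str

    def predict(self, table: SampleTable) -> np.ndarray:
        """Greedy per-sample argmax labels; refuses mismatched namespaces."""
        h = namespace_hash(table.feature_names)
        if self.namespace_hash and h != self.namespace_hash:
            raise ValueError(
                "feature namespace mismatch between policy and table; "
                "the policy was trained on a different feature set"
            )
        q = self.network.q_values(table.features)
        return np.argmax(q, axis=1)

    def q_table(self, table: SampleTable) -> np.ndarray:
        return self.network.q_values(table.features)

    def save(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "namespace_hash": self.namespace_hash,
            "n_features": self.network.n_features,
            "n_actions": self.network.n_actions,
            "hidden": list(self.network.hidden),
            "params": {k: v.tolist() for k, v in self.network.params.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "DQNPolicy":
        payload = json.loads(Path(path).read_text())
        cfg_raw = payload["config"]
        cfg_raw["hidden"] = tuple(cfg_raw["hidden"])
        config = AgentConfig(**cfg_raw)
        net = QNetwork(
            payload["n_features"], payload["n_actions"], config.variant,
            hidden=tuple(payload["hidden"]), seed=0,
        )
        net.params = {k: np.asarray(v, dtype=float) for k, v in payload["params"].items()}
        return cls(network=net, config=config, namespace_hash=payload["namespace_hash"])


def namespace_hash(feature_names: Sequence[str]) -> str:
    return hashlib.sha256("\x1f".join(feature_names).encode()).hexdigest()


def train(
    env: ClassificationEnv,
    config: AgentConfig,
    feature_names: Sequence[str] | None = None,
) -> tuple[DQNPolicy, EpisodeLog]:
    """Train a Q-network on the environment for ``config.episodes`` traversals.

    Each step: ε-greedy action, environment transition, transition stored,
    one replay update once the buffer holds a batch, per-step ε decay
    (default mode) and a hard target sync every ``config.target_update``
    steps.  All randomness flows from one seeded generator hierarchy, so
    identical configs reproduce identical runs.
    """
    rng = np.random.default_rng(config.seed)
    online = QNetwork(env.n_features, env.n_actions, config.variant,
                      hidden=config.hidden, seed=int(rng.integers(2**31 - 1)))
    target = online.clone()
    optimizer = Adam(online.params, lr=config.learning_rate)
    buffer = ReplayBuffer(config.replay_capacity)
    log = EpisodeLog()
    epsilon = config.epsilon
    step_count = 0
    for _ in range(config.episodes):
        state = env.reset(seed=int(rng.integers(2**31 - 1)))
        ep_rewards: list[float] = []
        ep_losses: list[float] = []
        done = False
        while not done:
            q = online.q_values(state)[0]
            action = epsilon_greedy(q, epsilon, rng)
            next_state, reward, done = env.step(action)
            buffer.push(Transition(state, action, reward, next_state, done))
            if len(buffer) >= config.batch_size:
                batch = buffer.sample(config.batch_size, rng)
                ep_losses.append(replay_update(online, batch, target, config, optimizer))
            step_count += 1
            if step_count % config.target_update == 0:
                sync_target(online, target)
            if config.epsilon_decay_mode == "step":
                epsilon = decay_epsilon(epsilon, config)
            ep_rewards.append(reward)
            state = next_state
        if config.epsilon_decay_mode == "episode":
            epsilon = decay_epsilon(epsilon, config)
        log.rewards.append(float(np.sum(ep_rewards)))
        log.accuracies.append(episode_accuracy(ep_rewards))
        log.losses.append(float(np.mean(ep_losses)) if ep_losses else float("nan"))
    ns_hash = namespace_hash(feature_names) if feature_names is not None else ""
    policy = DQNPolicy(network=online, config=config, namespace_hash=ns_hash)
    return policy, log


def predict(policy: DQNPolicy, table: SampleTable) -> np.ndarray:
    """Greedy labels for every row of the table (no exploration)."""
    return policy.predict(table)
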