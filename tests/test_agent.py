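"""Q-network family: fusion identities, TD targets, replay, training loop."""

import numpy as np
import pytest

from gliorl.agent import (
    Adam,
    AgentConfig,
    DQNPolicy,
    QNetwork,
    ReplayBuffer,
    Transition,
    decay_epsilon,
    dueling_q,
    epsilon_greedy,
    fuse_q_values,
    replay_update,
    sync_target,
    td_target,
    train,
)
from gliorl.env import ClassificationEnv
from gliorl.synthetic import SynthSpec, generate_classification_table
from gliorl.table import zscore_normalize


class TestFusionArithmetic:
    def test_context_fusion_scalar_example(self):
        """V=2, A=(1,3), w=0.5: centered A=(-1,1) so Q=(0.5, 1.5)."""
        np.testing.assert_allclose(fuse_q_values(2.0, np.array([1.0, 3.0]), 0.5), [0.5, 1.5])

    def test_weight_one_limit_collapses_to_value(self):
        q = fuse_q_values(3.0, np.array([5.0, -5.0]), 1 - 1e-12)
        np.testing.assert_allclose(q, [3.0, 3.0], atol=1e-9)

    def test_zero_value_gives_zero_mean_q(self):
        q = fuse_q_values(0.0, np.array([2.0, 4.0, 9.0]), 0.3)
        assert q.mean() == pytest.approx(0.0)

    def test_weight_outside_open_interval_rejected(self):
        for w in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError, match="open interval"):
                fuse_q_values(1.0, np.array([1.0, 2.0]), w)

    def test_dueling_scalar_example(self):
        """V=1, A=(0,2): mean A=1 so Q=(0,2)."""
        np.testing.assert_allclose(dueling_q(1.0, np.array([0.0, 2.0])), [0.0, 2.0])

    def test_dueling_constant_advantage_collapses_to_value(self):
        np.testing.assert_allclose(dueling_q(4.0, np.full(3, 7.0)), [4.0] * 3)


class TestNetworkIdentities:
    @pytest.mark.parametrize("variant", ["dueling", "dueling_double"])
    def test_plain_dueling_mean_q_equals_value(self, variant):
        """mean_a Q(s,a) = V(s): the centered-advantage identity."""
        net = QNetwork(6, 3, variant, seed=1)
        x = np.random.default_rng(0).normal(size=(17, 6))
        q, cache = net.forward(x, detail=True)
        np.testing.assert_allclose(q.mean(axis=1), cache["v"].ravel(), atol=1e-10)

    def test_context_attention_mean_q_equals_weighted_value(self):
        """mean_a Q(s,a) = w(s)*V(s) for the convex attention fusion."""
        net = QNetwork(6, 3, "context_attn", seed=2)
        x = np.random.default_rng(1).normal(size=(17, 6))
        q, cache = net.forward(x, detail=True)
        np.testing.assert_allclose(
            q.mean(axis=1), (cache["w"] * cache["v"]).ravel(), atol=1e-10
        )

    def test_attention_weight_in_open_unit_interval(self):
        net = QNetwork(4, 2, "context_attn", seed=3)
        x = np.random.default_rng(2).normal(size=(50, 4)) * 10
        _, cache = net.forward(x, detail=True)
        assert ((cache["w"] > 0) & (cache["w"] < 1)).all()

    def test_gradients_match_finite_differences(self):
        """Analytic backprop vs central finite differences on every variant."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=(5, 4))
        actions = rng.integers(0, 2, size=5)
        targets = rng.normal(size=5)
        for variant in ("dqn", "dueling", "dueling_double_attn", "context_attn"):
            net = QNetwork(4, 2, variant, seed=11)

            def loss():
                q = net.forward(x)
                return np.mean((q[np.arange(5), actions] - targets) ** 2)

            q, cache = net.forward(x, detail=True)
            err = q[np.arange(5), actions] - targets
            dq = np.zeros_like(q)
            dq[np.arange(5), actions] = 2 * err / 5
            grads = net.backward(cache, dq)
            for k in net.params:
                p = net.params[k]
                flat_idx = (0,) * p.ndim
                eps = 1e-6
                p[flat_idx] += eps
                up = loss()
                p[flat_idx] -= 2 * eps
                down = loss()
                p[flat_idx] += eps
                fd = (up - down) / (2 * eps)
                assert grads[k][flat_idx] == pytest.approx(fd, abs=1e-5), (variant, k)


class TestTDTargets:
    def test_terminal_returns_reward(self):
        net = QNetwork(3, 2, "dqn", seed=0)
        assert td_target(-1.0, np.zeros(3), True, 0.99, net) == -1.0

    def test_gamma_zero_returns_reward(self):
        net = QNetwork(3, 2, "dqn", seed=0)
        assert td_target(1.0, np.ones(3), False, 0.0, net) == pytest.approx(1.0)

    def test_scalar_arithmetic_oracle(self):
        """r=1, gamma=0.99, max target Q=2 -> 2.98."""
        net = QNetwork(2, 2, "dqn", seed=0)
        s = np.array([0.3, -0.2])
        q = net.q_values(s)[0]
        expected = 1.0 + 0.99 * q.max()
        assert td_target(1.0, s, False, 0.99, net) == pytest.approx(expected)
        # frozen-weights arithmetic check of the published example numbers
        assert 1.0 + 0.99 * 2.0 == pytest.approx(2.98)

    def test_double_target_never_exceeds_max_target(self):
        """Evaluating the online argmax under the target net is bounded by
        the target net's own max (the max inequality)."""
        rng = np.random.default_rng(9)
        online = QNetwork(5, 3, "dueling_double", seed=1)
        target = QNetwork(5, 3, "dueling_double", seed=2)
        for _ in range(20):
            s = rng.normal(size=5)
            dbl = td_target(0.5, s, False, 0.99, target, online, double=True)
            mx = td_target(0.5, s, False, 0.99, target)
            assert dbl <= mx + 1e-12

    def test_period_one_sync_makes_double_equal_max(self):
        online = QNetwork(4, 2, "double", seed=3)
        target = QNetwork(4, 2, "double", seed=4)
        sync_target(online, target)
        s = np.array([0.1, 0.2, -0.3, 0.4])
        assert td_target(1.0, s, False, 0.9, target, online, double=True) == pytest.approx(
            td_target(1.0, s, False, 0.9, target)
        )


class TestExploration:
    def test_greedy_when_epsilon_zero(self):
        rng = np.random.default_rng(0)
        assert epsilon_greedy(np.array([0.1, 0.9, 0.3]), 0.0, rng) == 1

    def test_tie_breaks_to_lowest_index(self):
        rng = np.random.default_rng(0)
        assert epsilon_greedy(np.array([0.5, 0.5, 0.5]), 0.0, rng) == 0

    def test_uniform_when_epsilon_one(self):
        rng = np.random.default_rng(1)
        counts = np.zeros(3)
        for _ in range(10_000):
            counts[epsilon_greedy(np.zeros(3), 1.0, rng)] += 1
        # 3-sigma binomial band around p=1/3
        sigma = np.sqrt(10_000 * (1 / 3) * (2 / 3))
        assert (np.abs(counts - 10_000 / 3) < 3 * sigma).all()

    def test_decay_arithmetic_and_floor(self):
        cfg = AgentConfig()
        assert decay_epsilon(0.5, cfg) == pytest.approx(0.4975)
        assert decay_epsilon(0.01, cfg) == 0.01
        eps, seq = 0.5, []
        for _ in range(2000):
            eps = decay_epsilon(eps, cfg)
            seq.append(eps)
        assert all(a >= b for a, b in zip(seq, seq[1:]))
        assert seq[-1] == 0.01


class TestReplay:
    def _transitions(self, n, nf=3, na=2, seed=0):
        rng = np.random.default_rng(seed)
        return [
            Transition(rng.normal(size=nf), int(rng.integers(na)),
                       float(rng.choice([-1, 1])), rng.normal(size=nf),
                       bool(rng.random() < 0.2))
            for _ in range(n)
        ]

    def test_buffer_capacity_fifo(self):
        buf = ReplayBuffer(5)
        ts = self._transitions(8)
        for t in ts:
            buf.push(t)
        assert len(buf) == 5
        sampled = buf.sample(5, np.random.default_rng(0))
        # oldest three evicted: every sampled transition is among the last 5
        kept = {id(t) for t in ts[3:]}
        assert all(id(s) in kept for s in sampled)

    def test_batch_sample_without_replacement(self):
        buf = ReplayBuffer(10)
        for t in self._transitions(10):
            buf.push(t)
        batch = buf.sample(10, np.random.default_rng(1))
        assert len({id(t) for t in batch}) == 10

    def test_zero_error_batch_leaves_loss_zero(self):
        """Targets equal to current predictions: loss 0, no parameter drift."""
        net = QNetwork(3, 2, "dqn", seed=5)
        target = net.clone()
        cfg = AgentConfig(gamma=0.0, variant="dqn")
        opt = Adam(net.params, lr=0.001)
        s = np.array([0.5, -0.5, 1.0])
        q = net.q_values(s)[0]
        batch = [Transition(s, 0, float(q[0]), np.zeros(3), True)]
        before = {k: v.copy() for k, v in net.params.items()}
        loss = replay_update(net, batch, target, cfg, opt)
        assert loss == pytest.approx(0.0, abs=1e-20)
        for k in before:
            np.testing.assert_allclose(net.params[k], before[k], atol=1e-12)

    def test_loss_matches_hand_computed_mse(self):
        net = QNetwork(3, 2, "dueling", seed=6)
        target = net.clone()
        cfg = AgentConfig(gamma=0.9, variant="dueling")
        opt = Adam(net.params, lr=0.0)  # lr 0: inspect loss only
        ts = self._transitions(2, seed=3)
        q = net.q_values(np.stack([t.state for t in ts]))
        qn = target.q_values(np.stack([t.next_state for t in ts]))
        expected = []
        for i, t in enumerate(ts):
            y = t.reward if t.terminal else t.reward + 0.9 * qn[i].max()
            expected.append((q[i, t.action] - y) ** 2)
        loss = replay_update(net, ts, target, cfg, opt)
        assert loss == pytest.approx(np.mean(expected))

    def test_repeated_updates_overfit_fixed_batch(self):
        net = QNetwork(4, 2, "context_attn", seed=7)
        target = net.clone()
        cfg = AgentConfig(variant="context_attn")
        opt = Adam(net.params, lr=0.01)
        batch = self._transitions(8, nf=4, seed=4)
        batch = [Transition(t.state, t.action, t.reward, t.next_state, True) for t in batch]
        first = replay_update(net, batch, target, cfg, opt)
        for _ in range(300):
            last = replay_update(net, batch, target, cfg, opt)
        assert last < 0.01 * max(first, 1e-6) or last < 1e-6

    def test_sync_target_exact_copy(self):
        online = QNetwork(3, 2, "dueling", seed=8)
        target = QNetwork(3, 2, "dueling", seed=9)
        x = np.random.default_rng(3).normal(size=(4, 3))
        assert not np.allclose(online.q_values(x), target.q_values(x))
        sync_target(online, target)
        np.testing.assert_allclose(online.q_values(x), target.q_values(x), atol=1e-7)


@pytest.fixture(scope="module")
def trained():
    spec = SynthSpec(class_counts=(50, 50), n_features=15, n_informative=5,
                     effect_size=3.0, seed=21)
    table, _ = generate_classification_table(spec)
    table, _ = zscore_normalize(table)
    env = ClassificationEnv(table, seed=2)
    cfg = AgentConfig(episodes=30, seed=3)
    policy, log = train(env, cfg, feature_names=table.feature_names)
    return table, cfg, policy, log


class TestTraining:
    def test_learns_separable_data_within_30_episodes(self, trained):
        _, _, _, log = trained
        assert max(log.accuracies) >= 0.95

    def test_log_lengths_match_episodes(self, trained):
        _, cfg, _, log = trained
        assert len(log.rewards) == len(log.accuracies) == len(log.losses) == cfg.episodes

    def test_reward_accuracy_identity(self, trained):
        table, _, _, log = trained
        n = len(table)
        for r, a in zip(log.rewards, log.accuracies):
            assert a == pytest.approx((r + n) / (2 * n))

    def test_greedy_predictions_near_final_episode_accuracy(self, trained):
        table, _, policy, log = trained
        acc = (policy.predict(table) == table.labels).mean()
        assert acc >= log.accuracies[-1] - 0.02

    def test_prediction_equivariant_under_row_permutation(self, trained):
        table, _, policy, _ = trained
        perm = np.random.default_rng(4).permutation(len(table))
        preds = policy.predict(table)
        preds_perm = policy.predict(table.subset_rows(perm))
        np.testing.assert_array_equal(preds_perm, preds[perm])

    def test_seed_determinism_of_training(self):
        spec = SynthSpec(class_counts=(15, 15), n_features=8, n_informative=3,
                         effect_size=2.0, seed=5)
        table, _ = generate_classification_table(spec)
        table, _ = zscore_normalize(table)
        logs = []
        for _ in range(2):
            env = ClassificationEnv(table, seed=1)
            policy, log = train(env, AgentConfig(episodes=5, seed=9))
            logs.append((log.rewards, policy.network.params["W1"].copy()))
        assert logs[0][0] == logs[1][0]
        np.testing.assert_array_equal(logs[0][1], logs[1][1])

    def test_checkpoint_round_trip_and_namespace_guard(self, trained, tmp_path):
        table, _, policy, _ = trained
        p = tmp_path / "policy.json"
        policy.save(p)
        loaded = DQNPolicy.load(p)
        np.testing.assert_array_equal(loaded.predict(table), policy.predict(table))
        renamed = table.df.rename(columns={table.feature_names[0]: "other"})
        from gliorl.table import SampleTable

        with pytest.raises(ValueError, match="namespace"):
            loaded.predict(SampleTable(renamed))


class TestConfigValidation:
    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            AgentConfig(gamma=1.5)
        with pytest.raises(ValueError):
            AgentConfig(epsilon=0.1, epsilon_min=0.2)
        with pytest.raises(ValueError):
            AgentConfig(variant="rainbow")
        with pytest.raises(ValueError):
            AgentConfig(epsilon_decay=0.0)
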