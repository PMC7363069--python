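"""REINFORCE losses, gradients, baseline bookkeeping and the training loop."""

import numpy as np
import pytest

import colorgame as cg
from colorgame.agents import channel_noise, receiver_forward, sender_word_probs, Message
from colorgame.training import (
    GameConfig,
    play_batch_continuous,
    play_batch_discrete,
    reward,
)
from conftest import make_chips


@pytest.fixture(scope="module")
def chart3():
    return cg.ChipChart(chips=make_chips((0, 0, 0), (100, 0, 0), (0, 100, 0)), name="c3")


class TestReward:
    def test_identical_chips_reward_one(self, chart3):
        assert reward(1, 1, chart3) == 1.0

    def test_closed_form_at_distance_100(self, chart3):
        assert reward(0, 1, chart3) == pytest.approx(np.exp(-10))

    def test_symmetric(self, chart3):
        assert reward(0, 2, chart3) == reward(2, 0, chart3)

    def test_unknown_chip_rejected(self, chart3):
        with pytest.raises(ValueError):
            reward(5, 0, chart3)


class TestContinuousBatch:
    def test_single_game_matches_hand_forward_pass(self, chart3):
        """The batch loss equals -log pi(c|t) * r computed step by step with
        the agent-module forward functions and a replayed rng stream."""
        params = cg.init_agent_parameters(3, np.random.default_rng(0), hidden_width=4,
                                          message_dim=5)
        cfg = GameConfig(sigma_e_sq=2.0, sigma_c_sq=0.3, batch_size=1, n_episodes=1,
                         hidden_width=4, message_dim=5)
        loss, grads, row = play_batch_continuous(params, chart3, cfg, np.random.default_rng(42))

        rng = np.random.default_rng(42)  # replay the identical draw sequence
        t = int(rng.integers(0, 3, size=1)[0])
        x = chart3.coords[t] + rng.normal(0, np.sqrt(2.0), size=(1, 3))
        w = sender_word_probs(params, x)[0]
        m = w + rng.normal(0, np.sqrt(0.3), size=(1, 5))[0]
        p = receiver_forward(params, m)
        u = rng.random(1)[0]
        guess = int(np.searchsorted(np.cumsum(p), u, side="left"))
        expected = -np.log(p[guess]) * reward(guess, t, chart3)
        assert loss == pytest.approx(expected, rel=1e-9)
        assert row["mean_reward"] == pytest.approx(reward(guess, t, chart3))

    def test_certain_guesses_give_zero_loss(self):
        """If the sampled guess always has probability ~1, -log 1 = 0."""
        chart1 = cg.ChipChart(chips=make_chips((0, 0, 0)), name="c1")
        params = cg.init_agent_parameters(1, np.random.default_rng(0))
        cfg = GameConfig(sigma_e_sq=0.0, sigma_c_sq=0.0, batch_size=8, n_episodes=1)
        loss, _, _ = play_batch_continuous(params, chart1, cfg, np.random.default_rng(1))
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_loss_finite_and_gradients_nonzero(self, chart3, rng):
        params = cg.init_agent_parameters(3, rng)
        cfg = GameConfig(batch_size=16, n_episodes=1)
        loss, grads, _ = play_batch_continuous(params, chart3, cfg, rng)
        assert np.isfinite(loss)
        assert any(np.any(g != 0) for g in grads.values())

    @pytest.mark.parametrize("mode", ["continuous", "discrete"])
    def test_gradients_match_finite_differences(self, chart3, mode):
        """Replayed action draws make the REINFORCE loss a deterministic,
        differentiable function; central differences must match the backprop."""
        params = cg.init_agent_parameters(3, np.random.default_rng(3), hidden_width=4,
                                          message_dim=5)
        cfg = GameConfig(sigma_e_sq=1.0, sigma_c_sq=0.05, batch_size=6, n_episodes=1,
                         message_mode=mode, hidden_width=4, message_dim=5)

        def loss_and_grads():
            rng = np.random.default_rng(77)
            if mode == "continuous":
                loss, g, _ = play_batch_continuous(params, chart3, cfg, rng)
                return loss, g
            ls, lr, g, _ = play_batch_discrete(params, chart3, cfg, rng, 2, 0.9)
            return ls + lr, g

        _, grads = loss_and_grads()
        for name in ("theta_s", "phi_r", "b_s2"):
            arr = getattr(params, name)
            idx = tuple(0 for _ in arr.shape)
            eps = 1e-6
            arr[idx] += eps
            up, _ = loss_and_grads()
            arr[idx] -= 2 * eps
            down, _ = loss_and_grads()
            arr[idx] += eps
            assert grads[name][idx] == pytest.approx((up - down) / (2 * eps), abs=1e-5)


class TestDiscreteBatch:
    def test_running_baseline_is_mean_of_rewards_seen(self, chart3):
        params = cg.init_agent_parameters(3, np.random.default_rng(0))
        cfg = GameConfig(message_mode="discrete", batch_size=4, n_episodes=1)
        _, _, _, row = play_batch_discrete(params, chart3, cfg, np.random.default_rng(0))
        assert row["baseline_count"] == 4
        # e.g. rewards [1, 0] observed so far -> running mean 0.5
        assert (1.0 + 0.0) / 2 == 0.5
        _, _, _, row2 = play_batch_discrete(
            params, chart3, cfg, np.random.default_rng(1),
            row["baseline_count"], row["baseline_sum"],
        )
        assert row2["baseline_count"] == 8
        assert row2["baseline_sum"] >= row["baseline_sum"]

    def test_zero_advantage_gives_zero_losses(self):
        """All rewards equal to the baseline: both cost functions vanish."""
        same = cg.ChipChart(chips=make_chips((0, 0, 0), (0, 0, 0), (0, 0, 0)), name="same")
        params = cg.init_agent_parameters(3, np.random.default_rng(0))
        cfg = GameConfig(message_mode="discrete", batch_size=16, n_episodes=1)
        # every reward is 1; prior running mean is exactly 1 as well
        ls, lr, grads, _ = play_batch_discrete(
            params, same, cfg, np.random.default_rng(2), 10, 10.0
        )
        assert ls == pytest.approx(0.0, abs=1e-12)
        assert lr == pytest.approx(0.0, abs=1e-12)
        assert all(np.allclose(g, 0) for g in grads.values())

    def test_single_game_matches_hand_computation(self, chart3):
        params = cg.init_agent_parameters(3, np.random.default_rng(1), hidden_width=4,
                                          message_dim=5)
        cfg = GameConfig(message_mode="discrete", sigma_e_sq=1.0, batch_size=1,
                         n_episodes=1, hidden_width=4, message_dim=5)
        ls, lr, _, _ = play_batch_discrete(params, chart3, cfg, np.random.default_rng(9), 1, 0.4)

        rng = np.random.default_rng(9)
        t = int(rng.integers(0, 3, size=1)[0])
        x = chart3.coords[t] + rng.normal(0, 1.0, size=(1, 3))
        w = sender_word_probs(params, x)[0]
        mi = int(np.searchsorted(np.cumsum(w), rng.random(1)[0], side="left"))
        m = np.zeros(5)
        m[mi] = 1.0
        p = receiver_forward(params, m)
        guess = int(np.searchsorted(np.cumsum(p), rng.random(1)[0], side="left"))
        adv = reward(guess, t, chart3) - 0.4
        assert ls == pytest.approx(-np.log(w[mi]) * adv, rel=1e-9)
        assert lr == pytest.approx(-np.log(p[guess]) * adv, rel=1e-9)


class TestSharedForward:
    def test_modes_share_sender_and_receiver_code(self, chart3):
        """Given identical parameters and inputs, the evaluation-time forward
        functions reproduce what both training paths compute: the sender
        softmax feeding the continuous channel equals the categorical the
        discrete mode samples from, and a zero-noise channel is the identity."""
        params = cg.init_agent_parameters(3, np.random.default_rng(5))
        x = chart3.coords[1]
        w = sender_word_probs(params, x)
        msg = cg.sender_forward(params, x, "continuous")
        assert np.array_equal(msg.values, w)
        assert np.array_equal(channel_noise(msg, 0.0, np.random.default_rng(0)), w)


class TestTrainLoop:
    def test_same_seed_identical_traces(self, chart_tiny):
        cfg = GameConfig(n_episodes=50, batch_size=10, seed=3, kl_probe_interval=25)
        p1, t1 = cg.train(chart_tiny, cfg)
        p2, t2 = cg.train(chart_tiny, cfg)
        assert t1.mean_reward == t2.mean_reward
        assert t1.term_count == t2.term_count
        assert t1.kl_probe == t2.kl_probe
        assert np.array_equal(p1.phi_r, p2.phi_r)

    def test_trace_lengths_and_snapshots(self, chart_tiny):
        cfg = GameConfig(n_episodes=40, batch_size=10, seed=0, kl_probe_interval=None)
        _, trace = cg.train(chart_tiny, cfg)
        assert trace.n_episodes == 40
        assert len(trace.term_count) == 40
        episodes = [e for e, _, _ in trace.snapshots]
        assert episodes[0] == 0 and episodes == sorted(episodes)

    def test_discrete_mode_runs_and_tracks_baseline(self, chart_tiny):
        cfg = GameConfig(message_mode="discrete", n_episodes=30, batch_size=16, seed=1,
                         kl_probe_interval=None)
        _, trace = cg.train(chart_tiny, cfg)
        assert len(trace.baseline) == 30
        assert all(0 <= b <= 1 for b in trace.baseline)

    def test_mode_defaults(self):
        assert GameConfig(message_mode="continuous").batch_size == 100
        assert GameConfig(message_mode="continuous").n_episodes == 20000
        assert GameConfig(message_mode="discrete").batch_size == 256
        assert GameConfig(message_mode="discrete").n_episodes == 25000
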