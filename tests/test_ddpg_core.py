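import numpy as np
import pytest

from neuroctrl.ddpg_core import Agent, Batch, OUNoise, ReplayBuffer, Transition

from conftest import flatten_params, set_flat_params


def make_batch(rng, state_dim=3, action_dim=1, batch=4, n_agents=1, terminal=False):
    return Batch(
        states=rng.normal(size=(n_agents, batch, state_dim)),
        actions=rng.uniform(-1, 1, size=(n_agents, batch, action_dim)),
        rewards=rng.normal(size=(n_agents, batch)),
        next_states=rng.normal(size=(n_agents, batch, state_dim)),
        terminals=np.full(batch, terminal),
    )


def zero_net_with_bias(net, bias):
    """Set all parameters to zero except the final-layer bias."""
    flat = np.zeros(net.n_params())
    set_flat_params(net, flat)
    net.biases[-1][...] = bias


class TestOUNoise:
    def test_pure_decay(self, rng):
        ou = OUNoise(1, theta=0.15, sigma=0.0, dt=1.0, rng=rng)
        ou.x[...] = 1.0
        assert ou.step() == pytest.approx(0.85)

    def test_zero_fixed_point(self, rng):
        ou = OUNoise(2, theta=0.15, sigma=0.0, dt=1.0, rng=rng)
        for _ in range(50):
            assert np.all(ou.step() == 0.0)

    def test_stationary_variance_exact_ar1(self, rng):
        # the Euler update is an AR(1) process with exact stationary
        # variance sigma^2 dt / (1 - (1 - theta dt)^2)
        theta, sigma, dt = 0.15, 0.2, 1.0
        ou = OUNoise(1, theta=theta, sigma=sigma, dt=dt, rng=rng)
        xs = np.array([ou.step()[0] for _ in range(100_000)])
        target = sigma**2 * dt / (1 - (1 - theta * dt) ** 2)
        assert np.var(xs[1000:]) == pytest.approx(target, rel=0.05)
        assert np.mean(xs[1000:]) == pytest.approx(0.0, abs=0.02)

    def test_stationary_variance_continuum_limit(self, rng):
        # at small theta*dt the AR(1) variance approaches the
        # continuous-time OU value sigma^2 / (2 theta)
        ou = OUNoise(1, theta=0.15, sigma=0.2, dt=0.1, rng=rng)
        xs = np.array([ou.step()[0] for _ in range(100_000)])
        assert np.var(xs[5000:]) == pytest.approx(0.2**2 / (2 * 0.15), rel=0.05)

    @pytest.mark.parametrize("kwargs", [dict(theta=0.0), dict(theta=-1.0), dict(dt=0.0), dict(sigma=-0.1)])
    def test_bad_config(self, kwargs):
        with pytest.raises(ValueError):
            OUNoise(1, **kwargs)


class TestSelectAction:
    def test_deterministic_without_exploration(self, rng):
        agent = Agent(3, 1, hidden_dims=(8, 8), a_max=2.0, rng=rng)
        s = np.array([0.3, -1.0, 0.5])
        a1 = agent.select_action(s, explore=False)
        a2 = agent.select_action(s, explore=False)
        assert np.array_equal(a1, a2)

    def test_zero_sigma_explore_matches_greedy(self, rng):
        agent = Agent(3, 1, hidden_dims=(8, 8), a_max=2.0, ou_sigma=0.0, rng=rng)
        s = np.array([0.3, -1.0, 0.5])
        assert np.allclose(agent.select_action(s, True), agent.select_action(s, False))

    def test_near_zero_initial_policy(self, rng):
        # small final-layer init keeps initial actions near zero
        agent = Agent(4, 2, hidden_dims=(16, 16), a_max=5.0, rng=rng)
        a = agent.select_action(rng.normal(size=4))
        assert np.all(np.abs(a) < 0.2)

    def test_dimension_mismatch(self, rng):
        agent = Agent(3, 1, hidden_dims=(8, 8), rng=rng)
        with pytest.raises(ValueError):
            agent.select_action(np.zeros(5))

    def test_bounds_respected_under_noise(self, rng):
        agent = Agent(3, 1, hidden_dims=(8, 8), a_max=0.5, ou_sigma=5.0, rng=rng)
        s = rng.normal(size=3)
        for _ in range(100):
            assert np.all(np.abs(agent.select_action(s, explore=True)) <= 0.5)


class TestTdTarget:
    def test_bootstrap_value(self, rng):
        agent = Agent(3, 1, hidden_dims=(8, 8), gamma=0.99, rng=rng)
        zero_net_with_bias(agent.target_critic, 2.0)
        batch = make_batch(rng)
        batch.rewards[...] = 1.0
        assert agent.td_target(batch) == pytest.approx(2.98)

    def test_terminal_drops_bootstrap(self, rng):
        agent = Agent(3, 1, hidden_dims=(8, 8), gamma=0.99, rng=rng)
        zero_net_with_bias(agent.target_critic, 2.0)
        batch = make_batch(rng, terminal=True)
        batch.rewards[...] = -1.0
        assert agent.td_target(batch) == pytest.approx(-1.0)

    def test_myopic_limit(self, rng):
        agent = Agent(3, 1, hidden_dims=(8, 8), gamma=0.0, rng=rng)
        batch = make_batch(rng)
        assert np.allclose(agent.td_target(batch), batch.rewards)


class TestCriticUpdate:
    def test_exact_critic_no_change(self, rng):
        agent = Agent(3, 1, hidden_dims=(8, 8), rng=rng)
        batch = make_batch(rng, terminal=True)
        batch.rewards[...] = 0.7
        zero_net_with_bias(agent.critic, 0.7)
        before = flatten_params(agent.critic.params).copy()
        loss = agent.critic_update(batch)
        assert loss == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(flatten_params(agent.critic.params), before)

    def test_identical_transitions_loss(self, rng):
        agent = Agent(3, 1, hidden_dims=(8, 8), rng=rng)
        batch = make_batch(rng, batch=6, terminal=True)
        batch.states[...] = batch.states[:, :1, :]
        batch.actions[...] = batch.actions[:, :1, :]
        batch.rewards[...] = 1.5
        q = agent.critic.forward(
            np.concatenate([batch.states, batch.actions], axis=-1)
        )[0, 0, 0]
        loss = agent.critic_update(batch)
        assert loss == pytest.approx((q - 1.5) ** 2)

    def test_empty_batch_rejected(self, rng):
        agent = Agent(3, 1, hidden_dims=(8, 8), rng=rng)
        batch = make_batch(rng, batch=0)
        with pytest.raises(ValueError):
            agent.critic_update(batch)

    def test_gradient_matches_finite_differences(self, rng):
        # tiny critic: 2 state dims, 1 action dim, hidden (2, 2)
        agent = Agent(2, 1, hidden_dims=(2, 2), rng=rng)
        batch = make_batch(rng, state_dim=2, batch=5)
        y = agent.td_target(batch)
        x = np.concatenate(
            [batch.states, batch.actions], axis=-1
        )

        def loss_at(flat):
            saved = [p.copy() for p in agent.critic.params]
            set_flat_params(agent.critic, flat)
            q = agent.critic.forward(x)[..., 0]
            out = float(np.mean((q - y) ** 2))
            agent.critic.set_params(saved)
            return out

        q, cache = agent.critic.forward(x, want_cache=True)
        err = q[..., 0] - y
        dy = (2.0 / err.shape[-1]) * err[..., None]
        grads, _ = agent.critic.backward(cache, dy)
        analytic = flatten_params(grads)

        flat0 = flatten_params(agent.critic.params)
        eps = 1e-6
        numeric = np.empty_like(flat0)
        for i in range(flat0.size):
            up, dn = flat0.copy(), flat0.copy()
            up[i] += eps
            dn[i] -= eps
            numeric[i] = (loss_at(up) - loss_at(dn)) / (2 * eps)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-5, atol=1e-7)


class _QuadraticCritic:
    """Q(s, a) = -(a - c)^2, with backward exposing dQ/da."""

    def __init__(self, c, state_dim):
        self.c = c
        self.state_dim = state_dim

    def forward(self, x, want_cache=False):
        a = x[..., self.state_dim :]
        q = -((a - self.c) ** 2).sum(axis=-1, keepdims=True)
        return (q, a) if want_cache else q

    def backward(self, cache, dy):
        a = cache
        da = dy * (-2.0 * (a - self.c))
        dx = np.concatenate([np.zeros(a.shape[:-1] + (self.state_dim,)), da], axis=-1)
        return [], dx


class TestActorUpdate:
    def test_converges_to_critic_argmax(self, rng):
        agent = Agent(1, 1, hidden_dims=(16, 16), a_max=5.0, lr=0.02, rng=rng)
        agent.critic = _QuadraticCritic(3.0, state_dim=1)
        batch = make_batch(rng, state_dim=1, batch=8)
        batch.states[...] = 0.5
        for _ in range(1500):
            agent.actor_update(batch)
        a = agent.select_action(np.array([0.5]))
        assert a[0] == pytest.approx(3.0, abs=0.01)

    def test_constant_critic_is_noop(self, rng):
        agent = Agent(3, 1, hidden_dims=(8, 8), rng=rng)
        zero_net_with_bias(agent.critic, 4.2)
        before = flatten_params(agent.actor.params).copy()
        mean_q = agent.actor_update(make_batch(rng))
        assert mean_q == pytest.approx(4.2)
        assert np.array_equal(flatten_params(agent.actor.params), before)

    def test_empty_batch_rejected(self, rng):
        agent = Agent(3, 1, hidden_dims=(8, 8), rng=rng)
        with pytest.raises(ValueError):
            agent.actor_update(make_batch(rng, batch=0))

    def test_gradient_matches_finite_differences(self, rng):
        agent = Agent(2, 1, hidden_dims=(2, 2), rng=rng)
        # give the critic some non-trivial structure
        for p in agent.critic.params:
            p += rng.normal(scale=0.3, size=p.shape)
        batch = make_batch(rng, state_dim=2, batch=5)
        s = batch.states

        def objective_at(flat):
            saved = [p.copy() for p in agent.actor.params]
            set_flat_params(agent.actor, flat)
            a = agent.actor.forward(s)
            q = agent.critic.forward(np.concatenate([s, a], axis=-1))
            agent.actor.set_params(saved)
            return float(np.mean(q))

        a, a_cache = agent.actor.forward(s, want_cache=True)
        q, q_cache = agent.critic.forward(
            np.concatenate([s, a], axis=-1), want_cache=True
        )
        dq = np.full_like(q, -1.0 / q.shape[-2])  # gradient of -mean Q
        _, dx = agent.critic.backward(q_cache, dq)
        grads, _ = agent.actor.backward(a_cache, dx[..., 2:])
        analytic = -flatten_params(grads)  # ascent direction

        flat0 = flatten_params(agent.actor.params)
        eps = 1e-6
        numeric = np.empty_like(flat0)
        for i in range(flat0.size):
            up, dn = flat0.copy(), flat0.copy()
            up[i] += eps
            dn[i] -= eps
            numeric[i] = (objective_at(up) - objective_at(dn)) / (2 * eps)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-5, atol=1e-7)


class TestPolyak:
    def test_targets_start_equal(self, rng):
        agent = Agent(3, 2, hidden_dims=(8, 8), rng=rng)
        assert np.array_equal(
            flatten_params(agent.actor.params), flatten_params(agent.target_actor.params)
        )
        assert np.array_equal(
            flatten_params(agent.critic.params), flatten_params(agent.target_critic.params)
        )

    def test_tau_one_copies(self, rng):
        agent = Agent(3, 1, hidden_dims=(8, 8), tau=1.0, rng=rng)
        for p in agent.target_actor.params:
            p += 1.0
        agent.polyak_update()
        assert np.array_equal(
            flatten_params(agent.actor.params), flatten_params(agent.target_actor.params)
        )

    def test_tau_zero_freezes(self, rng):
        agent = Agent(3, 1, hidden_dims=(8, 8), tau=0.0, rng=rng)
        before = flatten_params(agent.target_critic.params).copy()
        for p in agent.critic.params:
            p += 1.0
        agent.polyak_update()
        assert np.array_equal(flatten_params(agent.target_critic.params), before)

    def test_methods_tau_arithmetic(self, rng):
        agent = Agent(3, 1, hidden_dims=(8, 8), tau=0.001, rng=rng)
        zero_net_with_bias(agent.target_critic, 0.0)
        zero_net_with_bias(agent.critic, 0.0)
        agent.critic.biases[-1][...] = 1.0
        agent.polyak_update()
        assert agent.target_critic.biases[-1].ravel()[0] == pytest.approx(0.001)

    def test_polyak_conservation(self, rng):
        agent = Agent(3, 1, hidden_dims=(8, 8), tau=0.37, rng=rng)
        for p in agent.critic.params:
            p += rng.normal(size=p.shape)
        old = [p.copy() for p in agent.target_critic.params]
        agent.polyak_update()
        for p_t, p_old, p_live in zip(
            agent.target_critic.params, old, agent.critic.params
        ):
            np.testing.assert_allclose(
                p_t - p_old, 0.37 * (p_live - p_old), rtol=1e-14, atol=1e-15
            )


class TestReplayBuffer:
    @staticmethod
    def _push_scalar(buf, v, terminal=False):
        buf.push(np.array([v]), np.array([v]), v, np.array([v]), terminal)

    def test_fifo_eviction(self):
        buf = ReplayBuffer(2, state_dim=1)
        for v in (1.0, 2.0, 3.0):
            self._push_scalar(buf, v)
        held = sorted(t.reward for t in buf.contents())
        assert held == [2.0, 3.0]

    def test_single_roundtrip_bitwise(self, rng):
        buf = ReplayBuffer(10, state_dim=3, action_dim=2)
        s, a, s2 = rng.normal(size=3), rng.normal(size=2), rng.normal(size=3)
        buf.push(s, a, 0.25, s2, True)
        batch = buf.sample(1, rng)
        assert np.array_equal(batch.states[0, 0], s)
        assert np.array_equal(batch.actions[0, 0], a)
        assert batch.rewards[0, 0] == 0.25
        assert np.array_equal(batch.next_states[0, 0], s2)
        assert batch.terminals[0]

    def test_uniform_sampling_frequency(self, rng):
        buf = ReplayBuffer(4, state_dim=1)
        for v in range(4):
            self._push_scalar(buf, float(v))
        counts = np.zeros(4)
        n = 10_000
        for _ in range(n):
            batch = buf.sample(1, rng)
            counts[int(batch.rewards[0, 0])] += 1
        np.testing.assert_allclose(counts / n, 0.25, atol=0.02)

    def test_empty_sample_rejected(self, rng):
        buf = ReplayBuffer(4, state_dim=1)
        with pytest.raises(ValueError):
            buf.sample(1, rng)

    def test_oversample_rejected(self, rng):
        buf = ReplayBuffer(4, state_dim=1)
        self._push_scalar(buf, 1.0)
        with pytest.raises(ValueError):
            buf.sample(2, rng)

    def test_transition_shape_contract(self):
        with pytest.raises(ValueError):
            Transition(np.zeros(3), np.zeros(1), 0.0, np.zeros(4), False)


class TestCheckpoint:
    def test_roundtrip(self, rng, tmp_path):
        agent = Agent(3, 1, hidden_dims=(8, 8), rng=rng)
        agent.save(tmp_path / "ckpt")
        other = Agent(3, 1, hidden_dims=(8, 8), rng=np.random.default_rng(999))
        other.load(tmp_path / "ckpt")
        s = rng.normal(size=3)
        assert np.array_equal(agent.select_action(s), other.select_action(s))

    def test_mismatch_rejected(self, rng, tmp_path):
        agent = Agent(3, 1, hidden_dims=(8, 8), rng=rng)
        agent.save(tmp_path / "ckpt")
        other = Agent(5, 1, hidden_dims=(8, 8), rng=rng)
        with pytest.raises(ValueError):
            other.load(tmp_path / "ckpt")


def run_bandit(c, seed, n_updates=2000):
    """Full DDPG loop on a single-state continuous bandit with reward
    -(a - c)^2; returns the greedy action after training.

    Exploration noise and the learning rate are annealed over the run,
    and the agent uses the saturation safeguards (leaky hidden units,
    bound-aware action gradients) so the tanh output layer cannot pin
    permanently at a bound.
    """
    rng = np.random.default_rng(seed)
    agent = Agent(
        1,
        1,
        hidden_dims=(64, 64),
        a_max=4.0,
        lr=0.01,
        gamma=0.99,
        tau=0.05,
        ou_sigma=0.2,
        bound_grad_scaling=True,
        hidden_activation="leaky_relu",
        squash_grad_floor=0.01,
        rng=rng,
    )
    buf = ReplayBuffer(2000, state_dim=1)
    s = np.zeros(1)
    for t in range(n_updates):
        f = t / n_updates
        agent.noise.sigma = max(0.3 * (1 - 1.2 * f), 0.05)
        if f > 0.5:  # cosine decay of both learning rates, second half
            g = 0.5 * (1 + np.cos(np.pi * (f - 0.5) / 0.5))
            agent.critic_opt.lr = agent.actor_opt.lr = 0.01 * (0.1 + 0.9 * g)
        a = agent.select_action(s, explore=True)
        r = -float((a[0] - c) ** 2)
        buf.push(s, a, r, s, True)
        if len(buf) >= 128:
            agent.update(buf.sample(128, rng))
    return float(agent.select_action(s)[0])


@pytest.mark.parametrize("c", [-1.0, 0.0, 2.0])
def test_bandit_convergence(c):
    ok = sum(abs(run_bandit(c, seed) - c) <= 0.05 for seed in (0, 1, 2))
    assert ok == 3
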