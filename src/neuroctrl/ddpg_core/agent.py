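"""DDPG agent: actor/critic pairs, target networks, and the two updates.

The critic is trained on the squared temporal-difference error against
the bootstrapped target ``y = r + gamma * Q_target(s', mu_target(s'))``
(bootstrap dropped on terminal transitions); the actor ascends the
deterministic policy gradient obtained by chaining ``dQ/da`` through the
actor.  Target copies track the live networks by Polyak averaging.

One :class:`Agent` instance can hold ``n_agents`` independent
actor-critic pairs of identical architecture (independent learners for
the multi-agent tasks); all updates are batched over that stack.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .nets import Adam, MLPSpec, MLPStack
from .noise import OUNoise
from .replay import Batch


class Agent:
    def __init__(
        self,
        state_dim: int,
        action_dim: int = 1,
        hidden_dims: tuple[int, int] = (400, 300),
        a_max: float = 1.0,
        gamma: float = 0.99,
        tau: float = 0.001,
        lr: float = 1e-3,
        ou_theta: float = 0.15,
        ou_sigma: float = 0.2,
        ou_dt: float = 1.0,
        n_agents: int = 1,
        bound_grad_scaling: bool = False,
        hidden_activation: str = "relu",
        squash_grad_floor: float = 0.0,
        dtype=np.float64,
        rng: np.random.Generator | None = None,
    ):
        if not (0.0 <= gamma <= 1.0):
            raise ValueError("gamma must be in [0, 1]")
        if not (0.0 <= tau <= 1.0):
            raise ValueError("tau must be in [0, 1]")
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.rng = rng if rng is not None else np.random.default_rng()
        self.state_dim = int(state_dim)
        self.action_dim = int(action_dim)
        self.n_agents = int(n_agents)
        self.a_max = float(a_max)
        self.gamma = float(gamma)
        self.tau = float(tau)
        self.lr = float(lr)
        self.bound_grad_scaling = bool(bound_grad_scaling)
        self.dtype = np.dtype(dtype)

        actor_spec = MLPSpec(
            state_dim, tuple(hidden_dims), action_dim, "bounded", a_max,
            hidden_activation=hidden_activation,
            squash_grad_floor=squash_grad_floor,
        )
        critic_spec = MLPSpec(
            state_dim + action_dim, tuple(hidden_dims), 1, "none",
            hidden_activation=hidden_activation,
        )
        self.actor = MLPStack(actor_spec, n_agents, self.rng, dtype=self.dtype)
        self.critic = MLPStack(critic_spec, n_agents, self.rng, dtype=self.dtype)
        self.target_actor = MLPStack(actor_spec, n_agents, self.rng, dtype=self.dtype)
        self.target_critic = MLPStack(critic_spec, n_agents, self.rng, dtype=self.dtype)
        self.target_actor.copy_from(self.actor)
        self.target_critic.copy_from(self.critic)

        self.actor_opt = Adam(lr=lr)
        self.critic_opt = Adam(lr=lr)
        # OU sigma is conventionally scaled by the action bound.
        self.noise = OUNoise(
            (n_agents, action_dim),
            theta=ou_theta,
            sigma=ou_sigma * self.a_max,
            dt=ou_dt,
            rng=self.rng,
        )

    # -- acting -------------------------------------------------------------

    def _as_stack_input(self, state: np.ndarray) -> np.ndarray:
        state = np.asarray(state, dtype=self.dtype)
        if state.ndim == 1:  # shared state vector
            if state.shape[0] != self.state_dim:
                raise ValueError(
                    f"state dimension {state.shape[0]} != actor input {self.state_dim}"
                )
            return state[None, :]  # (B=1, S), broadcast over the stack
        if state.shape != (self.n_agents, self.state_dim):
            raise ValueError(
                f"expected state of shape ({self.n_agents}, {self.state_dim}), got {state.shape}"
            )
        return state[:, None, :]  # (M, B=1, S)

    def select_action(self, state: np.ndarray, explore: bool = False) -> np.ndarray:
        """Deterministic policy output, plus OU noise when exploring.

        ``state`` is either one shared vector ``(S,)`` or per-agent
        vectors ``(M, S)``.  Returns ``(M, A)``, squeezed to ``(A,)``
        for a single-agent stack.
        """
        x = self._as_stack_input(state)
        a = self.actor.forward(x)
        a = np.broadcast_to(a, (self.n_agents, 1, self.action_dim))[:, 0, :].copy()
        if explore:
            a = np.clip(a + self.noise.step(), -self.a_max, self.a_max)
        if self.n_agents == 1:
            return a[0]
        return a

    def reset_noise(self) -> None:
        self.noise.reset()

    # -- learning -----------------------------------------------------------

    def _critic_input(self, states: np.ndarray, actions: np.ndarray) -> np.ndarray:
        states = np.asarray(states, dtype=self.dtype)
        actions = np.asarray(actions, dtype=self.dtype)
        if states.ndim == 2:  # shared (B, S) -> (M, B, S)
            states = np.broadcast_to(
                states[None], (self.n_agents, states.shape[0], states.shape[1])
            )
        return np.concatenate([states, actions], axis=-1)

    def td_target(self, batch: Batch) -> np.ndarray:
        """Bellman targets ``y`` of shape ``(M, B)`` with the bootstrap
        term evaluated by the *target* networks and dropped on terminal
        transitions."""
        if batch.rewards.size == 0:
            raise ValueError("empty batch")
        s2 = np.asarray(batch.next_states, dtype=self.dtype)
        a2 = self.target_actor.forward(s2 if s2.ndim == 3 else s2[None])
        if s2.ndim == 2:
            a2 = np.broadcast_to(a2, (self.n_agents, s2.shape[0], self.action_dim))
        q2 = self.target_critic.forward(self._critic_input(s2, a2))[..., 0]
        not_done = ~np.asarray(batch.terminals, dtype=bool)
        return batch.rewards + self.gamma * not_done * q2

    def critic_update(self, batch: Batch) -> float:
        """One Adam step on the mean squared TD error; returns the
        pre-update loss (mean over batch and stack)."""
        y = self.td_target(batch)  # (M, B)
        x = self._critic_input(batch.states, batch.actions)
        q, cache = self.critic.forward(x, want_cache=True)
        err = q[..., 0] - y
        loss = float(np.mean(err**2))
        b = err.shape[-1]
        dy = (2.0 / b) * err[..., None]
        grads, _ = self.critic.backward(cache, dy)
        self.critic_opt.step(self.critic.params, grads)
        return loss

    def actor_update(self, batch: Batch) -> float:
        """One Adam ascent step on ``mean_s Q(s, mu(s))`` with the critic
        frozen; returns the mean Q before the update."""
        if batch.rewards.size == 0:
            raise ValueError("empty batch")
        s = np.asarray(batch.states, dtype=self.dtype)
        a, a_cache = self.actor.forward(s if s.ndim == 3 else s[None], want_cache=True)
        if s.ndim == 2:
            a = np.broadcast_to(a, (self.n_agents, s.shape[0], self.action_dim))
        x = self._critic_input(s, a)
        q, q_cache = self.critic.forward(x, want_cache=True)
        mean_q = float(np.mean(q))
        b = q.shape[-2]
        # descend on -Q: upstream gradient -1/B per sample
        dq = np.full_like(q, -1.0 / b)
        _, dx = self.critic.backward(q_cache, dq)
        da = dx[..., self.state_dim :]
        if self.bound_grad_scaling:
            # "inverting gradients" (Hausknecht & Stone): damp the ascent
            # direction as the action approaches the bound it is pushed
            # towards, preventing permanent tanh saturation.
            ascent = -da
            up = (self.a_max - a) / (2.0 * self.a_max)
            down = (a + self.a_max) / (2.0 * self.a_max)
            da = -np.where(ascent > 0, ascent * up, ascent * down)
        grads, _ = self.actor.backward(a_cache, da)
        self.actor_opt.step(self.actor.params, grads)
        return mean_q

    def polyak_update(self) -> None:
        """``p_target <- tau * p_live + (1 - tau) * p_target``, exactly."""
        tau = self.tau
        if tau == 0.0:
            return
        for live, tgt in (
            (self.actor, self.target_actor),
            (self.critic, self.target_critic),
        ):
            for p_live, p_tgt in zip(live.params, tgt.params):
                if tau == 1.0:
                    p_tgt[...] = p_live
                else:
                    # difference form keeps p_t - old == tau*(live - old) exact
                    p_tgt += tau * (p_live - p_tgt)

    def update(self, batch: Batch) -> tuple[float, float]:
        """Convenience: one critic step, one actor step, one Polyak step."""
        loss = self.critic_update(batch)
        mean_q = self.actor_update(batch)
        self.polyak_update()
        return loss, mean_q

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write parameters as flat arrays (.npz) plus a JSON manifest."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for name, net in self._net_map().items():
            for i, p in enumerate(net.params):
                arrays[f"{name}_{i}"] = p
        np.savez(path / "params.npz", **arrays)
        manifest = {
            "state_dim": self.state_dim,
            "action_dim": self.action_dim,
            "hidden_dims": list(self.actor.spec.hidden_dims),
            "a_max": self.a_max,
            "gamma": self.gamma,
            "tau": self.tau,
            "lr": self.lr,
            "n_agents": self.n_agents,
            "shapes": {k: list(v.shape) for k, v in arrays.items()},
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    def load(self, path: str | Path) -> None:
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        if manifest["state_dim"] != self.state_dim or manifest["n_agents"] != self.n_agents:
            raise ValueError("checkpoint does not match agent architecture")
        with np.load(path / "params.npz") as data:
            for name, net in self._net_map().items():
                params = [data[f"{name}_{i}"] for i in range(len(net.params))]
                net.set_params(params)

    def _net_map(self) -> dict[str, MLPStack]:
        return {
            "actor": self.actor,
            "critic": self.critic,
            "target_actor": self.target_actor,
            "target_critic": self.target_critic,
        }
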