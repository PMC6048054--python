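"""The three closed-loop control environments.

Each task exposes the same surface to the learner: ``n_agents``
independent policies act simultaneously; ``reset()`` returns per-agent
state vectors (or one shared vector), ``step(actions)`` advances the
underlying simulator and returns ``(states, rewards, done)``.

* :class:`SpikeTrainTask` — fully actuated: one agent per SLIF cell
  injects current to reproduce a Poisson target spike train; per-cell
  match/mismatch reward.
* :class:`LatentTask` — under actuated: one agent per community of a
  symmetric block network steers the phase of the population activity
  projected onto leading principal components; shared half-circle
  phase-agreement reward.
* :class:`SyncTask` — one agent per non-reference Kuramoto oscillator
  applies phase increments; shaped reward mixing global order,
  synchronization with a reference oscillator, and an action-norm
  penalty.
"""

from __future__ import annotations

import numpy as np

from . import slif_model as slif
from . import kuramoto_model as km
from .latent_phase import (
    PCModel,
    estimate_phase,
    fit_pca,
    project,
    target_schedule,
)

__all__ = [
    "spike_reward",
    "phase_reward",
    "sync_reward",
    "accuracy",
    "SpikeTrainTask",
    "LatentTask",
    "SyncTask",
]


# ---------------------------------------------------------------------------
# reward functions


def spike_reward(s_next, h_next):
    """+1 for a correctly induced spike, -1 for any mismatch, 0 for
    correct silence.  Vectorized over binary arrays."""
    s = np.asarray(s_next)
    h = np.asarray(h_next)
    if not (np.isin(s, (0, 1)).all() and np.isin(h, (0, 1)).all()):
        raise ValueError("spike_reward expects binary inputs")
    r = np.where(s != h, -1.0, np.where(s == 1, 1.0, 0.0))
    if np.isscalar(s_next) or np.ndim(s_next) == 0:
        return float(r)
    return r


def phase_reward(phi_targ: float, phi_ctrl: float) -> float:
    """+1 iff both phases fall in the same half of the unit circle
    ([0, pi) vs [pi, 2*pi)), else -1."""
    same = (km.wrap_phase(phi_targ) < np.pi) == (km.wrap_phase(phi_ctrl) < np.pi)
    return 1.0 if same else -1.0


def sync_reward(q, q_ref_i, a_i, eps: float = 0.1, eta: float = 1.0,
                literal_action_sign: bool = False):
    """Shaped synchronization reward ``(q + eps*q' - eta*||a||_1)/(2+eps)``.

    The action-norm term is a penalty by default; the printed form with
    ``+eta*||a||_1`` (which would *favor* large actions) is available via
    ``literal_action_sign``.
    """
    norm = np.sum(np.abs(np.atleast_1d(a_i)), axis=-1)
    sign = 1.0 if literal_action_sign else -1.0
    r = (np.asarray(q) + eps * np.asarray(q_ref_i) + sign * eta * norm) / (2.0 + eps)
    if np.ndim(r) == 0:
        return float(r)
    return r


def accuracy(raster, targets) -> float:
    """Fraction of (cell, timestep) entries where raster equals target."""
    raster = np.asarray(raster)
    targets = np.asarray(targets)
    if raster.shape != targets.shape:
        raise ValueError("raster and targets must have matching shapes")
    return float(np.mean(raster == targets))


# ---------------------------------------------------------------------------
# fully-actuated spike-train induction


class SpikeTrainTask:
    """One agent per cell; state = own spike history ++ target lookahead."""

    shared_state = False
    action_dim = 1

    def __init__(
        self,
        network: slif.SlifNetwork,
        episode_len: int = 100,
        history_len: int = 10,
        lookahead_len: int = 10,
        target_rate: float = 0.15,
        a_max: float = 20.0,
        rng: np.random.Generator | None = None,
    ):
        self.network = network
        self.episode_len = int(episode_len)
        self.history_len = int(history_len)
        self.lookahead_len = int(lookahead_len)
        self.target_rate = float(target_rate)
        self.a_max = float(a_max)
        self.rng = rng if rng is not None else np.random.default_rng()
        self.n_agents = network.n_cells
        self.state_dim = self.history_len + self.lookahead_len
        self._state = None
        self.targets = None

    def reset(self) -> np.ndarray:
        """Resting potentials, cleared history, fresh Bernoulli targets
        (Bernoulli(rate) per cell and step approximates a small-rate
        Poisson train clipped to binary)."""
        n, T = self.n_agents, self.episode_len
        self._state = slif.SlifNetworkState.initial(self.network)
        # column t holds the target for step t (1-based); lookahead pads with 0
        self.targets = np.zeros((n, T + self.lookahead_len + 1), dtype=np.int8)
        self.targets[:, 1 : T + 1] = (
            self.rng.random(size=(n, T)) < self.target_rate
        ).astype(np.int8)
        self._history = np.zeros((n, self.history_len), dtype=np.int8)
        self._t = 0
        self.raster = np.zeros((n, T), dtype=np.int8)
        self.reward_trace = []
        return self._observe()

    def _observe(self) -> np.ndarray:
        look = self.targets[:, self._t + 1 : self._t + 1 + self.lookahead_len]
        return np.concatenate([self._history, look], axis=1).astype(float)

    def step(self, actions) -> tuple[np.ndarray, np.ndarray, bool]:
        actions = np.reshape(np.asarray(actions, dtype=float), (self.n_agents,))
        u = np.clip(actions, -self.a_max, self.a_max)
        slif.slif_step(self.network, self._state, u, rng=self.rng)
        spikes = self._state.spiked.astype(np.int8)
        self._t += 1
        self.raster[:, self._t - 1] = spikes
        rewards = spike_reward(spikes, self.targets[:, self._t])
        self._history = np.roll(self._history, -1, axis=1)
        self._history[:, -1] = spikes
        self.reward_trace.append(rewards)
        done = self._t >= self.episode_len
        return self._observe(), rewards, done

    def episode_accuracy(self) -> float:
        return accuracy(self.raster, self.targets[:, 1 : self.episode_len + 1])


# ---------------------------------------------------------------------------
# under-actuated latent-trajectory induction


class LatentTask:
    """One agent per community stimulates a single cell; the shared
    reward scores agreement between the target phase schedule and the
    phase of the population activity in PC space."""

    shared_state = False
    action_dim = 1

    def __init__(
        self,
        network: slif.SlifNetwork,
        n_communities: int,
        pc_dim: int = 1,
        period: int | None = None,
        episode_len: int = 100,
        history_len: int = 10,
        lookahead_len: int = 10,
        a_max: float = 20.0,
        r_max: float = 0.5,
        smoothing_window: int = 5,
        calibration_steps: int = 400,
        rng: np.random.Generator | None = None,
    ):
        if pc_dim not in (1, 2) or pc_dim > n_communities:
            raise ValueError("need pc_dim in {1, 2} and pc_dim <= n_communities")
        self.network = network
        self.n_communities = int(n_communities)
        self.pc_dim = int(pc_dim)
        self.period = int(period) if period else (40 if pc_dim == 1 else 60)
        self.episode_len = int(episode_len)
        self.history_len = int(history_len)
        self.lookahead_len = int(lookahead_len)
        self.a_max = float(a_max)
        self.r_max = float(r_max)
        self.smoothing_window = int(smoothing_window)
        self.calibration_steps = int(calibration_steps)
        self.rng = rng if rng is not None else np.random.default_rng()

        self.labels = slif.community_labels(network.n_cells, n_communities)
        self.actuated_cells = np.array(
            [
                self.rng.choice(np.flatnonzero(self.labels == c))
                for c in range(n_communities)
            ]
        )
        self.n_agents = self.n_communities
        self.state_dim = self.history_len + self.lookahead_len
        self.pc_model: PCModel | None = None
        # backward-difference step for the 1-D position-velocity phase
        self.lag = max(1, min(3, self.period // 4))

    # -- calibration --------------------------------------------------------

    def calibrate(self) -> PCModel:
        """Fit the principal components on a raster generated by random
        stimulation of the actuated cells; loadings are then frozen."""
        inputs = np.zeros((self.calibration_steps, self.network.n_cells))
        pulses = self.rng.random(size=(self.calibration_steps, self.n_communities))
        rates = np.linspace(0.3, 0.15, self.n_communities)  # distinct per block
        for c, cell in enumerate(self.actuated_cells):
            inputs[:, cell] = np.where(pulses[:, c] < rates[c], 10.0 * self.a_max, 0.0)
        raster, _, _ = slif.run_rollout(
            self.network, self.calibration_steps, inputs, rng=self.rng
        )
        self.pc_model = fit_pca(raster, self.pc_dim, self.smoothing_window)
        return self.pc_model

    # -- episode logic ------------------------------------------------------

    def _target_components(self) -> np.ndarray:
        """Per-community target waveform in [-1, 1], shape (T, n_comm).

        1-D: sin(phi_targ), so that a latent signal following the
        waveform sits at phase phi_targ under the position-velocity
        estimator.  2-D: the unit circle traced in the PC plane.
        """
        T = self.episode_len
        if self.pc_dim == 1:
            phases = target_schedule(1, self.period, T)
            comp = np.sin(phases)[:, None]
        else:
            _, curve = target_schedule(2, self.period, T)
            comp = curve
        # communities beyond pc_dim track the first component
        idx = np.minimum(np.arange(self.n_communities), self.pc_dim - 1)
        return comp[:, idx]

    def reset(self) -> np.ndarray:
        if self.pc_model is None:
            self.calibrate()
        n, T = self.network.n_cells, self.episode_len
        self._state = slif.SlifNetworkState.initial(self.network)
        self.target_phases = target_schedule(1, self.period, T)
        comp = self._target_components()
        rates = self.r_max * (1.0 + comp) / 2.0
        self._lookahead_bits = (
            self.rng.random(size=(T + self.lookahead_len, self.n_communities)) <
            np.vstack([rates, np.zeros((self.lookahead_len, self.n_communities))])
        ).astype(np.int8)
        self._history = np.zeros((self.n_communities, self.history_len), dtype=np.int8)
        self._t = 0
        self._spike_buffer = np.zeros((n, self.smoothing_window), dtype=np.int8)
        self._proj_history: list[np.ndarray] = []
        self._phase = 0.0
        self.raster = np.zeros((n, T), dtype=np.int8)
        self.control_phases = np.zeros(T)
        self.reward_trace = []
        return self._observe()

    def _observe(self) -> np.ndarray:
        look = self._lookahead_bits[self._t : self._t + self.lookahead_len].T
        return np.concatenate([self._history, look], axis=1).astype(float)

    def step(self, actions) -> tuple[np.ndarray, np.ndarray, bool]:
        actions = np.reshape(np.asarray(actions, dtype=float), (self.n_agents,))
        u = np.zeros(self.network.n_cells)
        u[self.actuated_cells] = np.clip(actions, -self.a_max, self.a_max)
        slif.slif_step(self.network, self._state, u, rng=self.rng)
        spikes = self._state.spiked.astype(np.int8)

        self._spike_buffer = np.roll(self._spike_buffer, -1, axis=1)
        self._spike_buffer[:, -1] = spikes
        proj = project(self.pc_model, self._spike_buffer)
        self._proj_history.append(proj)
        traj = np.asarray(self._proj_history)
        self._phase = estimate_phase(
            traj if self.pc_dim == 2 else traj[:, 0],
            k=self.pc_dim,
            lag=self.lag,
            prev_phase=self._phase,
            period=self.period,
        )

        self.raster[:, self._t] = spikes
        self.control_phases[self._t] = self._phase
        r = phase_reward(self.target_phases[self._t], self._phase)
        rewards = np.full(self.n_agents, r)
        self._history = np.roll(self._history, -1, axis=1)
        self._history[:, -1] = spikes[self.actuated_cells]
        self._t += 1
        self.reward_trace.append(rewards)
        done = self._t >= self.episode_len
        return self._observe(), rewards, done

    def episode_phase_accuracy(self) -> float:
        """Fraction of steps where the induced phase was in the target
        half-circle (chance level 0.5)."""
        hits = [
            phase_reward(pt, pc) > 0
            for pt, pc in zip(self.target_phases[: self._t], self.control_phases[: self._t])
        ]
        return float(np.mean(hits))


# ---------------------------------------------------------------------------
# Kuramoto synchronization by entrainment


class SyncTask:
    """One agent per non-reference oscillator; all agents observe one
    shared state (phase history of every oscillator plus the flattened
    adjacency matrix)."""

    shared_state = True
    action_dim = 1

    def __init__(
        self,
        network: km.KuramotoNetwork,
        history_len: int = 40,
        eps: float = 0.1,
        eta: float = 1.0,
        a_max: float = 0.5,
        episode_len: int = 500,
        phase_encoding: str = "raw",  # "raw" | "sincos"
        literal_action_sign: bool = False,
        reference_id: int | None = None,
        include_adjacency: bool = True,
        rng: np.random.Generator | None = None,
    ):
        if not (0.0 <= eps <= 1.0 and 0.0 <= eta <= 1.0):
            raise ValueError("eps and eta must lie in [0, 1]")
        if phase_encoding not in ("raw", "sincos"):
            raise ValueError(f"unknown phase_encoding {phase_encoding!r}")
        self.network = network
        self.history_len = int(history_len)
        self.eps = float(eps)
        self.eta = float(eta)
        self.a_max = float(a_max)
        self.episode_len = int(episode_len)
        self.phase_encoding = phase_encoding
        self.literal_action_sign = bool(literal_action_sign)
        self.rng = rng if rng is not None else np.random.default_rng()
        n = network.n_osc
        self.reference_id = (
            int(reference_id)
            if reference_id is not None
            else int(self.rng.integers(n))
        )
        self.controlled = np.array(
            [i for i in range(n) if i != self.reference_id]
        )
        self.n_agents = n - 1
        self.include_adjacency = bool(include_adjacency)
        per_step = n if phase_encoding == "raw" else 2 * n
        n_adj = n * n if self.include_adjacency else 0
        self.state_dim = self.history_len * per_step + n_adj
        self._adj_flat = (
            network.adjacency.ravel().astype(float)
            if self.include_adjacency
            else np.empty(0)
        )

    def _encode(self, phi: np.ndarray) -> np.ndarray:
        if self.phase_encoding == "raw":
            return phi
        return np.concatenate([np.cos(phi), np.sin(phi)])

    def reset(self) -> np.ndarray:
        n = self.network.n_osc
        self._state = km.KuramotoState.random(n, self.rng)
        per_step = n if self.phase_encoding == "raw" else 2 * n
        self._hist = np.zeros((self.history_len, per_step))
        self._hist[-1] = self._encode(self._state.phi)
        self._t = 0
        self.q_trace = []
        self.q_ref_trace = []
        self.reward_trace = []
        return self._observe()

    def _observe(self) -> np.ndarray:
        return np.concatenate([self._hist.ravel(), self._adj_flat])

    def step(self, actions) -> tuple[np.ndarray, np.ndarray, bool]:
        actions = np.reshape(np.asarray(actions, dtype=float), (self.n_agents,))
        a_full = np.zeros(self.network.n_osc)
        a_full[self.controlled] = np.clip(actions, -self.a_max, self.a_max)
        km.km_step(self.network, self._state, a_full)
        phi = self._state.phi
        q, _ = km.order_parameter(phi)
        q_ref = km.reference_sync(phi[self.controlled], phi[self.reference_id])
        rewards = sync_reward(
            q,
            q_ref,
            a_full[self.controlled, None],
            eps=self.eps,
            eta=self.eta,
            literal_action_sign=self.literal_action_sign,
        )
        self._hist = np.roll(self._hist, -1, axis=0)
        self._hist[-1] = self._encode(phi)
        self._t += 1
        self.q_trace.append(q)
        self.q_ref_trace.append(float(np.mean(q_ref)))
        self.reward_trace.append(rewards)
        done = self._t >= self.episode_len
        return self._observe(), rewards, done

    def mean_q(self) -> float:
        return float(np.mean(self.q_trace))

    def mean_q_ref(self) -> float:
        return float(np.mean(self.q_ref_trace))
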