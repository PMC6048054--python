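"""Bounded experience-replay buffer with uniform minibatch sampling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Transition:
    """One (s, a, r, s', terminal) tuple for a single agent."""

    state: np.ndarray
    action: np.ndarray
    reward: float
    next_state: np.ndarray
    terminal: bool

    def __post_init__(self):
        if np.shape(self.state) != np.shape(self.next_state):
            raise ValueError("state and next_state must have equal dimension")


@dataclass
class Batch:
    """Stacked minibatch.  ``states`` is ``(B, S)`` when shared across the
    agent stack, or ``(M, B, S)`` when per-agent; actions are
    ``(M, B, A)``, rewards and terminals ``(M, B)`` / ``(B,)``."""

    states: np.ndarray
    actions: np.ndarray
    rewards: np.ndarray
    next_states: np.ndarray
    terminals: np.ndarray


class ReplayBuffer:
    """FIFO ring buffer over preallocated arrays.

    ``n_agents`` adds a leading stack axis to actions/rewards (and to
    states unless ``shared_state`` is set, in which case one state vector
    per timestep is stored and shared by every agent — the multi-agent
    synchronization task observes a single global state).
    """

    def __init__(
        self,
        capacity: int,
        state_dim: int,
        action_dim: int = 1,
        n_agents: int = 1,
        shared_state: bool = False,
    ):
        if capacity <= 0:
            raise ValueError("capacity must be positive")
        self.capacity = int(capacity)
        self.n_agents = int(n_agents)
        self.shared_state = bool(shared_state)
        s_shape = (capacity, state_dim) if shared_state else (capacity, n_agents, state_dim)
        self._s = np.zeros(s_shape)
        self._a = np.zeros((capacity, n_agents, action_dim))
        self._r = np.zeros((capacity, n_agents))
        self._s2 = np.zeros_like(self._s)
        self._done = np.zeros(capacity, dtype=bool)
        self._size = 0
        self._cursor = 0

    def __len__(self) -> int:
        return self._size

    def push(self, state, action, reward, next_state, terminal: bool) -> None:
        """Insert one timestep; evicts the oldest entry when full."""
        i = self._cursor
        self._s[i] = state
        self._a[i] = np.reshape(action, self._a.shape[1:])
        self._r[i] = reward
        self._s2[i] = next_state
        self._done[i] = terminal
        self._cursor = (self._cursor + 1) % self.capacity
        self._size = min(self._size + 1, self.capacity)

    def sample(self, batch_size: int, rng: np.random.Generator) -> Batch:
        """Uniform sample without replacement within the batch.

        The same timestep indices are used for every agent in the stack;
        agents learn independently, so the cross-agent coupling of the
        sample does not bias any individual update.
        """
        if self._size == 0:
            raise ValueError("cannot sample from an empty buffer")
        if batch_size > self._size:
            raise ValueError(f"batch_size {batch_size} exceeds buffer size {self._size}")
        idx = rng.choice(self._size, size=batch_size, replace=False)
        if self.shared_state:
            states = self._s[idx]
            next_states = self._s2[idx]
        else:
            # reorder to (M, B, S)
            states = np.swapaxes(self._s[idx], 0, 1)
            next_states = np.swapaxes(self._s2[idx], 0, 1)
        return Batch(
            states=states,
            actions=np.swapaxes(self._a[idx], 0, 1),
            rewards=self._r[idx].T,
            next_states=next_states,
            terminals=self._done[idx],
        )

    def contents(self) -> list[Transition]:
        """All stored transitions, oldest first (single-agent view of
        agent 0; mainly for testing the FIFO contract)."""
        order = (np.arange(self._size) + (self._cursor - self._size)) % self.capacity
        out = []
        for i in order:
            s = self._s[i] if self.shared_state else self._s[i, 0]
            s2 = self._s2[i] if self.shared_state else self._s2[i, 0]
            out.append(
                Transition(
                    state=s.copy(),
                    action=self._a[i, 0].copy(),
                    reward=float(self._r[i, 0]),
                    next_state=s2.copy(),
                    terminal=bool(self._done[i]),
                )
            )
        return out
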