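"""Kuramoto oscillator network with additive phase control.

Forward-Euler update for oscillator ``i``:

    phi_i <- wrap(phi_i + dt * [omega_i + (K/N) sum_j A_ij rho(phi_j - phi_i)] + a_i)

where ``a_i`` is the per-step control-phase increment (the cumulative
control phase is tracked separately).  Synchronization is measured by
the modulus of the mean unit phasor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

TWO_PI = 2.0 * np.pi

__all__ = [
    "KuramotoNetwork",
    "KuramotoState",
    "km_step",
    "order_parameter",
    "reference_sync",
    "generate_km_network",
    "inversion_increment",
    "wrap_phase",
]


def wrap_phase(phi):
    """Reduce phases to [0, 2*pi)."""
    return np.mod(phi, TWO_PI)


@dataclass(frozen=True)
class KuramotoNetwork:
    n_osc: int
    K: float
    adjacency: np.ndarray  # (N, N) weights in [0, 1]
    omega: np.ndarray  # natural frequencies
    dt: float = 0.01
    rho: Callable = np.sin

    def __post_init__(self) -> None:
        if self.n_osc < 2:
            raise ValueError("need at least 2 oscillators")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        a = np.asarray(self.adjacency, dtype=float)
        w = np.asarray(self.omega, dtype=float)
        if a.shape != (self.n_osc, self.n_osc):
            raise ValueError("adjacency must be N x N")
        if w.shape != (self.n_osc,):
            raise ValueError("omega must have length N")
        object.__setattr__(self, "adjacency", a)
        object.__setattr__(self, "omega", w)


@dataclass
class KuramotoState:
    phi: np.ndarray  # phases in [0, 2*pi)
    phi_ctrl: np.ndarray  # cumulative control phase (unwrapped)
    t: int = 0

    @classmethod
    def random(cls, n_osc: int, rng: np.random.Generator) -> "KuramotoState":
        return cls(
            phi=rng.uniform(0.0, TWO_PI, size=n_osc),
            phi_ctrl=np.zeros(n_osc),
        )


def coupling_drive(net: KuramotoNetwork, phi: np.ndarray) -> np.ndarray:
    """(K/N) * sum_j A_ij * rho(phi_j - phi_i) for every i."""
    diff = phi[None, :] - phi[:, None]
    return (net.K / net.n_osc) * np.sum(net.adjacency * net.rho(diff), axis=1)


def km_step(net: KuramotoNetwork, state: KuramotoState, a: np.ndarray) -> KuramotoState:
    """Advance one Euler step with control-phase increments ``a``.

    Mutates and returns ``state``; the cumulative control phase
    accumulates ``a``.
    """
    a = np.asarray(a, dtype=float)
    if a.shape != (net.n_osc,):
        raise ValueError(f"control increment must have shape ({net.n_osc},)")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite control increment")
    drift = net.omega + coupling_drive(net, state.phi)
    state.phi = wrap_phase(state.phi + net.dt * drift + a)
    state.phi_ctrl = state.phi_ctrl + a
    state.t += 1
    return state


def order_parameter(phi: np.ndarray) -> tuple[float, float]:
    """Modulus ``q`` and argument ``psi`` of the mean unit phasor."""
    phi = np.asarray(phi, dtype=float)
    if phi.size == 0:
        raise ValueError("empty phase vector")
    z = np.mean(np.exp(1j * phi))
    return float(np.abs(z)), float(wrap_phase(np.angle(z)))


def reference_sync(phi_i, phi_ref) -> np.ndarray | float:
    """Two-oscillator order parameter |cos((phi_i - phi_ref)/2)|,
    vectorized over ``phi_i``."""
    val = np.abs(np.cos((np.asarray(phi_i, dtype=float) - phi_ref) / 2.0))
    if np.isscalar(phi_i) or np.ndim(phi_i) == 0:
        return float(val)
    return val


def generate_km_network(
    n_osc: int = 20,
    K: float = 0.1,
    omega_std: float = 10.0,
    rng: np.random.Generator | None = None,
    dt: float = 0.01,
) -> tuple[KuramotoNetwork, KuramotoState]:
    """Random symmetric network (weights iid U[0,1], zero diagonal),
    natural frequencies iid N(0, omega_std^2), uniform random initial
    phases."""
    if n_osc < 2:
        raise ValueError("n_osc must be >= 2")
    rng = rng if rng is not None else np.random.default_rng()
    a = np.zeros((n_osc, n_osc))
    iu = np.triu_indices(n_osc, k=1)
    a[iu] = rng.uniform(0.0, 1.0, size=len(iu[0]))
    a = a + a.T
    omega = rng.normal(0.0, omega_std, size=n_osc)
    net = KuramotoNetwork(n_osc=n_osc, K=K, adjacency=a, omega=omega, dt=dt)
    state = KuramotoState.random(n_osc, rng)
    return net, state


def inversion_increment(
    net: KuramotoNetwork, state: KuramotoState, phi_target: np.ndarray
) -> np.ndarray:
    """Control increment that reaches ``phi_target`` at the next step.

    Solving the discretized update for the control term gives
    ``a = phi_target - phi - dt * (omega + coupling)``; feeding the
    result to :func:`km_step` reproduces the target exactly (mod 2*pi).
    """
    drift = net.omega + coupling_drive(net, state.phi)
    return np.asarray(phi_target, dtype=float) - state.phi - net.dt * drift
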