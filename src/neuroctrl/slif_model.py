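"""Network of stochastic leaky integrate-and-fire (SLIF) neurons.

Membrane dynamics (forward Euler-Maruyama, one cell ``i``):

    V_i <- V_i + dt * [ -(V_i - V_leak)/tau_v
                        + (b*u_i + sum_j A_ij * I_syn_j) / C ]
           + eta * sqrt(dt) * z_i

where the synaptic current from cell ``j`` is an alpha-conductance
current ``I_syn_j = -g_j(t) * (V_i - E_syn)`` with
``g_j(t) = g_bar * (t - t_s)/tau_s * exp(-(t - t_s)/tau_s)`` summed over
``j``'s recent spikes.  Cells crossing ``v_thresh`` spike and reset to
``v_rest``.

The leak target is configurable: ``leak_mode="rest"`` (default) decays
toward the resting potential so that the standard rest/threshold
constants are meaningful; ``leak_mode="zero"`` decays toward 0 (the
literal first term of the membrane equation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SlifParams",
    "SlifNetwork",
    "SlifNetworkState",
    "alpha_conductance",
    "conductance_vector",
    "synaptic_current",
    "slif_step",
    "generate_network",
    "run_rollout",
]

# spikes older than this many synaptic time constants contribute
# relative conductance < 5e-4 and are dropped
SYNAPTIC_MEMORY_TAUS = 10.0


@dataclass(frozen=True)
class SlifParams:
    tau_v: float = 15.0
    C: float = 10.0
    v_rest: float = -70.0
    v_thresh: float = -50.0
    refractory_len: int = 0
    tau_s: float = 1.0
    g_bar: float = 0.01
    e_syn: float = 70.0
    noise_eta: float = math.sqrt(2.0)
    dt: float = 1.0
    b: float = 1.0
    leak_mode: str = "rest"  # "rest" | "zero"

    def __post_init__(self) -> None:
        if self.v_rest >= self.v_thresh:
            raise ValueError("v_rest must be below v_thresh")
        if min(self.tau_v, self.tau_s, self.C, self.dt) <= 0:
            raise ValueError("time constants, capacitance and dt must be positive")
        if self.leak_mode not in ("rest", "zero"):
            raise ValueError(f"unknown leak_mode {self.leak_mode!r}")

    @property
    def memory_steps(self) -> int:
        return int(np.ceil(SYNAPTIC_MEMORY_TAUS * self.tau_s / self.dt))


@dataclass(frozen=True)
class SlifNetwork:
    n_cells: int
    adjacency: np.ndarray  # (n, n) nonnegative weights, zero diagonal
    params: SlifParams = field(default_factory=SlifParams)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.shape != (self.n_cells, self.n_cells):
            raise ValueError("adjacency must be n_cells x n_cells")
        if np.any(a < 0):
            raise ValueError("adjacency weights must be nonnegative")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        object.__setattr__(self, "adjacency", a)


@dataclass
class SlifNetworkState:
    """Mutable simulation state: membrane potentials, last-step spike
    indicators, per-cell spike times, and the bounded recent-spike ring
    used for the synaptic conductances."""

    v: np.ndarray
    spiked: np.ndarray
    spike_times: list[list[int]]
    t: int
    recent_spikes: np.ndarray  # (memory_steps, n) binary, row k = t - 1 - k
    refractory: np.ndarray

    @classmethod
    def initial(cls, network: SlifNetwork) -> "SlifNetworkState":
        n = network.n_cells
        p = network.params
        return cls(
            v=np.full(n, p.v_rest),
            spiked=np.zeros(n, dtype=np.int8),
            spike_times=[[] for _ in range(n)],
            t=0,
            recent_spikes=np.zeros((p.memory_steps, n), dtype=np.int8),
            refractory=np.zeros(n, dtype=int),
        )


def alpha_conductance(t_elapsed, params: SlifParams):
    """Alpha-function conductance ``g_bar * (t/tau_s) * exp(-t/tau_s)``.

    Vectorized over ``t_elapsed``; non-positive elapsed times contribute
    zero (a spike in the future, or at the current instant, has no
    conductance yet).  Peaks at ``t_elapsed == tau_s``.
    """
    te = np.asarray(t_elapsed, dtype=float)
    out = np.where(
        te > 0.0,
        params.g_bar * (te / params.tau_s) * np.exp(-te / params.tau_s),
        0.0,
    )
    if np.isscalar(t_elapsed):
        return float(out)
    return out


def conductance_vector(state: SlifNetworkState, params: SlifParams) -> np.ndarray:
    """Per-cell total synaptic conductance from each cell's recent
    spikes (contributions from multiple spikes sum)."""
    k = np.arange(1, params.memory_steps + 1)
    kernel = alpha_conductance(k * params.dt, params)  # (memory,)
    return kernel @ state.recent_spikes


def synaptic_current(network: SlifNetwork, state: SlifNetworkState, i: int | None = None):
    """Weighted synaptic current ``sum_j A_ij * (-g_j * (V_i - E_syn))``.

    Returns the full vector when ``i`` is None, else the scalar for
    cell ``i``.
    """
    g = conductance_vector(state, network.params)
    drive = network.adjacency @ g  # (n,)
    currents = drive * (network.params.e_syn - state.v)
    if i is None:
        return currents
    return float(currents[i])


def slif_step(
    network: SlifNetwork,
    state: SlifNetworkState,
    u: np.ndarray,
    rng: np.random.Generator | None = None,
) -> SlifNetworkState:
    """Advance the network one Euler-Maruyama step with input ``u``.

    Mutates and returns ``state``.  ``rng`` is required when the noise
    amplitude is nonzero.
    """
    p = network.params
    u = np.asarray(u, dtype=float)
    if u.shape != (network.n_cells,):
        raise ValueError(f"input must have shape ({network.n_cells},)")
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite input")

    i_syn = synaptic_current(network, state)
    v_leak = p.v_rest if p.leak_mode == "rest" else 0.0
    dv = p.dt * (-(state.v - v_leak) / p.tau_v + (p.b * u + i_syn) / p.C)
    if p.noise_eta > 0:
        if rng is None:
            raise ValueError("rng required when noise_eta > 0")
        dv = dv + p.noise_eta * np.sqrt(p.dt) * rng.standard_normal(network.n_cells)

    active = state.refractory == 0
    state.v = np.where(active, state.v + dv, state.v)

    fired = active & (state.v >= p.v_thresh)
    state.spiked = fired.astype(np.int8)
    state.v = np.where(fired, p.v_rest, state.v)
    if p.refractory_len > 0:
        state.refractory = np.maximum(state.refractory - 1, 0)
        state.refractory[fired] = p.refractory_len
    for i in np.flatnonzero(fired):
        state.spike_times[i].append(state.t)

    # ring update: row 0 is the most recent step
    state.recent_spikes = np.roll(state.recent_spikes, 1, axis=0)
    state.recent_spikes[0] = state.spiked
    state.t += 1
    return state


def generate_network(
    n_cells: int,
    topology: str = "directed-random",
    n_communities: int | None = None,
    rng: np.random.Generator | None = None,
    p_cross: float = 0.05,
    w_cross: float = 0.1,
    params: SlifParams | None = None,
) -> SlifNetwork:
    """Random network generators.

    ``directed-random``: all off-diagonal weights iid U[0, 1].
    ``block-community``: symmetric; within-block weights iid U[0, 1];
    each cross-block (unordered) pair gets weight 0 with probability
    ``1 - p_cross``, else iid U[0, w_cross].  Blocks are as equal as
    possible.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    params = params if params is not None else SlifParams()

    if topology == "directed-random":
        a = rng.uniform(0.0, 1.0, size=(n_cells, n_cells))
        np.fill_diagonal(a, 0.0)
    elif topology == "block-community":
        if not n_communities or n_communities < 1 or n_communities > n_cells:
            raise ValueError("block-community requires 1 <= n_communities <= n_cells")
        labels = community_labels(n_cells, n_communities)
        same = labels[:, None] == labels[None, :]
        a = np.zeros((n_cells, n_cells))
        iu = np.triu_indices(n_cells, k=1)
        within = rng.uniform(0.0, 1.0, size=len(iu[0]))
        crossed = rng.random(len(iu[0])) < p_cross
        cross_w = rng.uniform(0.0, w_cross, size=len(iu[0]))
        vals = np.where(same[iu], within, np.where(crossed, cross_w, 0.0))
        a[iu] = vals
        a = a + a.T
    else:
        raise ValueError(f"unknown topology {topology!r}")
    return SlifNetwork(n_cells=n_cells, adjacency=a, params=params)


def community_labels(n_cells: int, n_communities: int) -> np.ndarray:
    """Contiguous, as-equal-as-possible block assignment."""
    if n_communities < 1 or n_communities > n_cells:
        raise ValueError("need 1 <= n_communities <= n_cells")
    sizes = np.full(n_communities, n_cells // n_communities)
    sizes[: n_cells % n_communities] += 1
    return np.repeat(np.arange(n_communities), sizes)


def run_rollout(
    network: SlifNetwork,
    n_steps: int,
    inputs: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    state: SlifNetworkState | None = None,
):
    """Simulate ``n_steps`` with per-step inputs (default zero).

    Returns ``(raster, v_trace, state)`` where ``raster`` is
    ``(n_cells, n_steps)`` binary and ``v_trace`` holds the end-of-step
    membrane potentials (reset applied on spike steps).
    """
    n = network.n_cells
    if inputs is None:
        inputs = np.zeros((n_steps, n))
    state = state if state is not None else SlifNetworkState.initial(network)
    raster = np.zeros((n, n_steps), dtype=np.int8)
    v_trace = np.zeros((n, n_steps))
    for t in range(n_steps):
        slif_step(network, state, inputs[t], rng=rng)
        raster[:, t] = state.spiked
        v_trace[:, t] = state.v
    return raster, v_trace, state


def raster_to_frame(raster: np.ndarray):
    """Spike raster as a tidy (cell_id, timestep) table."""
    import pandas as pd

    cells, steps = np.nonzero(raster)
    return pd.DataFrame({"cell_id": cells, "timestep": steps})
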