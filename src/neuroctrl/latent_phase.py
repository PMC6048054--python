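"""Latent phase-space analysis of spike rasters.

A raster is smoothed per cell (centered moving average) into an
instantaneous firing rate, mean-centered, and decomposed by PCA; the
leading one or two components define the latent plane in which target
oscillations are induced.  Phase is read off the projection: directly by
``atan2`` for two components, via the position-velocity convention for
one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kuramoto_model import wrap_phase

__all__ = [
    "PCModel",
    "fit_pca",
    "project",
    "estimate_phase",
    "target_schedule",
    "recover_communities",
    "smooth_raster",
]


@dataclass(frozen=True)
class PCModel:
    loadings: np.ndarray  # (n_cells, k), orthonormal columns
    mean: np.ndarray  # (n_cells,)
    explained_variance: np.ndarray  # (k,), non-increasing
    smoothing_window: int

    def __post_init__(self) -> None:
        l = np.asarray(self.loadings, dtype=float)
        if not np.allclose(l.T @ l, np.eye(l.shape[1]), atol=1e-8):
            raise ValueError("loadings must be orthonormal")

    @property
    def n_cells(self) -> int:
        return self.loadings.shape[0]

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


def smooth_raster(raster: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along time for each cell (edges use the
    zero-padded window, matching ``np.convolve`` 'same')."""
    if window < 1:
        raise ValueError("window must be >= 1")
    kernel = np.ones(window) / window
    return np.apply_along_axis(lambda x: np.convolve(x, kernel, mode="same"), 1,
                               np.asarray(raster, dtype=float))


def fit_pca(raster: np.ndarray, k: int, smoothing_window: int = 5) -> PCModel:
    """PCA of the smoothed, mean-centered raster.

    Eigendecomposition of the cell-by-cell covariance; the top-``k``
    eigenvectors are returned with a deterministic sign convention (the
    largest-magnitude loading of each component is positive).
    """
    raster = np.asarray(raster, dtype=float)
    n_cells, T = raster.shape
    if k > n_cells:
        raise ValueError(f"k={k} exceeds the number of cells {n_cells}")
    if np.all(raster == raster[:, :1]):
        raise ValueError("raster is constant in time; no principal directions")
    rates = smooth_raster(raster, smoothing_window)
    mean = rates.mean(axis=1)
    centered = rates - mean[:, None]
    cov = (centered @ centered.T) / max(T - 1, 1)
    if np.allclose(cov, 0.0):
        raise ValueError("raster has zero covariance; no principal directions")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:k]
    loadings = evecs[:, order]
    evals = evals[order]
    # sign convention: largest-|loading| entry positive
    for j in range(k):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    return PCModel(
        loadings=loadings,
        mean=mean,
        explained_variance=np.maximum(evals, 0.0),
        smoothing_window=int(smoothing_window),
    )


def project(model: PCModel, spikes_window: np.ndarray) -> np.ndarray:
    """Project the population rate at the end of a spike window.

    ``spikes_window`` is ``(n_cells, w)`` with ``w >= smoothing_window``;
    the last ``smoothing_window`` columns are averaged into the
    instantaneous rate (a trailing estimate of the centered moving
    average), centered with the stored mean, and multiplied by the
    loadings.
    """
    w = np.asarray(spikes_window, dtype=float)
    if w.ndim != 2 or w.shape[0] != model.n_cells:
        raise ValueError(f"window must be ({model.n_cells}, >= {model.smoothing_window})")
    if w.shape[1] < model.smoothing_window:
        raise ValueError("window shorter than the smoothing window")
    rate = w[:, -model.smoothing_window :].mean(axis=1)
    return model.loadings.T @ (rate - model.mean)


def estimate_phase(
    trajectory: np.ndarray,
    k: int,
    lag: int | None = None,
    prev_phase: float = 0.0,
    period: float | None = None,
) -> float:
    """Phase angle of the latest projection.

    ``k = 2``: ``atan2(pc2, pc1)`` of the last sample.

    ``k = 1``: position-velocity phase ``atan2(x, xdot / omega0)`` with
    the derivative approximated by a ``lag``-step backward difference
    and ``omega0 = 2*pi/period`` — the standard phase convention for a
    scalar oscillator.  For ``x = cos(omega0 t)`` it returns
    ``omega0 t + pi/2`` (counterclockwise, advancing 2*pi per cycle) and
    places the phase in the lower half-circle exactly when ``x > 0``, so
    half-circle membership responds to the *instantaneous* signal value
    rather than a quarter-period-old one.

    A zero-magnitude embedding carries ``prev_phase`` forward.
    """
    traj = np.asarray(trajectory, dtype=float)
    if k == 2:
        traj = traj.reshape(-1, 2)
        x, y = traj[-1, 0], traj[-1, 1]
        if x == 0.0 and y == 0.0:
            return prev_phase
        return float(wrap_phase(np.arctan2(y, x)))
    if k == 1:
        vals = traj.reshape(-1)
        if lag is None or period is None:
            raise ValueError("k=1 phase estimation requires lag and period")
        if len(vals) < lag + 1:
            return prev_phase
        x_t = vals[-1]
        dx = (vals[-1] - vals[-1 - lag]) * period / (2.0 * np.pi * lag)
        if x_t == 0.0 and dx == 0.0:
            return prev_phase
        return float(wrap_phase(np.arctan2(x_t, dx)))
    raise ValueError("k must be 1 or 2")


def target_schedule(pc_dim: int, period: int, T: int):
    """Target phase sequence ``wrap(2*pi*t/period)`` for ``t < T``;
    for ``pc_dim = 2`` also the unit circle traced in the PC plane."""
    if period < 4:
        raise ValueError("period must be >= 4")
    if T < period:
        raise ValueError("schedule must cover at least one period")
    t = np.arange(T)
    phases = wrap_phase(2.0 * np.pi * t / period)
    if pc_dim == 1:
        return phases
    if pc_dim == 2:
        curve = np.stack([np.cos(phases), np.sin(phases)], axis=1)
        return phases, curve
    raise ValueError("pc_dim must be 1 or 2")


def recover_communities(model: PCModel) -> np.ndarray:
    """Assign each cell to the component with the largest absolute
    loading — exact community recovery for block-diagonal covariance."""
    return np.argmax(np.abs(model.loadings), axis=1)
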