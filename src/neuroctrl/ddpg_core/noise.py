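"""Ornstein-Uhlenbeck exploration noise (Euler-Maruyama discretization)."""

from __future__ import annotations

import numpy as np


class OUNoise:
    """Mean-zero OU process, one component per action dimension.

    The update is ``x <- x + theta * (0 - x) * dt + sigma * sqrt(dt) * z``
    with ``z`` standard normal, giving stationary variance
    ``sigma**2 / (2 * theta)``.  ``shape`` may be multi-dimensional, e.g.
    ``(n_agents, action_dim)``.
    """

    def __init__(
        self,
        shape,
        theta: float = 0.15,
        sigma: float = 0.2,
        dt: float = 1.0,
        rng: np.random.Generator | None = None,
    ):
        if theta <= 0 or sigma < 0 or dt <= 0:
            raise ValueError("theta and dt must be positive; sigma must be >= 0")
        self.shape = tuple(np.atleast_1d(shape))
        self.theta = float(theta)
        self.sigma = float(sigma)
        self.dt = float(dt)
        self.rng = rng if rng is not None else np.random.default_rng()
        self.x = np.zeros(self.shape)

    @property
    def stationary_variance(self) -> float:
        if self.sigma == 0:
            return 0.0
        return self.sigma**2 / (2.0 * self.theta)

    def reset(self) -> None:
        self.x[...] = 0.0

    def step(self) -> np.ndarray:
        z = self.rng.standard_normal(self.shape)
        self.x = (
            self.x
            + self.theta * (0.0 - self.x) * self.dt
            + self.sigma * np.sqrt(self.dt) * z
        )
        return self.x.copy()
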