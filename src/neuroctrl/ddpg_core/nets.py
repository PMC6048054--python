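"""Dense networks and the Adam optimizer used by the DDPG agent.

Everything here operates on *stacked* parameter tensors with a leading
stack axis ``M`` so that ``M`` independent networks of identical shape
(one per controlled unit in the multi-agent tasks) evaluate and train
with a handful of batched matmuls instead of a Python loop.  A single
network is simply the ``M = 1`` case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DTYPE = np.float64


@dataclass(frozen=True)
class MLPSpec:
    """Architecture of a two-hidden-layer dense network.

    ``output_squash`` is either ``"none"`` (critic: unbounded value
    output) or ``"bounded"`` (actor: tanh scaled to
    ``[-output_scale, output_scale]``).
    """

    input_dim: int
    hidden_dims: tuple[int, int]
    output_dim: int
    output_squash: str = "none"  # "none" | "bounded"
    output_scale: float = 1.0
    hidden_activation: str = "relu"  # "relu" | "leaky_relu"
    leak: float = 0.01
    # lower bound on the tanh derivative used in backprop; a small
    # positive value lets a fully saturated actor recover (the forward
    # pass is unchanged)
    squash_grad_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.input_dim <= 0 or self.output_dim <= 0:
            raise ValueError("input_dim and output_dim must be positive")
        if len(self.hidden_dims) != 2 or any(h <= 0 for h in self.hidden_dims):
            raise ValueError("hidden_dims must be exactly two positive layer sizes")
        if self.output_squash not in ("none", "bounded"):
            raise ValueError(f"unknown output_squash {self.output_squash!r}")
        if self.output_squash == "bounded" and self.output_scale <= 0:
            raise ValueError("output_scale must be positive for bounded output")
        if self.hidden_activation not in ("relu", "leaky_relu"):
            raise ValueError(f"unknown hidden_activation {self.hidden_activation!r}")


class MLPStack:
    """``n_stack`` independent MLPs sharing one architecture.

    Parameters are lists of ``(W, b)`` with ``W`` shaped
    ``(M, fan_in, fan_out)`` and ``b`` shaped ``(M, 1, fan_out)``.
    Hidden layers use ReLU; hidden weights are fan-in-uniform
    initialized, final layers use small uniform weights so initial
    outputs are near zero.
    """

    FINAL_INIT = 3e-3

    def __init__(
        self,
        spec: MLPSpec,
        n_stack: int,
        rng: np.random.Generator,
        dtype=DTYPE,
    ):
        self.spec = spec
        self.n_stack = int(n_stack)
        self.dtype = np.dtype(dtype)
        dims = [spec.input_dim, *spec.hidden_dims, spec.output_dim]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for li, (din, dout) in enumerate(zip(dims[:-1], dims[1:])):
            last = li == len(dims) - 2
            bound = self.FINAL_INIT if last else 1.0 / np.sqrt(din)
            w = rng.uniform(-bound, bound, size=(n_stack, din, dout)).astype(self.dtype)
            b = rng.uniform(-bound, bound, size=(n_stack, 1, dout)).astype(self.dtype)
            self.weights.append(w)
            self.biases.append(b)

    # -- parameter plumbing -------------------------------------------------

    @property
    def params(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for w, b in zip(self.weights, self.biases):
            out.extend((w, b))
        return out

    def set_params(self, params: list[np.ndarray]) -> None:
        for i in range(len(self.weights)):
            self.weights[i] = params[2 * i]
            self.biases[i] = params[2 * i + 1]

    def copy_from(self, other: "MLPStack") -> None:
        for p_self, p_other in zip(self.params, other.params):
            p_self[...] = p_other

    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Evaluate the stack on ``x`` of shape ``(M, B, input_dim)``.

        ``x`` may have leading shape ``(B, input_dim)`` shared by all
        stack members; broadcasting handles it without copies.
        """
        h = x
        cache = [h]
        pre = []
        for li, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = np.matmul(h, w) + b
            last = li == len(self.weights) - 1
            if not last:
                if self.spec.hidden_activation == "leaky_relu":
                    h = np.where(z > 0.0, z, self.spec.leak * z)
                else:
                    h = np.maximum(z, 0.0)
            elif self.spec.output_squash == "bounded":
                h = self.spec.output_scale * np.tanh(z)
            else:
                h = z
            pre.append(z)
            cache.append(h)
        if want_cache:
            return h, (cache, pre)
        return h

    def backward(self, cache, dy: np.ndarray):
        """Backpropagate ``dy`` (same shape as the output).

        Returns ``(param_grads, dx)`` where ``param_grads`` matches the
        layout of :attr:`params` and gradients are *summed* over the
        batch axis (callers normalize).
        """
        activations, pre = cache
        grads: list[np.ndarray | None] = [None] * (2 * len(self.weights))
        delta = dy
        for li in reversed(range(len(self.weights))):
            z = pre[li]
            last = li == len(self.weights) - 1
            if last:
                if self.spec.output_squash == "bounded":
                    t = np.tanh(z)
                    dsq = np.maximum(1.0 - t * t, self.spec.squash_grad_floor)
                    delta = delta * self.spec.output_scale * dsq
            else:
                if self.spec.hidden_activation == "leaky_relu":
                    delta = delta * np.where(z > 0.0, 1.0, self.spec.leak)
                else:
                    delta = delta * (z > 0.0)
            # a_prev may be a shared (B, din) input; matmul broadcasts it
            # against the (M, B, dout) delta to give (M, din, dout).
            a_prev = activations[li]
            gw = np.matmul(np.swapaxes(a_prev, -1, -2), delta)
            gb = delta.sum(axis=-2, keepdims=True)
            grads[2 * li] = gw
            grads[2 * li + 1] = gb
            delta = np.matmul(delta, np.swapaxes(self.weights[li], -1, -2))
        return grads, delta


@dataclass
class Adam:
    """Adam with per-tensor state, operating on stacked parameters.

    The update is computed in-place through a per-tensor scratch buffer;
    mathematically it is the standard bias-corrected rule
    ``p -= lr * m_hat / (sqrt(v_hat) + eps)``.
    """

    lr: float
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: list = field(default_factory=list)
    v: list = field(default_factory=list)
    _scratch: list = field(default_factory=list)

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if not self.m:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
            self._scratch = [np.empty_like(p) for p in params]
        self.t += 1
        dt = params[0].dtype.type
        b1, b2 = dt(self.beta1), dt(self.beta2)
        one_m_b1, one_m_b2 = dt(1.0 - self.beta1), dt(1.0 - self.beta2)
        lr_corr = dt(self.lr / (1.0 - self.beta1 ** self.t))
        sqrt_inv_b2t = dt(1.0 / np.sqrt(1.0 - self.beta2 ** self.t))
        eps = dt(self.eps)
        for p, g, m, v, tmp in zip(params, grads, self.m, self.v, self._scratch):
            m *= b1
            np.multiply(g, one_m_b1, out=tmp)
            m += tmp
            v *= b2
            np.multiply(g, g, out=tmp)
            tmp *= one_m_b2
            v += tmp
            np.sqrt(v, out=tmp)
            tmp *= sqrt_inv_b2t
            tmp += eps
            np.divide(m, tmp, out=tmp)
            tmp *= lr_corr
            p -= tmp
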