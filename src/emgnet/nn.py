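"""Minimal NumPy neural-network engine.

Implements exactly the layers the compact CNN needs — 2-D convolution,
parametric/plain rectifiers, global pooling, flatten — together with a
softmax cross-entropy head and an Adam optimizer with an optional classic
L2 penalty.  Everything is deterministic given a seeded
``numpy.random.Generator``; there is no hidden global state.

Conventions
-----------
* Activations are ``(batch, channels, height, width)`` float64 arrays.
* ``forward`` caches whatever ``backward`` needs; ``backward`` receives the
  gradient of the scalar loss w.r.t. the layer output and returns the
  gradient w.r.t. the layer input, accumulating parameter gradients in
  ``layer.grads``.
* The L2 penalty is the classic formulation: ``l2 * sum(w ** 2)`` added to
  the data loss, i.e. a gradient contribution of ``2 * l2 * w``.  It is
  applied only to parameters named in ``layer.decay_params`` (convolution
  weights, never biases or rectifier slopes).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "PReLU",
    "ReLU",
    "GlobalAvgPool",
    "GlobalMaxPool",
    "Flatten",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


class Layer:
    """Base class: a layer owns ``params`` / ``grads`` dicts keyed by name."""

    decay_params: frozenset = frozenset()

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv2d(Layer):
    """2-D convolution (cross-correlation) via im2col."""

    decay_params = frozenset({"weight"})

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        if in_channels < 1 or out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if stride < 1 or kernel_size < 1 or padding < 0:
            raise ValueError("invalid kernel/stride/padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        # He fan-in init, suited to rectifier nets.
        self.params["weight"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(out_channels, fan_in)
        )
        if bias:
            self.params["bias"] = np.zeros(out_channels)
        self.zero_grad()

    def output_shape(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.kernel_size, self.stride, self.padding
        return ((h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1)

    def _im2col(self, xp: np.ndarray) -> np.ndarray:
        k, s = self.kernel_size, self.stride
        # (B, C, Ho, Wo, k, k) -> (B, Ho*Wo, C*k*k)
        windows = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        b, c, ho, wo = windows.shape[:4]
        cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho * wo, c * k * k)
        return np.ascontiguousarray(cols), (ho, wo)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (B, {self.in_channels}, H, W) input, got {x.shape}"
            )
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols, (ho, wo) = self._im2col(xp)
        out = cols @ self.params["weight"].T
        if "bias" in self.params:
            out = out + self.params["bias"]
        self._cache = (cols, x.shape, (ho, wo))
        return out.transpose(0, 2, 1).reshape(x.shape[0], self.out_channels, ho, wo)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        cols, x_shape, (ho, wo) = self._cache
        b, _, h, w = x_shape
        k, s, p = self.kernel_size, self.stride, self.padding
        g = grad_out.reshape(b, self.out_channels, ho * wo).transpose(0, 2, 1)
        self.grads["weight"] += np.einsum("blo,blf->of", g, cols)
        if "bias" in self.params:
            self.grads["bias"] += g.sum(axis=(0, 1))
        dcols = (g @ self.params["weight"]).reshape(b, ho, wo, self.in_channels, k, k)
        dxp = np.zeros((b, self.in_channels, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class PReLU(Layer):
    """Parametric rectifier; one slope per channel or one shared slope."""

    def __init__(self, n_channels: int, shared: bool = False, init: float = 0.25):
        super().__init__()
        n = 1 if shared else n_channels
        self.shared = shared
        self.params["alpha"] = np.full(n, init, dtype=float)
        self.zero_grad()

    def _alpha(self) -> np.ndarray:
        a = self.params["alpha"]
        return a.reshape(1, -1, 1, 1) if not self.shared else a.reshape(1, 1, 1, 1)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return np.where(x > 0, x, self._alpha() * x)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x = self._x
        neg = np.minimum(x, 0.0)
        if self.shared:
            self.grads["alpha"] += np.array([(grad_out * neg).sum()])
        else:
            self.grads["alpha"] += (grad_out * neg).sum(axis=(0, 2, 3))
        return np.where(x > 0, grad_out, self._alpha() * grad_out)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._mask


class GlobalAvgPool(Layer):
    """Adaptive mean pooling to a 1x1 spatial output."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3), keepdims=True)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        h, w = self._hw
        return np.broadcast_to(grad_out / (h * w), grad_out.shape[:2] + (h, w)).copy()


class GlobalMaxPool(Layer):
    """Adaptive max pooling to a 1x1 spatial output."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        flat = x.reshape(b, c, h * w)
        self._arg = flat.argmax(axis=2)
        self._shape = x.shape
        return flat.max(axis=2)[:, :, None, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        dx = np.zeros((b, c, h * w))
        bi, ci = np.meshgrid(np.arange(b), np.arange(c), indexing="ij")
        dx[bi, ci, self._arg] = grad_out[:, :, 0, 0]
        return dx.reshape(self._shape)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out.reshape(self._shape)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    __call__ = forward

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def named_parameters(self):
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                yield f"layer{i}.{name}", layer, name, p

    def n_parameters(self) -> int:
        return sum(layer.n_parameters() for layer in self.layers)

    def l2_penalty(self, l2: float) -> float:
        if l2 == 0:
            return 0.0
        return l2 * sum(
            float((layer.params[n] ** 2).sum())
            for layer in self.layers
            for n in layer.decay_params
            if n in layer.params
        )

    def add_l2_grads(self, l2: float) -> None:
        if l2 == 0:
            return
        for layer in self.layers:
            for n in layer.decay_params:
                if n in layer.params:
                    layer.grads[n] += 2.0 * l2 * layer.params[n]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.copy() for k, _, _, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, layer, name, p in self.named_parameters():
            if k not in state:
                raise KeyError(f"missing parameter {k!r} in state dict")
            if state[k].shape != p.shape:
                raise ValueError(
                    f"shape mismatch for {k!r}: expected {p.shape}, got {state[k].shape}"
                )
            layer.params[name] = np.asarray(state[k], dtype=float).copy()


class Adam:
    """Adam with bias correction; learning rate may change between steps."""

    def __init__(self, model: Sequential, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = {k: np.zeros_like(p) for k, _, _, p in model.named_parameters()}
        self._v = {k: np.zeros_like(p) for k, _, _, p in model.named_parameters()}

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, layer, name, p in self.model.named_parameters():
            g = layer.grads[name]
            m = self._m[k] = b1 * self._m[k] + (1 - b1) * g
            v = self._v[k] = b2 * self._v[k] + (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            layer.params[name] = p - lr * m_hat / (np.sqrt(v_hat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits.

    ``targets`` is an integer class-index vector of length B.
    """
    b = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    log_probs = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -float(log_probs[np.arange(b), targets].mean())
    grad = np.exp(log_probs)
    grad[np.arange(b), targets] -= 1.0
    return loss, grad / b
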