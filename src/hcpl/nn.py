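"""A compact neural-network stack on numpy.

Explicit forward/backward layers (convolution via im2col, linear, ReLU),
an Adam optimiser and a cosine-annealed learning-rate schedule — just
enough machinery to train the desk-scale classifiers in this package
end-to-end on a CPU. Arrays are float64; feature maps are batch-first
``(B, C, H, W)``.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base layer: forward caches what backward needs; grads accumulate."""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    b, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (b, c, k, k, ho, wo),
        (s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride),
    )
    cols = np.ascontiguousarray(view).reshape(b, c * k * k, ho * wo)
    return cols, ho, wo


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (c_in * k * k))  # He initialisation for ReLU trunks
        self.weight = Parameter(rng.normal(0.0, scale, size=(c_out, c_in * k * k)))
        self.bias = Parameter(np.zeros(c_out))
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        out = np.einsum("oc,bcl->bol", self.weight.value, cols, optimize=True)
        out += self.bias.value[None, :, None]
        self._cache = (x.shape, cols, ho, wo)
        return out.reshape(x.shape[0], self.c_out, ho, wo)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, cols, ho, wo = self._cache
        b = x_shape[0]
        g = grad.reshape(b, self.c_out, ho * wo)
        self.weight.grad += np.einsum("bol,bcl->oc", g, cols, optimize=True)
        self.bias.grad += g.sum(axis=(0, 2))
        dcols = np.einsum("oc,bol->bcl", self.weight.value, g, optimize=True)
        # col2im: scatter-add the k*k taps back onto the padded grid
        h_p = x_shape[2] + 2 * self.pad
        w_p = x_shape[3] + 2 * self.pad
        dx = np.zeros((b, self.c_in, h_p, w_p))
        dcols = dcols.reshape(b, self.c_in, self.k, self.k, ho, wo)
        for i in range(self.k):
            for j in range(self.k):
                dx[:, :, i:i + ho * self.stride:self.stride,
                   j:j + wo * self.stride:self.stride] += dcols[:, :, i, j]
        if self.pad:
            dx = dx[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return dx


class ReLU(Module):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Linear(Module):
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None,
                 zero_init: bool = False) -> None:
        rng = rng or np.random.default_rng(0)
        if zero_init:
            w = np.zeros((d_in, d_out))
        else:
            w = rng.normal(0.0, np.sqrt(1.0 / d_in), size=(d_in, d_out))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(d_out))
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value.T


# ---------------------------------------------------------------------------
# numerics

def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(np.asarray(z, dtype=float))
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy over rows; returns (loss, dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.mean(np.log(np.clip(p[np.arange(n), targets], 1e-12, None)))
    dlogits = p.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return loss, dlogits / n


# ---------------------------------------------------------------------------
# optimisation

class Adam:
    def __init__(self, params: list[Parameter], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad ** 2
            mh = m / (1 - self.b1 ** self.t)
            vh = v / (1 - self.b2 ** self.t)
            p.value -= self.lr * mh / (np.sqrt(vh) + self.eps)


def cosine_lr(epoch: int, n_epochs: int, lr0: float = 2e-4,
              lr_floor: float = 1e-6) -> float:
    """Cosine-annealed learning rate: ``lr0`` at epoch 0 decaying to the floor."""
    if n_epochs <= 1:
        return lr0
    t = epoch / (n_epochs - 1)
    return lr_floor + 0.5 * (lr0 - lr_floor) * (1.0 + np.cos(np.pi * t))
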