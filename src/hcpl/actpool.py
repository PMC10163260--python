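"""Learnable Weibull activation pooling.

The aggregation path shared by the dual-stream and cell-level classifiers:
a rectified convolutional feature tensor ``R`` (nonnegative) is passed
elementwise through the Weibull function

    ``T_i = (R_i / lambda)^(zeta - 1) * exp(-(R_i / gamma)^eta)``,

then global average pooling over the spatial grid produces a descriptor
``S``, whose entries are power normalised as ``alpha * s^beta``. All six
scalars (lambda, zeta, gamma, eta, alpha, beta) are learnable; positivity is
enforced by learning their logarithms. The Weibull transform dampens weak
uninformative responses while equalising a learnable proportion of strong
ones; the power normalisation balances the nonlinear scaling before the
classifier heads.

Functional forms live beside layer objects so they can be unit-tested
against analytic values and finite differences without a training loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Module, Parameter

EPS = 1e-8  # clamp before fractional powers; keeps gradients finite at 0


@dataclass
class WeibullParams:
    """The four positive scalars of the Weibull activation."""

    lam: float = 1.0
    zeta: float = 2.0
    gamma: float = 1.0
    eta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("lam", "zeta", "gamma", "eta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class PowerNormParams:
    alpha: float = 1.0
    beta: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be strictly positive")


# ---------------------------------------------------------------------------
# functional forms

def weibull_activation(R: np.ndarray, p: WeibullParams) -> np.ndarray:
    """Elementwise ``(R/lam)^(zeta-1) * exp(-(R/gamma)^eta)``."""
    R = np.asarray(R, dtype=float)
    if (R < 0).any() and float(p.zeta) != int(p.zeta):
        raise ValueError("negative inputs undefined for non-integer zeta")
    if (R < 0).any():
        raise ValueError("inputs must be nonnegative (rectified features)")
    x = np.maximum(R, EPS)
    T = (x / p.lam) ** (p.zeta - 1.0) * np.exp(-((x / p.gamma) ** p.eta))
    # exact zero stays zero when the power term vanishes (zeta > 1)
    if p.zeta > 1.0:
        T = np.where(R == 0.0, 0.0, T)
    return T


def weibull_gradients(R: np.ndarray, p: WeibullParams) -> dict[str, np.ndarray]:
    """Analytic partial derivatives of the Weibull activation.

    Returns elementwise derivatives w.r.t. the input ``R`` and each of the
    four parameters, evaluated at strictly positive ``R``.
    """
    x = np.maximum(np.asarray(R, dtype=float), EPS)
    T = weibull_activation(x, p)
    w = (x / p.gamma) ** p.eta
    return {
        "R": T * ((p.zeta - 1.0) / x - p.eta * w / x),
        "lam": T * (-(p.zeta - 1.0) / p.lam),
        "zeta": T * np.log(x / p.lam),
        "gamma": T * (p.eta / p.gamma) * w,
        "eta": T * (-w * np.log(x / p.gamma)),
    }


def global_average_pool(T: np.ndarray) -> np.ndarray:
    """Mean over the two leading spatial axes of a ``(W, H, D)`` tensor."""
    T = np.asarray(T, dtype=float)
    if T.ndim != 3:
        raise ValueError("expected a (W, H, D) tensor")
    return T.mean(axis=(0, 1))


def power_normalise(S: np.ndarray, p: PowerNormParams) -> np.ndarray:
    """Elementwise ``alpha * s^beta`` on a nonnegative descriptor."""
    S = np.asarray(S, dtype=float)
    if (S < 0).any():
        raise ValueError("descriptor entries must be nonnegative")
    return p.alpha * np.maximum(S, 0.0) ** p.beta


# ---------------------------------------------------------------------------
# trainable layers (batch-first: (B, D, H, W) feature maps, (B, D) vectors)

class WeibullActivationLayer(Module):
    """Trainable Weibull activation over a ``(B, D, H, W)`` feature map.

    Parameters are stored as logarithms so unconstrained gradient steps keep
    them positive. ``per_channel=True`` learns one set of four scalars per
    feature channel instead of a single shared set.
    """

    def __init__(self, n_channels: int = 1, per_channel: bool = False,
                 init: WeibullParams | None = None) -> None:
        init = init or WeibullParams()
        shape = (1, n_channels, 1, 1) if per_channel else (1, 1, 1, 1)
        self.log_lam = Parameter(np.full(shape, np.log(init.lam)))
        self.log_zeta = Parameter(np.full(shape, np.log(init.zeta)))
        self.log_gamma = Parameter(np.full(shape, np.log(init.gamma)))
        self.log_eta = Parameter(np.full(shape, np.log(init.eta)))
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.log_lam, self.log_zeta, self.log_gamma, self.log_eta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        lam = np.exp(self.log_lam.value)
        zeta = np.exp(self.log_zeta.value)
        gamma = np.exp(self.log_gamma.value)
        eta = np.exp(self.log_eta.value)
        xc = np.maximum(x, EPS)
        w = (xc / gamma) ** eta
        T = (xc / lam) ** (zeta - 1.0) * np.exp(-w)
        self._cache = (xc, lam, zeta, gamma, eta, w, T)
        return T

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xc, lam, zeta, gamma, eta, w, T = self._cache
        g = grad * T
        dx = g * ((zeta - 1.0) / xc - eta * w / xc)
        axes = tuple(i for i in range(4) if self.log_lam.value.shape[i] == 1)
        self.log_lam.grad += (g * (-(zeta - 1.0))).sum(axis=axes, keepdims=True)
        self.log_zeta.grad += (g * np.log(xc / lam) * zeta).sum(axis=axes, keepdims=True)
        self.log_gamma.grad += (g * eta * w).sum(axis=axes, keepdims=True)
        self.log_eta.grad += (g * (-w * np.log(xc / gamma)) * eta).sum(axis=axes, keepdims=True)
        return dx


class GlobalAvgPoolLayer(Module):
    """``(B, D, H, W) -> (B, D)`` spatial mean."""

    def __init__(self) -> None:
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, d, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class PowerNormLayer(Module):
    """Trainable ``alpha * s^beta`` over a ``(B, D)`` descriptor."""

    def __init__(self, init: PowerNormParams | None = None) -> None:
        init = init or PowerNormParams()
        self.log_alpha = Parameter(np.array([np.log(init.alpha)]))
        self.log_beta = Parameter(np.array([np.log(init.beta)]))
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.log_alpha, self.log_beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        alpha = np.exp(self.log_alpha.value[0])
        beta = np.exp(self.log_beta.value[0])
        xc = np.maximum(x, EPS)
        y = alpha * xc ** beta
        self._cache = (xc, alpha, beta, y)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xc, alpha, beta, y = self._cache
        self.log_alpha.grad += np.array([(grad * y).sum()])
        self.log_beta.grad += np.array([(grad * y * np.log(xc) * beta).sum()])
        return grad * alpha * beta * xc ** (beta - 1.0)
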