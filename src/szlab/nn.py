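"""A compact numpy training engine for windowed feed-forward networks.

Layers operate on channel-last float64 arrays: images are ``(N, H, W, C)``,
flattened features ``(N, D)``.  Each layer implements ``forward`` /
``backward`` with manual backpropagation; correctness is pinned down by
finite-difference gradient checks in the test suite.

Windowed layers (``Dense`` / ``Conv2D`` with a ``window``) recompute their
effective weights ``(W * F) / rho`` on every forward pass with the window
held constant.  The gradient of the loss with respect to a raw weight is the
effective-weight gradient times ``F / rho``, so masked raw weights receive an
exactly-zero gradient — the developmental-mode invariant — and a full
(all-ones) window is bit-identical to a conventional layer.

Initialization is He's method (normal, std ``sqrt(2 / fan_in)``) on the raw
weights with full fan-in; the ``1/rho`` renormalization compensates the scale
of masked layers.  Optimizers: Adam and RMSprop (with the multiplicative
``lr / (1 + decay * iterations)`` schedule).
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ContractError, DomainError
from .masking import ACTIVATIONS, apply_activation, effective_weights, sz_conv_effective_kernel
from .windows import WindowMatrix

__all__ = [
    "Dense",
    "Conv2D",
    "MaxPool2D",
    "Flatten",
    "Dropout",
    "BatchNorm",
    "Sequential",
    "Adam",
    "RMSprop",
    "cross_entropy",
    "softmax_ce_delta",
    "he_init",
]


def he_init(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
    return rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)


class Layer:
    """Base layer: stateless unless it owns parameters."""

    def init_params(self, rng: np.random.Generator) -> None:  # pragma: no cover
        pass

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, delta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_grads(self):
        """Pairs of (parameter array, gradient array), updated in place."""
        return []

    def n_params(self) -> int:
        return sum(p.size for p, _ in self.param_grads())


class Dense(Layer):
    """Fully connected layer, optionally masked by a weight window.

    With ``window=None`` this is a conventional dense layer; with a window it
    is a windowed ("schizophrenia connection") layer in the given ``mode``.
    ``l1`` adds an L1 penalty on the raw weights (used by the regularization
    control experiment).
    """

    def __init__(
        self,
        n_in: int,
        n_out: int,
        activation: str = "relu",
        bias: bool = True,
        window: WindowMatrix | None = None,
        mode: str = "developmental",
        l1: float = 0.0,
    ):
        if activation not in ACTIVATIONS:
            raise DomainError(f"unknown activation {activation!r}")
        if window is not None and window.shape != (n_in, n_out):
            raise ContractError(
                f"window shape {window.shape} does not match layer ({n_in}, {n_out})"
            )
        if mode == "disorganized" and bias:
            raise ContractError("disorganized layers must be bias-free")
        if l1 < 0:
            raise DomainError(f"l1 strength must be >= 0, got {l1}")
        self.n_in, self.n_out = n_in, n_out
        self.activation = activation
        self.use_bias = bias
        self.window = window
        self.mode = mode
        self.l1 = float(l1)
        # rho and F are constants for the lifetime of the attachment
        self._F = None if window is None else window.values
        self._rho = None if window is None else window.retained_fraction
        self.W: np.ndarray | None = None
        self.b: np.ndarray | None = None
        self.gW = self.gb = None

    def init_params(self, rng):
        self.W = he_init(rng, self.n_in, (self.n_in, self.n_out))
        if self.use_bias:
            self.b = np.zeros(self.n_out)

    def effective_W(self) -> np.ndarray:
        if self.window is None:
            return self.W
        return effective_weights(self.W, self.window)

    def forward(self, x, training):
        if x.ndim != 2 or x.shape[1] != self.n_in:
            raise ContractError(f"Dense expects (N, {self.n_in}), got {x.shape}")
        self._x = x
        self._Weff = self.effective_W()
        z = x @ self._Weff
        if self.use_bias:
            z = z + self.b
        if self.activation == "relu":
            self._pos = z > 0
        return apply_activation(z, self.activation)

    def backward(self, delta):
        # softmax deltas arrive pre-combined with cross-entropy (dL/dz)
        if self.activation == "relu":
            delta = delta * self._pos
        gW = self._x.T @ delta
        if self.window is not None:
            gW = gW * self._F / self._rho
        if self.l1:
            gW = gW + self.l1 * np.sign(self.W)
        self.gW = gW
        if self.use_bias:
            self.gb = delta.sum(axis=0)
        return delta @ self._Weff.T

    def param_grads(self):
        out = [(self.W, self.gW)]
        if self.use_bias:
            out.append((self.b, self.gb))
        return out

    def regularization_loss(self) -> float:
        return self.l1 * float(np.abs(self.W).sum()) if self.l1 else 0.0


class Conv2D(Layer):
    """2-D convolution (stride 1), optionally channel-masked by a window.

    Kernel layout is ``(k_h, k_w, c_in, c_out)``; the channel window, when
    present, masks the last two axes identically at every spatial position.
    ``padding`` is ``'same'`` (zero pad) or ``'valid'``.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel_size: int = 3,
        activation: str = "relu",
        padding: str = "same",
        bias: bool = True,
        channel_window: WindowMatrix | None = None,
        mode: str = "developmental",
    ):
        if activation not in ACTIVATIONS:
            raise DomainError(f"unknown activation {activation!r}")
        if padding not in ("same", "valid"):
            raise DomainError(f"padding must be 'same' or 'valid', got {padding!r}")
        if channel_window is not None and channel_window.shape != (c_in, c_out):
            raise ContractError(
                f"channel window {channel_window.shape} vs channels ({c_in}, {c_out})"
            )
        if mode == "disorganized" and bias:
            raise ContractError("disorganized layers must be bias-free")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel_size
        self.activation = activation
        self.padding = padding
        self.use_bias = bias
        self.window = channel_window
        self.mode = mode
        self.K: np.ndarray | None = None
        self.b: np.ndarray | None = None

    def init_params(self, rng):
        fan_in = self.k * self.k * self.c_in
        self.K = he_init(rng, fan_in, (self.k, self.k, self.c_in, self.c_out))
        if self.use_bias:
            self.b = np.zeros(self.c_out)

    def effective_K(self) -> np.ndarray:
        if self.window is None:
            return self.K
        return sz_conv_effective_kernel(self.K, self.window)

    def forward(self, x, training):
        if x.ndim != 4 or x.shape[3] != self.c_in:
            raise ContractError(f"Conv2D expects (N, H, W, {self.c_in}), got {x.shape}")
        k = self.k
        if self.padding == "same":
            p = (k - 1) // 2
            q = k - 1 - p
            x = np.pad(x, ((0, 0), (p, q), (p, q), (0, 0)))
        self._xp_shape = x.shape
        # (N, OH, OW, C, k, k) -> (N, OH, OW, k, k, C)
        patches = sliding_window_view(x, (k, k), axis=(1, 2)).transpose(0, 1, 2, 4, 5, 3)
        n, oh, ow = patches.shape[:3]
        self._cols = patches.reshape(n * oh * ow, k * k * self.c_in)
        self._out_hw = (n, oh, ow)
        Keff = self.effective_K()
        self._Kr = Keff.reshape(k * k * self.c_in, self.c_out)
        z = self._cols @ self._Kr
        if self.use_bias:
            z = z + self.b
        z = z.reshape(n, oh, ow, self.c_out)
        if self.activation == "relu":
            self._pos = z > 0
        return apply_activation(z, self.activation)

    def backward(self, delta):
        if self.activation == "relu":
            delta = delta * self._pos
        n, oh, ow = self._out_hw
        dflat = delta.reshape(n * oh * ow, self.c_out)
        gK = (self._cols.T @ dflat).reshape(self.K.shape)
        if self.window is not None:
            gK = gK * self.window.values[None, None] / self.window.retained_fraction
        self.gK = gK
        if self.use_bias:
            self.gb = dflat.sum(axis=0)
        dcols = (dflat @ self._Kr.T).reshape(n, oh, ow, self.k, self.k, self.c_in)
        dxp = np.zeros(self._xp_shape)
        for u in range(self.k):
            for v in range(self.k):
                dxp[:, u : u + oh, v : v + ow, :] += dcols[:, :, :, u, v, :]
        if self.padding == "same":
            p = (self.k - 1) // 2
            q = self.k - 1 - p
            h = dxp.shape[1] - p - q
            w = dxp.shape[2] - p - q
            dxp = dxp[:, p : p + h, p : p + w, :]
        return dxp

    def param_grads(self):
        out = [(self.K, self.gK)]
        if self.use_bias:
            out.append((self.b, self.gb))
        return out


class MaxPool2D(Layer):
    """2x2 max pooling with stride 2 (trailing odd row/column dropped)."""

    def forward(self, x, training):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xc = x[:, : 2 * h2, : 2 * w2, :]
        xr = xc.reshape(n, h2, 2, w2, 2, c)
        out = xr.max(axis=(2, 4))
        mask = xr == out[:, :, None, :, None, :]
        # split gradient equally among tied maxima
        self._mask = mask / mask.sum(axis=(2, 4), keepdims=True)
        return out

    def backward(self, delta):
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        dxr = self._mask * delta[:, :, None, :, None, :]
        dx = np.zeros(self._in_shape)
        dx[:, : 2 * h2, : 2 * w2, :] = dxr.reshape(n, 2 * h2, 2 * w2, c)
        return dx


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, delta):
        return delta.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; active only during training.  Uses the model's rng."""

    def __init__(self, rate: float):
        if not (0.0 <= rate < 1.0):
            raise DomainError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng: np.random.Generator | None = None  # assigned by Sequential

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, delta):
        return delta if self._mask is None else delta * self._mask


class BatchNorm(Layer):
    """Batch normalization over the channel (last) axis."""

    def __init__(self, n_channels: int, momentum: float = 0.99, eps: float = 1e-3):
        self.n_channels = n_channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = np.ones(n_channels)
        self.beta = np.zeros(n_channels)
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)

    def forward(self, x, training):
        if x.shape[-1] != self.n_channels:
            raise ContractError(
                f"BatchNorm expects {self.n_channels} channels, got {x.shape[-1]}"
            )
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._invstd
        self._axes = axes
        self._m = x.size // self.n_channels
        return self.gamma * self._xhat + self.beta

    def backward(self, delta):
        axes, m = self._axes, self._m
        self.ggamma = (delta * self._xhat).sum(axis=axes)
        self.gbeta = delta.sum(axis=axes)
        dxhat = delta * self.gamma
        return (self._invstd / m) * (
            m * dxhat
            - dxhat.sum(axis=axes)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes)
        )

    def param_grads(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]


class Sequential:
    """An ordered stack of layers with seeded initialization.

    Parameters are initialized in layer order from one generator, so two
    models with identical layer shapes and the same seed draw identical
    weights (the basis of the full-window equivalence property).
    """

    def __init__(self, layers: list[Layer], seed: int = 0):
        self.layers = layers
        self.seed = seed
        rng = np.random.default_rng(seed)
        for layer in layers:
            layer.init_params(rng)
        drop_rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
        for layer in layers:
            if isinstance(layer, Dropout):
                layer.rng = drop_rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, delta: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            delta = layer.backward(delta)
        return delta

    def param_grads(self):
        for layer in self.layers:
            yield from layer.param_grads()

    def count_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def regularization_loss(self) -> float:
        return sum(
            layer.regularization_loss()
            for layer in self.layers
            if hasattr(layer, "regularization_loss")
        )


# ---------------------------------------------------------------------------
# loss


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy from predicted probabilities."""
    p = probs[np.arange(len(labels)), labels]
    return float(-np.log(np.clip(p, 1e-12, None)).mean())


def softmax_ce_delta(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Gradient of mean cross-entropy w.r.t. the softmax pre-activations."""
    delta = probs.copy()
    delta[np.arange(len(labels)), labels] -= 1.0
    return delta / len(labels)


# ---------------------------------------------------------------------------
# optimizers


class Adam:
    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, model: Sequential):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for i, (p, g) in enumerate(model.param_grads()):
            m = self._m.setdefault(i, np.zeros_like(p))
            v = self._v.setdefault(i, np.zeros_like(p))
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class RMSprop:
    """RMSprop with the multiplicative iteration decay ``lr/(1+decay*t)``."""

    def __init__(self, lr=1e-3, rho=0.9, eps=1e-7, decay=0.0):
        self.lr, self.rho, self.eps, self.decay = lr, rho, eps, decay
        self.t = 0
        self._acc: dict[int, np.ndarray] = {}

    def step(self, model: Sequential):
        lr_t = self.lr / (1.0 + self.decay * self.t)
        self.t += 1
        for i, (p, g) in enumerate(model.param_grads()):
            acc = self._acc.setdefault(i, np.zeros_like(p))
            acc *= self.rho
            acc += (1 - self.rho) * g * g
            p -= lr_t * g / (np.sqrt(acc) + self.eps)
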