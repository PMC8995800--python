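"""Masked-layer arithmetic: effective weights, normalization, disorganization.

A windowed ("schizophrenia") layer keeps a *raw* weight matrix ``W`` and a
fixed window ``F``; its effective weights are

    W_eff = (W * F) / rho,        rho = sum(F) / N,

i.e. the masked weights are renormalized by the retained fraction so that the
total weight "mass" is preserved (exactly when the mask is uncorrelated with
the weights, in expectation in general).  Masking is applied on every forward
pass with the window held constant, so under backpropagation the gradient at
a masked (``f_ij = 0``) position is exactly zero and masked raw weights never
move.

Two intervention modes are distinguished:

``developmental``
    the window is attached before training and constrains every update
    (concurrent pathology and development); biases allowed.
``disorganized``
    a conventionally trained layer is masked only at evaluation
    (degeneration after network formation); no bias, since a bias cannot be
    attributed to any inter-node distance after the fact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, DomainError
from .windows import WindowMatrix

__all__ = [
    "effective_weights",
    "sz_dense_forward",
    "sz_conv_effective_kernel",
    "SzDenseLayer",
    "SzConvLayer",
    "disorganize",
    "apply_activation",
]

ACTIVATIONS = ("linear", "relu", "softmax")


def apply_activation(z: np.ndarray, activation: str) -> np.ndarray:
    """Apply ``linear`` / ``relu`` / ``softmax`` (softmax over the last axis)."""
    if activation == "linear":
        return z
    if activation == "relu":
        return np.maximum(z, 0.0)
    if activation == "softmax":
        shifted = z - z.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        return e / e.sum(axis=-1, keepdims=True)
    raise DomainError(f"unknown activation {activation!r}")


def effective_weights(W: np.ndarray, window: WindowMatrix) -> np.ndarray:
    """``(W * F) / rho`` — masked weights renormalized by the retained fraction."""
    W = np.asarray(W, dtype=float)
    if W.shape != window.shape:
        raise ContractError(
            f"weight shape {W.shape} does not match window shape {window.shape}"
        )
    return W * window.values / window.retained_fraction


@dataclass
class SzDenseLayer:
    """A dense layer with an attached weight window.

    ``W`` is the raw trainable matrix (n_in x n_out); the forward pass always
    goes through :func:`effective_weights`.  ``mode='disorganized'`` layers
    carry no bias.
    """

    W: np.ndarray
    window: WindowMatrix
    b: np.ndarray | None = None
    mode: str = "developmental"
    activation: str = "linear"

    def __post_init__(self):
        if self.mode not in ("developmental", "disorganized"):
            raise DomainError(f"unknown mode {self.mode!r}")
        if self.activation not in ACTIVATIONS:
            raise DomainError(f"unknown activation {self.activation!r}")
        if np.asarray(self.W).shape != self.window.shape:
            raise ContractError(
                f"W shape {np.asarray(self.W).shape} vs window {self.window.shape}"
            )
        if self.mode == "disorganized" and self.b is not None:
            raise ContractError("disorganized layers must not carry a bias")
        if self.b is not None and np.asarray(self.b).shape != (self.window.shape[1],):
            raise ContractError(
                f"bias length {np.asarray(self.b).shape} vs n_out {self.window.shape[1]}"
            )

    @property
    def effective(self) -> np.ndarray:
        return effective_weights(self.W, self.window)


def sz_dense_forward(x: np.ndarray, layer: SzDenseLayer) -> np.ndarray:
    """Forward pass ``activation(x @ W_eff + b)`` for a vector or a batch."""
    x = np.asarray(x, dtype=float)
    n_in = layer.window.shape[0]
    if x.shape[-1] != n_in:
        raise ContractError(f"input length {x.shape[-1]} does not match n_in {n_in}")
    z = x @ layer.effective
    if layer.b is not None:
        z = z + layer.b
    return apply_activation(z, layer.activation)


def sz_conv_effective_kernel(K: np.ndarray, channel_window: WindowMatrix) -> np.ndarray:
    """Mask a conv kernel along its channel axes only.

    ``K`` has logical layout (k_h, k_w, c_in, c_out); the same
    ``c_in x c_out`` window divides by its retained fraction and multiplies
    every spatial position identically, so the zero pattern is constant
    across (h, w).
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 4:
        raise ContractError(f"kernel must be 4-D (kh, kw, c_in, c_out), got {K.shape}")
    if K.shape[2:] != channel_window.shape:
        raise ContractError(
            f"kernel channel dims {K.shape[2:]} vs window {channel_window.shape}"
        )
    return K * channel_window.values[None, None] / channel_window.retained_fraction


@dataclass
class SzConvLayer:
    """A convolution layer whose kernel is channel-masked by a window."""

    K: np.ndarray
    channel_window: WindowMatrix
    b: np.ndarray | None = None
    mode: str = "developmental"
    activation: str = "linear"

    def __post_init__(self):
        K = np.asarray(self.K)
        if K.ndim != 4 or K.shape[2:] != self.channel_window.shape:
            raise ContractError(
                f"kernel shape {K.shape} incompatible with channel window "
                f"{self.channel_window.shape}"
            )
        if self.mode == "disorganized" and self.b is not None:
            raise ContractError("disorganized layers must not carry a bias")

    @property
    def effective(self) -> np.ndarray:
        return sz_conv_effective_kernel(self.K, self.channel_window)


def disorganize(trained_layer, window: WindowMatrix) -> SzDenseLayer:
    """Attach a window to an already-trained dense layer (post-training mask).

    ``trained_layer`` may be any object with a ``W`` attribute (an engine
    layer or an :class:`SzDenseLayer`); its weights are *shared*, not copied,
    and the original object is not modified.  The result is a bias-free
    ``mode='disorganized'`` layer.
    """
    W = trained_layer.W if hasattr(trained_layer, "W") else np.asarray(trained_layer)
    activation = getattr(trained_layer, "activation", "linear")
    return SzDenseLayer(
        W=W, window=window, b=None, mode="disorganized", activation=activation
    )
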