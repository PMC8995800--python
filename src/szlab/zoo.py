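"""Network configurations A-E, training schedules, and the training loop.

The five architectures (one-hidden-layer dense, twin-hidden-layer dense,
two conv blocks with a dense top, the same with a post-training-masked top,
and a VGG16 stack with channel-masked convolutions) come with their published
training schedules:

=======  ============  ==========  =========  ==========================
config   protocol      optimizer   batch      notes
=======  ============  ==========  =========  ==========================
A        developmental adam 1e-3   32         Sz(512) hidden, MNIST-shaped
B        disorganized  adam 1e-3   32         twin hidden (64-1024), 2nd masked at eval
C        developmental rmsprop     32         conv 32/32/64/64, Sz top 512
                       1e-4/1e-6
D        disorganized  same as C   32         top masked at eval (bias-free)
E        developmental adam 5e-4,  200        VGG16, last 3 conv SzConv(512),
                       1e-4@150               batchnorm + dropout, augmentation
=======  ============  ==========  =========  ==========================

Reduced-scale presets (``a_small``, ``c_small``, ``e_small``) preserve the
topology (layer count, window placement, pooling positions) at desk-test
widths.  Hidden activations are ReLU, outputs softmax, He initialization;
biases everywhere except layers destined for post-training masking, which are
built bias-free from the start.  Loss is categorical cross-entropy.
"""

from __future__ import annotations

import copy
import time
from dataclasses import dataclass, field, replace

import numpy as np

from ._seeds import derive_seed
from .data import AugmentParams, ImageDataset, augment
from .errors import ContractError, DomainError, TrainingError
from .nn import (
    Adam,
    BatchNorm,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    MaxPool2D,
    RMSprop,
    Sequential,
    cross_entropy,
    softmax_ce_delta,
)
from .windows import NodeGeometry, WindowMatrix, solve_window

__all__ = [
    "WindowSpec",
    "NetworkConfig",
    "TrainingSchedule",
    "TrainingTrace",
    "build_network",
    "train",
    "evaluate",
    "disorganize_model",
    "l1_variant",
    "l1_reduction",
    "config_a",
    "config_b",
    "config_c",
    "config_d",
    "config_e",
    "schedule_ab",
    "schedule_cd",
    "schedule_e",
    "config_from_dict",
]


@dataclass(frozen=True)
class WindowSpec:
    """Requested window: family plus target parameter reduction (eliminated share)."""

    family: str = "full"
    reduction: float = 0.0
    n_bands: int = 2  # stripe family only
    seed: int | None = None  # random family; derived from the build seed if None

    def resolve(self, n_in: int, n_out: int, fallback_seed: int = 0) -> WindowMatrix | None:
        """Materialize the window for a concrete geometry; None means full."""
        if self.family == "full" or self.reduction == 0.0:
            return None
        seed = self.seed
        if seed is None:
            seed = derive_seed(fallback_seed, "window", self.family, n_in, n_out)
        return solve_window(
            NodeGeometry(n_in, n_out),
            self.family,
            self.reduction,
            seed=seed,
            n_bands=self.n_bands,
        )


@dataclass(frozen=True)
class NetworkConfig:
    """One of the A-E architectures (or a scaled variant).

    ``width`` is the hidden width for A/B and the dense-top width for C/D/E;
    ``filters`` the conv filter counts for C/D (two blocks of two) and the
    per-block widths for E.  ``window`` applies to the designated windowed
    layer(s): at build time for developmental configs, at evaluation (via
    :func:`disorganize_model`) for disorganized ones.
    """

    config_id: str
    protocol: str  # developmental | disorganized
    input_shape: tuple[int, int, int]
    n_classes: int = 10
    width: int = 512
    filters: tuple[int, ...] = ()
    window: WindowSpec = field(default_factory=WindowSpec)
    batchnorm: bool = False
    dropout: float = 0.0
    l1: float = 0.0
    top_widths: tuple[int, ...] = ()  # E only
    sz_tops: bool = False  # E only: window the dense tops too

    def __post_init__(self):
        if self.protocol not in ("developmental", "disorganized"):
            raise DomainError(f"unknown protocol {self.protocol!r}")
        if self.l1 < 0:
            raise DomainError("l1 strength must be >= 0")


@dataclass(frozen=True)
class TrainingSchedule:
    """Optimizer, learning-rate rule, batch size, epoch count and seed."""

    optimizer: str = "adam"  # adam | rmsprop
    lr: float = 1e-3
    decay: float = 0.0  # rmsprop iteration decay
    lr_switch: tuple[int, float] | None = None  # (epoch, new lr)
    batch_size: int = 32
    epochs: int = 10
    augment: AugmentParams | None = None
    seed: int = 0

    def __post_init__(self):
        if self.optimizer not in ("adam", "rmsprop"):
            raise DomainError(f"unknown optimizer {self.optimizer!r}")
        if self.epochs < 1 or self.batch_size < 1:
            raise DomainError("epochs and batch_size must be >= 1")


@dataclass
class TrainingTrace:
    """Per-epoch train/validation error for one seeded session."""

    train_errors: list[float]
    val_errors: list[float]
    seed: int
    wall_time: float = 0.0

    def __post_init__(self):
        for seq in (self.train_errors, self.val_errors):
            if seq and not all(0.0 <= e <= 1.0 for e in seq):
                raise ContractError("trace errors must lie in [0, 1]")

    @property
    def final_val_error(self) -> float:
        return self.val_errors[-1]


# ---------------------------------------------------------------------------
# presets


def config_a(width: int = 512, window: WindowSpec = WindowSpec("diagonal", 0.5)) -> NetworkConfig:
    """Network A: input 28x28 -> windowed dense hidden -> softmax output."""
    return NetworkConfig("A", "developmental", (28, 28, 1), width=width, window=window)


def config_b(width: int = 512, window: WindowSpec = WindowSpec("diagonal", 0.5)) -> NetworkConfig:
    """Network B: twin equal-width hiddens; the second is masked at evaluation."""
    if not (1 <= width):
        raise DomainError("width must be positive")
    return NetworkConfig("B", "disorganized", (28, 28, 1), width=width, window=window)


def config_c(
    top: int = 512,
    filters: tuple[int, ...] = (32, 32, 64, 64),
    window: WindowSpec = WindowSpec("diagonal", 0.5),
) -> NetworkConfig:
    """Network C: conv/conv/pool twice, then a windowed dense top."""
    return NetworkConfig(
        "C", "developmental", (32, 32, 3), width=top, filters=filters, window=window
    )


def config_d(
    top: int = 512,
    filters: tuple[int, ...] = (32, 32, 64, 64),
    window: WindowSpec = WindowSpec("diagonal", 0.5),
) -> NetworkConfig:
    """Network D: as C, but the top layer is bias-free and masked at evaluation."""
    return NetworkConfig(
        "D", "disorganized", (32, 32, 3), width=top, filters=filters, window=window
    )


def config_e(
    window: WindowSpec = WindowSpec("diagonal", 0.6),
    top_widths: tuple[int, ...] = (4096, 4096, 1024),
    dropout: float = 0.5,
    sz_tops: bool = False,
) -> NetworkConfig:
    """Network E: VGG16 conv stack, last three convs channel-masked, dense tops.

    Batch-normalization placement (after every convolution) and dropout (0.5
    after each top dense layer) are this package's defaults and overridable —
    the original regularization placement is not part of the published
    configuration tables.  ``sz_tops=True`` windows the dense tops as well.
    """
    return NetworkConfig(
        "E",
        "developmental",
        (32, 32, 3),
        filters=(64, 128, 256, 512, 512),
        window=window,
        batchnorm=True,
        dropout=dropout,
        top_widths=top_widths,
        sz_tops=sz_tops,
    )


def a_small(width: int = 32, window: WindowSpec = WindowSpec("diagonal", 0.5)) -> NetworkConfig:
    return config_a(width=width, window=window)


def c_small(window: WindowSpec = WindowSpec("diagonal", 0.5)) -> NetworkConfig:
    return config_c(top=64, filters=(8, 8, 16, 16), window=window)


def e_small(window: WindowSpec = WindowSpec("diagonal", 0.6)) -> NetworkConfig:
    """One VGG-style block, one channel-masked conv, one masked dense top."""
    return NetworkConfig(
        "E-small",
        "developmental",
        (32, 32, 3),
        width=64,
        filters=(16, 32),
        window=window,
        batchnorm=True,
        dropout=0.5,
        top_widths=(64,),
        sz_tops=True,
    )


def schedule_ab(epochs: int = 20, seed: int = 0) -> TrainingSchedule:
    return TrainingSchedule("adam", lr=1e-3, batch_size=32, epochs=epochs, seed=seed)


def schedule_cd(epochs: int = 100, seed: int = 0) -> TrainingSchedule:
    return TrainingSchedule(
        "rmsprop", lr=1e-4, decay=1e-6, batch_size=32, epochs=epochs, seed=seed
    )


def schedule_e(epochs: int = 200, seed: int = 0) -> TrainingSchedule:
    return TrainingSchedule(
        "adam",
        lr=5e-4,
        lr_switch=(150, 1e-4),
        batch_size=200,
        epochs=epochs,
        augment=AugmentParams(flip=True, shift_frac=0.1),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# builders


def build_network(config: NetworkConfig, seed: int = 0) -> Sequential:
    """Materialize a config into a seeded model.

    Developmental configs resolve and attach their window at build time;
    disorganized configs build the target layer as a plain (bias-free) dense
    layer, to be masked later by :func:`disorganize_model`.  The returned
    model carries ``sz_layer_index`` (the windowed / to-be-windowed layer)
    and ``l1_layer_index`` when an L1 penalty is present.
    """
    h, w, c = config.input_shape
    n_cls = config.n_classes
    layers: list = []
    sz_index = None
    l1_index = None

    if config.config_id.startswith("A"):
        n_in = h * w * c
        window = config.window.resolve(n_in, config.width, seed)
        layers = [
            Flatten(),
            Dense(n_in, config.width, "relu", bias=True, window=window, l1=config.l1),
            Dense(config.width, n_cls, "softmax"),
        ]
        sz_index = 1
        if config.l1 > 0:
            l1_index = sz_index
    elif config.config_id.startswith("B"):
        n_in = h * w * c
        layers = [
            Flatten(),
            Dense(n_in, config.width, "relu", bias=True),
            # masked at evaluation; bias-free from the start per the bias rule
            Dense(config.width, config.width, "relu", bias=False),
            Dense(config.width, n_cls, "softmax"),
        ]
        sz_index = 2
    elif config.config_id.startswith(("C", "D")):
        f1, f2, f3, f4 = config.filters
        layers = [
            Conv2D(c, f1, 3, padding="same"),
            Conv2D(f1, f2, 3, padding="valid"),
            MaxPool2D(),
            Conv2D(f2, f3, 3, padding="same"),
            Conv2D(f3, f4, 3, padding="valid"),
            MaxPool2D(),
            Flatten(),
        ]
        spatial = (((h - 2) // 2) - 2) // 2  # same, valid, pool, same, valid, pool
        flat = spatial * spatial * f4
        if config.config_id.startswith("C"):
            window = config.window.resolve(flat, config.width, seed)
            layers.append(
                Dense(flat, config.width, "relu", bias=True, window=window, l1=config.l1)
            )
        else:
            layers.append(Dense(flat, config.width, "relu", bias=False, l1=config.l1))
        sz_index = len(layers) - 1
        if config.l1 > 0:
            l1_index = sz_index
        layers.append(Dense(config.width, n_cls, "softmax"))
    elif config.config_id.startswith("E"):
        layers, sz_index = _build_vgg(config, seed)
    else:
        raise DomainError(f"unknown config_id {config.config_id!r}")

    model = Sequential(layers, seed=seed)
    model.sz_layer_index = sz_index
    model.l1_layer_index = l1_index
    model.config = config
    return model


def _build_vgg(config: NetworkConfig, seed: int):
    """VGG-style conv stack with the last conv(s) channel-masked, dense tops.

    Full-scale E uses the VGG16 block plan (2, 2, 3, 3, 3 convolutions per
    block) with the last three convolutions channel-masked; the small variant
    uses one plain block of two convolutions plus one masked convolution.
    """
    h, w, c = config.input_shape
    full_scale = config.config_id == "E"
    if full_scale:
        convs_per_block = (2, 2, 3, 3, 3)
        n_masked = 3
    else:
        convs_per_block = (2, 1)
        n_masked = 1
    blocks = config.filters
    n_conv = sum(convs_per_block[: len(blocks)])
    layers: list = []
    spatial = h
    c_prev = c
    conv_i = 0
    for block, n_in_block in zip(blocks, convs_per_block):
        for _ in range(n_in_block):
            masked = conv_i >= n_conv - n_masked
            window = (
                config.window.resolve(c_prev, block, derive_seed(seed, "conv", conv_i))
                if masked
                else None
            )
            layers.append(
                Conv2D(c_prev, block, 3, padding="same", channel_window=window)
            )
            if config.batchnorm:
                layers.append(BatchNorm(block))
            c_prev = block
            conv_i += 1
        layers.append(MaxPool2D())
        spatial //= 2
    layers.append(Flatten())
    n_prev = spatial * spatial * c_prev
    sz_index = None
    for width in config.top_widths:
        window = (
            config.window.resolve(n_prev, width, derive_seed(seed, "top", width))
            if config.sz_tops
            else None
        )
        layers.append(Dense(n_prev, width, "relu", bias=True, window=window))
        sz_index = len(layers) - 1
        if config.dropout:
            layers.append(Dropout(config.dropout))
        n_prev = width
    layers.append(Dense(n_prev, config.n_classes, "softmax"))
    return layers, sz_index


def disorganize_model(model: Sequential, window: WindowMatrix) -> Sequential:
    """Post-training intervention: mask the model's target layer at evaluation.

    Returns a shallow copy of the model whose ``sz_layer_index`` dense layer
    is replaced by a windowed, bias-free copy *sharing* the trained weights;
    the original model is untouched.
    """
    idx = getattr(model, "sz_layer_index", None)
    if idx is None:
        raise ContractError("model has no designated layer to disorganize")
    old = model.layers[idx]
    if not isinstance(old, Dense):
        raise ContractError("disorganization targets a dense layer")
    if window.shape != (old.n_in, old.n_out):
        raise ContractError(
            f"window {window.shape} does not fit layer ({old.n_in}, {old.n_out})"
        )
    new_layer = Dense(
        old.n_in,
        old.n_out,
        old.activation,
        bias=False,
        window=window,
        mode="disorganized",
    )
    new_layer.W = old.W  # shared, never trained further
    clone = copy.copy(model)
    clone.layers = list(model.layers)
    clone.layers[idx] = new_layer
    return clone


def l1_variant(config: NetworkConfig, l1_strength: float, zero_tolerance: float = 1e-4):
    """A fully connected control with an L1 penalty on the top dense layer.

    Returns ``(config, report_fn)`` where ``report_fn(model)`` gives the
    post-training reduction: the fraction of top-layer weights with
    ``|w| < zero_tolerance``.
    """
    if l1_strength < 0:
        raise DomainError(f"l1_strength must be >= 0, got {l1_strength}")
    new = replace(config, window=WindowSpec("full", 0.0), l1=l1_strength)

    def report(model: Sequential) -> float:
        idx = model.l1_layer_index if model.l1_layer_index is not None else model.sz_layer_index
        return l1_reduction(model.layers[idx].W, zero_tolerance)

    return new, report


def l1_reduction(W: np.ndarray, zero_tolerance: float = 1e-4) -> float:
    """Fraction of weights regarded as zero (``|w| < zero_tolerance``)."""
    W = np.asarray(W)
    return float(np.count_nonzero(np.abs(W) < zero_tolerance) / W.size)


# ---------------------------------------------------------------------------
# training / evaluation


def _make_optimizer(schedule: TrainingSchedule):
    if schedule.optimizer == "adam":
        return Adam(lr=schedule.lr)
    return RMSprop(lr=schedule.lr, decay=schedule.decay)


def train(
    model: Sequential,
    train_ds: ImageDataset,
    val_ds: ImageDataset,
    schedule: TrainingSchedule,
    record_trace: bool = True,
) -> TrainingTrace:
    """Train ``model`` in place; deterministic given (seed, data, schedule).

    With ``record_trace=False`` only the final train/validation errors are
    evaluated (one-element trace), which roughly halves sweep cost.
    """
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ContractError("train and validation splits must be non-empty")
    opt = _make_optimizer(schedule)
    rng = np.random.default_rng(derive_seed(schedule.seed, "shuffle"))
    x, y = train_ds.images, train_ds.labels
    n = len(x)
    t0 = time.perf_counter()
    train_errors: list[float] = []
    val_errors: list[float] = []
    for epoch in range(schedule.epochs):
        if schedule.lr_switch is not None and epoch == schedule.lr_switch[0]:
            opt.lr = schedule.lr_switch[1]
        perm = rng.permutation(n)
        for start in range(0, n, schedule.batch_size):
            idx = perm[start : start + schedule.batch_size]
            xb, yb = x[idx], y[idx]
            if schedule.augment is not None:
                xb = augment(
                    xb, schedule.augment, derive_seed(schedule.seed, "aug", epoch, start)
                )
            probs = model.forward(xb, training=True)
            loss = cross_entropy(probs, yb) + model.regularization_loss()
            if not np.isfinite(loss):
                raise TrainingError(
                    f"training diverged (non-finite loss) at epoch {epoch}", epoch=epoch
                )
            model.backward(softmax_ce_delta(probs, yb))
            opt.step(model)
        if record_trace or epoch == schedule.epochs - 1:
            train_errors.append(evaluate(model, train_ds))
            val_errors.append(evaluate(model, val_ds))
    return TrainingTrace(
        train_errors, val_errors, seed=schedule.seed, wall_time=time.perf_counter() - t0
    )


def evaluate(model: Sequential, dataset: ImageDataset, batch_size: int = 512) -> float:
    """Top-1 error fraction ``1 - accuracy`` on a dataset split; pure."""
    if len(dataset) == 0:
        raise ContractError("cannot evaluate on an empty split")
    wrong = 0
    for start in range(0, len(dataset), batch_size):
        xb = dataset.images[start : start + batch_size]
        yb = dataset.labels[start : start + batch_size]
        probs = model.forward(xb, training=False)
        wrong += int(np.count_nonzero(probs.argmax(axis=1) != yb))
    return wrong / len(dataset)


# ---------------------------------------------------------------------------
# config files


_PRESETS = {
    "A": config_a,
    "B": config_b,
    "C": config_c,
    "D": config_d,
    "E": config_e,
    "A-small": a_small,
    "C-small": c_small,
    "E-small": e_small,
}


def config_from_dict(d: dict) -> NetworkConfig:
    """Build a config from a plain mapping (YAML/JSON experiment files)."""
    d = dict(d)
    cid = d.pop("config_id")
    wspec = d.pop("window", {})
    window = WindowSpec(**wspec) if isinstance(wspec, dict) else wspec
    if cid in _PRESETS:
        factory = _PRESETS[cid]
        kwargs = {}
        if "width" in d and cid in ("A", "B", "A-small"):
            kwargs["width"] = d.pop("width")
        if "width" in d and cid in ("C", "D"):
            kwargs["top"] = d.pop("width")
        if "filters" in d:
            kwargs["filters"] = tuple(d.pop("filters"))
        cfg = factory(window=window, **kwargs)
        if d:
            cfg = replace(cfg, **d)
        return cfg
    return NetworkConfig(config_id=cid, window=window, **d)
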