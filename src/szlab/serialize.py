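"""Model/layer state export and import.

``save_state`` writes every layer's arrays (weights, biases, batch-norm
statistics) plus any attached windows (values, family, params) to a single
``.npz`` archive; ``load_state`` restores them into an
architecture-compatible model.  Round-tripping reproduces forward outputs
bit for bit, windows included.
"""

from __future__ import annotations

import json

import numpy as np

from .errors import ContractError
from .nn import BatchNorm, Conv2D, Dense, Sequential
from .windows import WindowMatrix

__all__ = ["save_state", "load_state"]


def _layer_arrays(layer) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    if isinstance(layer, Dense):
        out["W"] = layer.W
        if layer.use_bias:
            out["b"] = layer.b
    elif isinstance(layer, Conv2D):
        out["K"] = layer.K
        if layer.use_bias:
            out["b"] = layer.b
    elif isinstance(layer, BatchNorm):
        out["gamma"] = layer.gamma
        out["beta"] = layer.beta
        out["running_mean"] = layer.running_mean
        out["running_var"] = layer.running_var
    return out


def save_state(model: Sequential, path) -> None:
    """Write all trainable state and attached windows to one ``.npz`` archive."""
    arrays: dict[str, np.ndarray] = {}
    meta: list[dict] = []
    for i, layer in enumerate(model.layers):
        entry: dict = {"type": type(layer).__name__}
        for name, arr in _layer_arrays(layer).items():
            arrays[f"layer{i}/{name}"] = arr
        window = getattr(layer, "window", None)
        if window is not None:
            arrays[f"layer{i}/window"] = window.values
            entry["window_family"] = window.family
            entry["window_params"] = window.params
        meta.append(entry)
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_state(model: Sequential, path) -> Sequential:
    """Restore a :func:`save_state` archive into a compatible model, in place."""
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode("utf-8"))
        if len(meta) != len(model.layers):
            raise ContractError(
                f"archive has {len(meta)} layers, model has {len(model.layers)}"
            )
        for i, (layer, entry) in enumerate(zip(model.layers, meta)):
            if entry["type"] != type(layer).__name__:
                raise ContractError(
                    f"layer {i}: archive holds {entry['type']}, model has "
                    f"{type(layer).__name__}"
                )
            for name in _layer_arrays(layer):
                stored = archive[f"layer{i}/{name}"]
                current = getattr(layer, name)
                if stored.shape != current.shape:
                    raise ContractError(
                        f"layer {i} array {name}: shape {stored.shape} vs "
                        f"{current.shape}"
                    )
                setattr(layer, name, stored.copy())
            key = f"layer{i}/window"
            if key in archive.files:
                window = WindowMatrix(
                    archive[key],
                    family=entry.get("window_family", "full"),
                    params=entry.get("window_params", {}),
                )
                layer.window = window
                if isinstance(layer, Dense):
                    layer._F = window.values
                    layer._rho = window.retained_fraction
    return model
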