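"""Deterministic, order-independent seed derivation.

Every source of randomness in szlab flows through :func:`derive_seed`, which
hashes an arbitrary tuple of ints/strings into a stable 31-bit seed via
``numpy.random.SeedSequence``.  Deriving per-cell seeds from
(base_seed, protocol, family, grid index, session index) makes sweep cells
reproducible independently of execution order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def _as_int(part) -> int:
    if isinstance(part, (int, np.integer)):
        return int(part) & 0xFFFFFFFF
    if isinstance(part, str):
        return zlib.crc32(part.encode("utf-8"))
    if isinstance(part, float):
        if not float(part).is_integer():
            # hash the IEEE bits of non-integral floats stably
            return zlib.crc32(np.float64(part).tobytes())
        return int(part) & 0xFFFFFFFF
    raise TypeError(f"cannot derive a seed from {type(part).__name__}: {part!r}")


def derive_seed(*parts) -> int:
    """Hash ``parts`` (ints / strings / floats) into a seed in [0, 2**31)."""
    entropy = [_as_int(p) for p in parts]
    state = np.random.SeedSequence(entropy).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


def derive_rng(*parts) -> np.random.Generator:
    """A ``numpy.random.Generator`` seeded by :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(*parts))
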