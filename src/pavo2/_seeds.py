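"""Deterministic seed splitting.

All randomness in the package flows from one integer master seed. Independent
streams are derived with :func:`child_seq`, which feeds the master seed plus a
tuple of integer/string keys into :class:`numpy.random.SeedSequence`. String
keys are mapped to integers with CRC-32 so the rule is stable across runs and
platforms.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seq", "child_rng"]


def _key_to_int(key: int | str) -> int:
    if isinstance(key, (int, np.integer)):
        if key < 0:
            raise ValueError(f"seed keys must be non-negative, got {key}")
        return int(key)
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    raise TypeError(f"seed key must be int or str, got {type(key).__name__}")


def child_seq(master_seed: int, *keys: int | str) -> np.random.SeedSequence:
    """Derive an independent SeedSequence from the master seed and keys."""
    entropy = [int(master_seed)] + [_key_to_int(k) for k in keys]
    return np.random.SeedSequence(entropy)


def child_rng(master_seed: int, *keys: int | str) -> np.random.Generator:
    """Generator seeded by ``child_seq(master_seed, *keys)``."""
    return np.random.default_rng(child_seq(master_seed, *keys))
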