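"""Seeded substream derivation.

One master seed drives the whole pipeline; every entity (scan set, image,
tracer, reviewer, screening state, shuffle) gets its own generator derived
from the master seed plus a tuple of string/integer identifiers.  Derivation
hashes the identifiers, so streams are independent of the order in which
entities are generated — regenerating a single scan set in isolation yields
bit-identical pixels to generating the full study.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_int(key: object) -> int:
    # crc32 is stable across platforms and Python versions, unlike hash().
    return zlib.crc32(str(key).encode("utf-8"))


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator for the substream identified by ``keys``.

    Parameters
    ----------
    seed
        Non-negative master seed.
    *keys
        Identifier tuple (strings, ints, enums); hashed into the entropy.
    """
    if seed < 0:
        raise ValueError(f"seed must be non-negative, got {seed}")
    entropy = [int(seed)] + [_key_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
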