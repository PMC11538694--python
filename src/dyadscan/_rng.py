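"""Deterministic random-stream splitting.

All randomness in the package flows from one integer seed.  Independent
streams for (dyad, day, condition, subject, purpose, ...) are derived with a
counter-based scheme built on :class:`numpy.random.SeedSequence` spawn keys,
so any module can be exercised in isolation and still reproduce exactly what
it would produce inside a full study run.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf8"))


def child_rng(seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the stream identified by ``keys`` under ``seed``.

    Identical (seed, keys) always yields an identical stream; distinct key
    tuples yield statistically independent streams.
    """
    spawn_key = tuple(_key_to_int(k) for k in keys)
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=spawn_key)
    return np.random.Generator(np.random.PCG64(ss))
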