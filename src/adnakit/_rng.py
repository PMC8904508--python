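"""Keyed random-number streams.

A single integer seed expands into independent per-stage streams keyed by
arbitrary string/int tokens, so that results do not depend on the order in
which stages or individuals are evaluated.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "key_to_int"]


def key_to_int(key) -> int:
    """Map a hashable key (str/int/tuple) to a stable 32-bit integer."""
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    if isinstance(key, tuple):
        h = 0
        for part in key:
            h = zlib.crc32(key_to_int(part).to_bytes(4, "little"), h)
        return h
    return zlib.crc32(str(key).encode())


def stream(seed: int, *keys) -> np.random.Generator:
    """A generator seeded by ``seed`` plus a tuple of stream keys.

    Equal (seed, keys) always yields an identical stream; distinct keys give
    statistically independent streams (numpy SeedSequence entropy pooling).
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
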