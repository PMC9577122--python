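"""Seed-substream derivation.

All randomness in the pipeline flows from a single integer seed through
named substreams, so changing how one consumer draws never perturbs the
others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream_seed(seed: int, name: str) -> int:
    """Derive a deterministic 32-bit child seed for a named substream."""
    return zlib.crc32(name.encode("utf-8"), int(seed) & 0xFFFFFFFF)


def substream(seed: int, name: str) -> np.random.Generator:
    """A generator seeded from (seed, name), independent across names."""
    return np.random.default_rng([int(seed) & 0xFFFFFFFF, substream_seed(seed, name)])
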