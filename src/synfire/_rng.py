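"""Reproducible random-stream derivation.

All randomness in the package flows from one master seed. Independent streams
(one per purpose/index) are derived by hashing the master seed together with a
purpose tag, so adding a new stream never perturbs existing ones and results do
not depend on iteration order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream_rng", "stream_seed"]


def stream_seed(master: int, *tags) -> int:
    """Derive a 31-bit child seed from ``master`` and a tuple of hashable tags."""
    digest = zlib.crc32(repr(tags).encode("utf-8")) & 0xFFFFFFFF
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, digest])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def stream_rng(master: int, *tags) -> np.random.Generator:
    """A ``numpy`` Generator seeded from ``stream_seed(master, *tags)``."""
    return np.random.default_rng(stream_seed(master, *tags))
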