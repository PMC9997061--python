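"""Named random substreams.

A single user-facing seed is expanded into independent, reproducible
generators for each stochastic component (coordinate noise, decoding orders,
sampling draws, dataset jitter, dropout).  Tags are hashed stably so the
same (seed, tags) pair always yields the same stream, on any platform.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def _tag_key(tag) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag) & 0xFFFFFFFF
    return zlib.crc32(str(tag).encode("utf-8"))


def substream(seed: int, *tags) -> np.random.Generator:
    """Generator for the substream named by `tags` under the global `seed`."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(_tag_key(t) for t in tags))
    return np.random.default_rng(ss)


def substream_seed(seed: int, *tags) -> int:
    """A derived integer seed (< 2^31) for APIs that take a plain seed."""
    return int(substream(seed, *tags).integers(0, 2**31 - 1))
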