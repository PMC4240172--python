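"""Reproducible random-number streams.

Every stochastic operation in the package takes an explicit seed. A master
seed fans out to independent per-module streams through a counter-based
scheme built on :class:`numpy.random.SeedSequence`: string tags are hashed
(CRC32) into the spawn key, so the stream used by e.g. the gamete dropper
is stable no matter how many other streams a driver opens first.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "child_seed"]


def _key(tags: tuple) -> tuple[int, ...]:
    out = []
    for t in tags:
        if isinstance(t, (int, np.integer)):
            out.append(int(t) & 0xFFFFFFFF)
        else:
            out.append(zlib.crc32(str(t).encode()))
    return tuple(out)


def stream(seed: int, *tags) -> np.random.Generator:
    """Return a Generator for ``seed`` scoped by ``tags``.

    The same (seed, tags) pair always yields the same stream; different
    tags yield statistically independent streams.
    """
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=_key(tags)))


def child_seed(seed: int, *tags) -> int:
    """Derive a small (< 2**31) integer seed scoped by ``tags``."""
    return int(stream(seed, *tags).integers(0, 2**31 - 1))
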