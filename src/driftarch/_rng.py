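"""Seed-splitting scheme used across the package.

Every stochastic stage derives its generator from a single user-facing
integer seed through :func:`stage_rng`.  The stage is identified by a
tuple of labels (strings are hashed with CRC-32, integers pass through),
which becomes the ``spawn_key`` of a :class:`numpy.random.SeedSequence`.
Two calls with the same (seed, labels) always return identically-seeded
generators, and distinct labels give statistically independent streams,
so every pipeline stage is independently reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "stage_seed_sequence"]


def _key_part(part: int | str) -> int:
    if isinstance(part, (int, np.integer)):
        if part < 0:
            raise ValueError("seed-path integers must be non-negative")
        return int(part)
    return zlib.crc32(str(part).encode("utf-8"))


def stage_seed_sequence(seed: int, *path: int | str) -> np.random.SeedSequence:
    """SeedSequence for a named pipeline stage under a master ``seed``."""
    return np.random.SeedSequence(int(seed), spawn_key=tuple(_key_part(p) for p in path))


def stage_rng(seed: int, *path: int | str) -> np.random.Generator:
    """PCG64 generator for a named pipeline stage under a master ``seed``."""
    return np.random.Generator(np.random.PCG64(stage_seed_sequence(seed, *path)))
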