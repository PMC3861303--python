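"""Deterministic per-stage seed derivation.

Every stochastic stage derives its RNG from ``(master_seed, stage_name)``
so that stage outputs are reproducible independently of how many other
stages ran before them.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_seed", "stage_rng"]


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    """A :class:`numpy.random.SeedSequence` that is a pure function of the
    master seed and a stage name (CRC32 of the name, platform-stable)."""
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """PCG64 generator seeded from :func:`stage_seed`."""
    return np.random.default_rng(stage_seed(master_seed, stage))
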