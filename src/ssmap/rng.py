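"""Random-number policy: one master seed, named sub-streams per stage.

Every stochastic operation accepts either an integer seed or an existing
:class:`numpy.random.Generator`.  Pipeline stages derive independent streams
from the master seed and a stage name, so a stage can be re-run in isolation
and still reproduce its part of a full run.
"""
from __future__ import annotations

import zlib

import numpy as np

__all__ = ["as_rng", "stage_rng"]


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Return ``seed`` itself if it is already a Generator, else seed one."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage stream derived from the master seed.

    The stage name is hashed with CRC32 so streams are decoupled between
    stages but stable across runs and platforms.
    """
    entropy = [int(master_seed) & 0x7FFFFFFF, zlib.crc32(stage.encode("utf-8"))]
    return np.random.default_rng(np.random.SeedSequence(entropy))
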