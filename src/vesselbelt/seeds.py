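"""Seed policy: one root seed per run, independent streams per stage.

Every stochastic operation accepts either a `numpy.random.Generator` or an
integer seed.  Pipelines derive per-stage generators from the root seed and a
stage name, so any stage can be re-run in isolation and still see the same
stream it saw inside the full pipeline.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed", "as_rng"]

_MOD = 2**31


def derive_seed(root_seed: int, stage: str) -> int:
    """Deterministic child seed (< 2**31) for a named stage."""
    return int((int(root_seed) + zlib.crc32(stage.encode("utf-8"))) % _MOD)


def derive_rng(root_seed: int, stage: str) -> np.random.Generator:
    """Independent generator for (root seed, stage name)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(root_seed) % _MOD, zlib.crc32(stage.encode("utf-8"))])
    )


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed, Generator or None into a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
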