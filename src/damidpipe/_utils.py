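"""Small shared helpers: deterministic seed derivation and validation."""

from __future__ import annotations

import zlib

import numpy as np

MAX_SEED = 2**31 - 1


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage sub-seed from a global seed.

    Uses CRC32 of the stage name so every stage gets an independent,
    reproducible stream and can be re-run in isolation.
    """
    return (int(seed) ^ zlib.crc32(stage.encode("utf-8"))) % MAX_SEED


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(seed, stage))
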