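"""Deterministic seed fan-out.

One top-level integer seed is expanded into independent substreams keyed by
stage name (and optional extra integers), so re-running a late pipeline stage
never perturbs the randomness of earlier stages.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(seed: int, stage: str, *keys: int) -> int:
    """Derive a 31-bit child seed from (seed, stage, *keys)."""
    tag = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(tag, *map(int, keys)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def child_rng(seed: int, stage: str, *keys: int) -> np.random.Generator:
    """A numpy Generator on the substream for (seed, stage, *keys)."""
    tag = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(tag, *map(int, keys)))
    return np.random.default_rng(ss)
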