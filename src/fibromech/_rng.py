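"""Seeded substream management.

A single integer seed drives every stochastic stage of the pipeline.  Each
stage (and each unit of work within a stage, e.g. one force level of a
population simulation) draws from its own named substream so that enlarging
one stage never perturbs the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator for the substream identified by ``keys``.

    Identical (seed, keys) always yields an identical stream; distinct key
    tuples yield statistically independent streams.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
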