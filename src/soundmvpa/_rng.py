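"""Deterministic per-stage random streams derived from one top-level seed."""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(seed: int, *tags) -> np.random.SeedSequence:
    """Derive a SeedSequence for a named stage from the top-level seed.

    Tags (strings/ints) are hashed with crc32 so that streams for different
    stages, subjects or repetitions are independent but fully reproducible.
    """
    keys = [int(seed) & 0x7FFFFFFF]
    for t in tags:
        keys.append(zlib.crc32(str(t).encode("utf8")))
    return np.random.SeedSequence(keys)


def rng_for(seed: int, *tags) -> np.random.Generator:
    """A Generator for a named stage; same (seed, tags) -> identical stream."""
    return np.random.default_rng(child_seed(seed, *tags))
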