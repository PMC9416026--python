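"""Named-stream seed fan-out.

A single global seed is split into independent per-stage streams keyed by a
stable name, so adding a stage never perturbs the random draws of earlier
ones.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(seed: int, name: str) -> int:
    """Derive a deterministic 31-bit child seed for a named stream."""
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=(key,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def stream(seed: int, name: str) -> np.random.Generator:
    """Generator for the named child stream."""
    return np.random.default_rng(child_seed(seed, name))
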