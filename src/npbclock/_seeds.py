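"""Named substreams derived from a single master seed.

Every stochastic stage draws its RNG via ``rng_for(master, "stage", idx...)``
so stages are independently reproducible and insensitive to execution order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["seed_for", "rng_for"]


def seed_for(master: int, *tokens) -> np.random.SeedSequence:
    """Deterministic SeedSequence for a (master seed, token...) path."""
    keys = [zlib.crc32(str(t).encode("utf8")) for t in tokens]
    return np.random.SeedSequence(entropy=int(master), spawn_key=tuple(keys))


def rng_for(master: int, *tokens) -> np.random.Generator:
    return np.random.default_rng(seed_for(master, *tokens))
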