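"""Seed handling.

All randomness flows through numpy Generators seeded from a SeedSequence tree:
one root seed per experiment, one child per (scenario, design) cell, one child
per replicate, and three named streams per trial (allocation, deviations,
outcomes).  Adding replicates or cells never perturbs the draws of earlier ones.
"""
from __future__ import annotations

import numpy as np

SeedLike = "int | np.random.SeedSequence | np.random.Generator"


def seed_sequence(seed) -> np.random.SeedSequence:
    """Coerce an int or SeedSequence to a SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def rng_from(seed) -> np.random.Generator:
    """Coerce an int, SeedSequence or Generator to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn(seed, n: int) -> list[np.random.SeedSequence]:
    """Spawn ``n`` independent child SeedSequences."""
    return seed_sequence(seed).spawn(n)
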