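"""Seed plumbing shared by every stochastic component.

All randomness in the package flows from :class:`numpy.random.SeedSequence`
substreams so that independent components (factor initialisation, GA
operators, hold-out splits, ...) never perturb one another's draws.
"""

from __future__ import annotations

import numpy as np

__all__ = ["spawn_seeds", "seed_to_int", "rng_from"]


def spawn_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    """Split ``master_seed`` into ``n`` independent child seed sequences."""
    return np.random.SeedSequence(master_seed).spawn(n)


def seed_to_int(seed: int | np.random.SeedSequence) -> int:
    """A 31-bit integer seed (what scikit-learn's ``random_state`` accepts)."""
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1)[0] % (2**31 - 1))
    return int(seed) % (2**31 - 1)


def rng_from(seed: int | np.random.SeedSequence | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
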