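"""Small shared helpers: splittable seeding."""

from __future__ import annotations

import numpy as np


def child_seed(master_seed: int, *key: int) -> int:
    """Deterministic child seed spawned from a master seed and an index key.

    Uses numpy's SeedSequence spawn-key mechanism, so (master, key) pairs give
    statistically independent streams and adding further keys (more repeats,
    more representatives) never changes existing ones. The returned value is
    below 2**31.
    """
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def child_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Generator seeded by :func:`child_seed`."""
    return np.random.default_rng(child_seed(master_seed, *key))
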