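"""Stateless seed derivation.

`numpy.random.SeedSequence.spawn` advances an internal counter, so spawning
twice from the same object yields different children.  Reproducibility here
requires that the same (seed, index) always maps to the same stream, no
matter how often or in which order streams are derived — these helpers
construct children positionally instead.
"""

from __future__ import annotations

import numpy as np

__all__ = ["as_seed_sequence", "child_sequences"]


def as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def child_sequences(seed, n: int) -> list[np.random.SeedSequence]:
    """The first `n` children of `seed`, derived without mutating it."""
    ss = as_seed_sequence(seed)
    base = tuple(ss.spawn_key)
    return [np.random.SeedSequence(entropy=ss.entropy,
                                   spawn_key=base + (i,))
            for i in range(n)]
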