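"""Seed plumbing: one root seed, hierarchical child streams.

Every stochastic entry point accepts either an integer seed or a
``numpy.random.Generator``; child streams for per-trajectory / per-replication
work are derived with ``Generator.spawn`` so results do not depend on
execution order or parallelisation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["as_rng"]


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
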