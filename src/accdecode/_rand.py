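"""Seed handling.

Every stochastic operation in the package takes an explicit integer seed and
builds an independent :class:`numpy.random.Generator` from it.  Child seeds for
sub-stages are derived with ``numpy.random.SeedSequence.spawn`` so that stages
are decoupled: changing the number of draws in one stage does not perturb the
others.
"""

from __future__ import annotations

import numpy as np

__all__ = ["require_seed", "rng_from", "spawn_seeds"]


class MissingSeedError(ValueError):
    """Raised when a stochastic operation is called without an explicit seed."""


def require_seed(seed) -> int:
    if seed is None or isinstance(seed, bool):
        raise MissingSeedError(
            "stochastic operations require an explicit integer seed"
        )
    return int(seed)


def rng_from(seed) -> np.random.Generator:
    return np.random.default_rng(require_seed(seed))


def spawn_seeds(seed, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from ``seed``."""
    ss = np.random.SeedSequence(require_seed(seed))
    return [int(s.generate_state(1, dtype=np.uint32)[0] % (2**31)) for s in ss.spawn(n)]
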