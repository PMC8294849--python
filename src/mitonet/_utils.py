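"""Small numeric helpers used across modules."""

from __future__ import annotations

import math

import numpy as np


def round_half_away(x: float) -> int:
    """Round half away from zero (0.5 -> 1, -0.5 -> -1).

    Python's round() rounds half to even; constructed fractions such as
    round(n * fraction) must be reproducible regardless of parity, so all
    target-count rounding in the package goes through this function.
    """
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def allocate_counts(total: int, proportions) -> np.ndarray:
    """Integer counts per class summing exactly to ``total``.

    Each class receives round_half_away(total * p); any rounding remainder
    (positive or negative) is assigned one unit at a time to the
    lowest-index classes, so the allocation is deterministic.
    """
    proportions = np.asarray(proportions, dtype=float)
    counts = np.array([round_half_away(total * p) for p in proportions], dtype=int)
    excess = int(counts.sum()) - int(total)
    i = 0
    while excess != 0:
        step = -1 if excess > 0 else 1
        if counts[i % len(counts)] + step >= 0:
            counts[i % len(counts)] += step
            excess += step
        i += 1
    return counts


def spawn_rng(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for a sub-task, derived from a base seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))
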