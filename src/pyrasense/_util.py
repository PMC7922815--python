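"""Small shared helpers: report rounding and seed handling."""

from __future__ import annotations

import math

import numpy as np

#: Guessing probability of a 3-alternative forced-choice task.
CHANCE_3AFC = 1.0 / 3.0


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero, as printed sensory tables do.

    Python's built-in ``round`` uses banker's rounding (0.5 -> 0), which does
    not match how concentration/OAV tables are conventionally reported.
    """
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def rng_from_seed(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Accept a seed or an existing Generator and return a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
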