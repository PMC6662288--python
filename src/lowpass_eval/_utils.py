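"""Small shared helpers: deterministic rounding and RNG plumbing."""

from __future__ import annotations

import decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (never banker's rounding).

    Report percentages the way humans print them: 12.45 -> 12.5, never 12.4.
    """
    if not np.isfinite(x):
        return x
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage at fixed printed precision; denominator must be positive."""
    if denominator <= 0:
        raise ZeroDivisionError("percentage undefined for non-positive denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def child_rng(seed: int | np.random.Generator | None, *salt: int) -> np.random.Generator:
    """Derive an independent Generator from a seed plus a salt tuple.

    Keeps every stochastic stage bit-reproducible under a single integer seed
    while decoupling streams (so adding reads does not shift genotype draws).
    """
    if isinstance(seed, np.random.Generator):
        return seed
    ss = np.random.SeedSequence(entropy=seed, spawn_key=salt)
    return np.random.default_rng(ss)
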