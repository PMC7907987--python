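"""Small shared helpers: exact percentage rounding and seed derivation."""

from __future__ import annotations

from fractions import Fraction

import numpy as np

MAX_SEED = 2**31 - 1


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero, as clinical tables are printed.

    Python's built-in ``round`` uses banker's rounding (0.05 -> 0.0); printed
    cohort rates round 0.05 up to 0.1, so we do the same.
    """
    frac = Fraction(x).limit_denominator(10**12) if not isinstance(x, Fraction) else x
    scale = Fraction(10) ** ndigits
    scaled = frac * scale
    if scaled >= 0:
        rounded = (scaled + Fraction(1, 2)).__floor__()
    else:
        rounded = -((-scaled + Fraction(1, 2)).__floor__())
    return float(Fraction(rounded, 1) / scale)


def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Exact count ratio as a percentage, rounded half-up to `ndigits` decimals.

    Computed in rational arithmetic so e.g. 817/1015 -> 80.5 exactly, with no
    binary-float drift at the rounding boundary.
    """
    if denominator <= 0:
        raise ValueError("denominator must be a positive count")
    if numerator < 0:
        raise ValueError("numerator must be a nonnegative count")
    return round_half_up(Fraction(100 * numerator, denominator), ndigits)


def derive_seed(seed_sequence: np.random.SeedSequence) -> int:
    """One 31-bit integer seed from a SeedSequence child (fits sklearn's range)."""
    return int(seed_sequence.generate_state(1, np.uint64)[0] % MAX_SEED)
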