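"""Deterministic staining quantification formulas.

* H-score: immunohistochemistry intensity summary,
  3 x %strong + 2 x %moderate + 1 x %weak, ranging 0-300.
* Optical density from an 8-bit image gray value: OD = log10(255 / gray).
* Positivity rate: percent positive out of total, rounded half-up.
"""

from __future__ import annotations

import math

from .util import InputError, round_half_up

PCT_SUM_TOLERANCE = 0.5  # absorbs rounded percentage inputs


def h_score(
    pct_strong: float,
    pct_moderate: float,
    pct_weak: float,
    pct_unstained: float | None = None,
) -> float:
    """Weighted staining-intensity score in [0, 300].

    Unstained cells carry weight 0, so ``pct_unstained`` only enters the
    consistency check that the percentages sum to at most 100.
    """
    parts = [pct_strong, pct_moderate, pct_weak]
    if pct_unstained is not None:
        parts.append(pct_unstained)
    for p in parts:
        if not 0.0 <= p <= 100.0:
            raise InputError(f"percentage {p} outside [0, 100]")
    if sum(parts) > 100.0 + PCT_SUM_TOLERANCE:
        raise InputError(f"percentages sum to {sum(parts)} > 100")
    return 3.0 * pct_strong + 2.0 * pct_moderate + 1.0 * pct_weak


def od_from_gray(gray_value: float) -> float:
    """Optical density of a stain from the mean gray value of the
    deconvolved channel: OD = log10(255 / gray). Gray 255 (pure white)
    gives OD 0; darker staining gives larger OD."""
    if not 0.0 < gray_value <= 255.0:
        raise InputError(f"gray value {gray_value} outside (0, 255]")
    return math.log10(255.0 / gray_value)


def positivity_rate(n_pos: int, n_total: int, digits: int = 0) -> float:
    """Percent positive, rounded half-up to ``digits`` decimals."""
    if n_total <= 0:
        raise InputError("n_total must be positive")
    if not 0 <= n_pos <= n_total:
        raise InputError(f"n_pos={n_pos} outside [0, {n_total}]")
    return round_half_up(100.0 * n_pos / n_total, digits)
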