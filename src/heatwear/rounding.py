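"""Decimal rounding with half-up ties.

Report tables round with ties away from zero (0.25 -> 0.3 at one digit),
which binary-float ``round()`` (banker's rounding) does not do; all printed
percentages and model estimates therefore go through :func:`round_half_up`.
"""
from __future__ import annotations

import decimal
import math
from typing import overload

import numpy as np

__all__ = ["round_half_up"]


@overload
def round_half_up(value: float, digits: int = 0) -> float: ...
@overload
def round_half_up(value: np.ndarray, digits: int = 0) -> np.ndarray: ...


def round_half_up(value, digits: int = 0):
    """Round to ``digits`` decimal places, ties away from zero.

    Performed in decimal arithmetic on the shortest repr of the float so that
    e.g. ``round_half_up(0.25, 1) == 0.3`` and ``round_half_up(7.843, 1) ==
    7.8``. NaN and infinities pass through unchanged. Accepts scalars or
    numpy arrays.
    """
    if digits < 0:
        raise ValueError(f"digits must be >= 0, got {digits}")
    if isinstance(value, np.ndarray):
        return np.array([round_half_up(float(v), digits) for v in value.ravel()]).reshape(value.shape)
    v = float(value)
    if not math.isfinite(v):
        return v
    quantum = decimal.Decimal(1).scaleb(-digits)
    return float(decimal.Decimal(repr(v)).quantize(quantum, rounding=decimal.ROUND_HALF_UP))
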