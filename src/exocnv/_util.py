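"""Small shared numerics: rounding conventions and interval overlap."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding, matching how summary-table percentages are printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    """Reciprocal overlap of two intervals: min over both intervals of the
    fraction covered by their intersection. Vectorised over numpy inputs."""
    inter = np.minimum(a_end, b_end) - np.maximum(a_start, b_start)
    inter = np.maximum(inter, 0)
    len_a = np.asarray(a_end) - np.asarray(a_start)
    len_b = np.asarray(b_end) - np.asarray(b_start)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.minimum(inter / len_a, inter / len_b)
    return frac
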