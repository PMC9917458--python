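"""Percentile rank of a value against a background distribution."""

from __future__ import annotations

import math
from collections.abc import Iterable


def percentile_rank(value: float, background: Iterable[float]) -> float:
    """Percentile of ``value`` in ``background``: strictly-below fraction
    times 100, ties counted as half.
    """
    bg = list(background)
    if not bg:
        raise ValueError("background must be nonempty")
    if any(isinstance(x, float) and math.isnan(x) for x in bg) or (
        isinstance(value, float) and math.isnan(value)
    ):
        raise ValueError("NaN in percentile computation")
    below = sum(1 for x in bg if x < value)
    ties = sum(1 for x in bg if x == value)
    return 100.0 * (below + 0.5 * ties) / len(bg)
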