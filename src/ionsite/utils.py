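"""Small shared helpers."""

from __future__ import annotations

import math

__all__ = ["round_half_away"]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (report/display convention).

    Python's built-in ``round`` uses banker's rounding; published tables
    round half away from zero, so −23.25 displays as −23.3.
    """
    scale = 10.0**decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale
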