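"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention used in the report tables).

    Python's built-in ``round`` rounds ties to even, which would turn e.g.
    78.485% into 78.4 instead of the conventional 78.5.
    """
    factor = 10.0**ndigits
    if x >= 0:
        return math.floor(x * factor + 0.5) / factor
    return -math.floor(-x * factor + 0.5) / factor
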