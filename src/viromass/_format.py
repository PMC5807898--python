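"""Display-rounding helpers shared by report renderers.

Conventions: counts/copies to two significant figures (scientific notation),
virus-to-cell ratios to two decimals, percentages to one decimal, and
contamination ratios to one significant figure.  Unrounded values are always
kept alongside rounded ones; rounding is display-only.
"""

from __future__ import annotations

import math


def round_sig(x: float, n_sig: int = 2) -> float:
    """Round ``x`` to ``n_sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (n_sig - 1))


def format_sci(x: float, n_sig: int = 2) -> str:
    """Two-sig-fig scientific notation, e.g. ``5.3e+06``."""
    if x == 0:
        return "0"
    return f"{round_sig(x, n_sig):.{n_sig - 1}e}"
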