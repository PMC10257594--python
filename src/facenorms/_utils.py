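"""Small numeric helpers used throughout the toolkit."""

from __future__ import annotations

import numpy as np


def round_half_away(x, ndigits: int = 0):
    """Round half away from zero (27.5 -> 28, -27.5 -> -28).

    numpy's default rounding is banker's (half-to-even); the published tables
    and the worked percentage examples follow the conventional half-away rule,
    so all reported rounding in this package goes through here.
    Accepts scalars or arrays; returns the same shape.
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0**ndigits
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    if out.ndim == 0:
        return float(out)
    return out
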