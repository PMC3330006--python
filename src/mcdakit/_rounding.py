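"""Rounding conventions used throughout the package.

All printed statistics follow commercial rounding — half away from zero —
not banker's rounding (Python's built-in ``round``). Committee statistics
are reported at 1 decimal place, percentages as integers.
"""

from __future__ import annotations

import numpy as np

__all__ = ["round_half_away", "percent"]


def round_half_away(x, decimals: int = 0):
    """Round half away from zero (4.65 -> 4.7, -4.65 -> -4.7).

    Works on scalars and arrays; returns the same shape. A small epsilon
    guards against binary-float representations of exact halves (e.g.
    2.675 stored as 2.67499...).
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    scaled = x * factor
    eps = np.finfo(float).eps * np.maximum(np.abs(scaled), 1.0) * 4
    out = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5 + eps) / factor
    if decimals <= 0:
        out = out.astype(int) if out.ndim else int(out)
    elif out.ndim == 0:
        out = float(out)
    return out


def percent(count, total) -> int:
    """Integer percentage of ``count`` out of ``total``, half away from zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(round_half_away(100.0 * count / total, 0))
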