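"""Small shared numerics."""

from __future__ import annotations

import numpy as np


def weighted_median(values, weights) -> float:
    """Weighted median; on an exact half split returns the lower value.

    Deterministic tie handling matters because event calls compare the
    median copy number against exactly 2.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("weighted_median of empty input")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def round_half_away(x, decimals: int = 1):
    """Round half away from zero (81.85 -> 81.9), unlike numpy's half-to-even."""
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out
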