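"""Shared statistical kernels.

One pairwise-complete Pearson implementation backs both the co-dependency
profiling (dependency scores) and the proteomics co-expression scan, so the
two streams agree exactly on identical inputs.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def pairwise_complete_pearson(
    x: np.ndarray, y: np.ndarray, min_n: int = 3
) -> tuple[float, int] | None:
    """Pearson r over positions where both vectors are finite.

    Returns ``(r, n)`` or ``None`` when fewer than ``min_n`` shared
    observations exist or either vector is constant over the shared support
    (r undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < min_n:
        return None
    xs = x[mask]
    ys = y[mask]
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    sx = float(np.sqrt(np.dot(xc, xc)))
    sy = float(np.sqrt(np.dot(yc, yc)))
    if sx == 0.0 or sy == 0.0:
        return None
    r = float(np.dot(xc, yc) / (sx * sy))
    return max(-1.0, min(1.0, r)), n


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via the t transform on n-2 df."""
    if n < 3:
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))
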