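"""Median-absolute-deviation outlier flagging shared by all filter stages."""

from __future__ import annotations

import numpy as np

#: Consistency constant making the MAD an unbiased sigma estimate for
#: Gaussian data.  All filters use the scaled MAD by default; pass
#: ``scale=1.0`` for the raw MAD.
MAD_SCALE = 1.4826


def mad(x: np.ndarray, scale: float = MAD_SCALE) -> float:
    """Scaled median absolute deviation of ``x`` (NaNs ignored)."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return np.nan
    med = np.median(x)
    return scale * float(np.median(np.abs(x - med)))


def mad_outliers_global(x: np.ndarray, k: float, scale: float = MAD_SCALE) -> np.ndarray:
    """Flag values more than ``k`` MADs from the global median.

    Zero-spread convention: when the MAD is 0, any deviation from the
    median is flagged.  NaNs are never flagged (they are "missing", not
    "outlying").
    """
    x = np.asarray(x, dtype=float)
    finite = np.isfinite(x)
    out = np.zeros(x.shape, dtype=bool)
    if not finite.any():
        return out
    med = np.median(x[finite])
    m = mad(x[finite], scale=scale)
    out[finite] = np.abs(x[finite] - med) > k * m
    return out


def mad_outliers_sliding(
    values: np.ndarray, k: float, window: int, scale: float = MAD_SCALE
) -> np.ndarray:
    """Flag rows deviating > ``k`` MAD from their sliding-window median.

    ``values`` is (n, n_features); a row is flagged if ANY of its
    features deviates.  The window is centered on each row and truncated
    at the edges.  Zero-spread convention as in
    :func:`mad_outliers_global`.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    n = values.shape[0]
    if window < 1:
        raise ValueError("window must be >= 1")
    half = window // 2
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, lo + window)
        lo = max(0, hi - window)
        block = values[lo:hi]
        med = np.nanmedian(block, axis=0)
        m = scale * np.nanmedian(np.abs(block - med), axis=0)
        dev = np.abs(values[i] - med)
        with np.errstate(invalid="ignore"):
            flags[i] = bool(np.any(dev > k * m))
    return flags
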