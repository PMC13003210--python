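"""Windowed feature time series: per-breath multimodal features are
averaged over sliding windows, window-level outliers removed and
refilled by linear interpolation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from respimodal.config import FusionConfig
from respimodal.ls import MULTIMODAL_FEATURES
from respimodal.outliers import MAD_SCALE, mad_outliers_global

logger = logging.getLogger(__name__)


def build_timeseries(
    breaths: pd.DataFrame,
    duration: float | None = None,
    config: FusionConfig | None = None,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Average per-breath features over 32-s windows with 75% overlap.

    A breath contributes to every window containing its inspiration
    onset.  Windows without any breath get NaN (filled later by
    :func:`remove_window_outliers`).  Returns one row per window with
    ``window_start_s`` plus the feature columns.
    """
    config = config or FusionConfig()
    features = features or [c for c in MULTIMODAL_FEATURES if c in breaths.columns]
    win = config.win_s
    hop = win * (1 - config.overlap)
    if breaths.empty:
        return pd.DataFrame(columns=["window_start_s"] + features)
    onsets = breaths["inspiration_onset_s"].to_numpy()
    if duration is None:
        duration = float(onsets.max()) + 1e-9
    n_win = max(int(np.floor(max(duration - win, 0.0) / hop)) + 1, 1)
    starts = hop * np.arange(n_win)
    rows = []
    for s in starts:
        sel = (onsets >= s) & (onsets < s + win)
        if sel.any():
            rows.append([s] + [float(breaths.loc[sel, f].mean()) for f in features])
        else:
            rows.append([s] + [np.nan] * len(features))
    return pd.DataFrame(rows, columns=["window_start_s"] + features)


def remove_window_outliers(
    series: pd.DataFrame, config: FusionConfig | None = None, scaled: bool = True
) -> pd.DataFrame:
    """Remove window means lying > ``mad_k`` MAD from the series median
    and refill removed (and missing) values by linear interpolation over
    window index, extending edge values.

    Median and MAD are global over the recording's series.  Per feature
    by default; with ``config.per_feature=False`` a window flagged for
    any feature is removed for all of them.  Adds one ``interpolated_*``
    flag column per feature.
    """
    config = config or FusionConfig()
    if series.empty:
        return series.copy()
    features = [c for c in series.columns if c != "window_start_s"]
    scale = MAD_SCALE if scaled else 1.0
    out = series.copy()
    flags = {}
    outlier_mask = {}
    for f in features:
        x = out[f].to_numpy(dtype=float)
        bad = mad_outliers_global(x, config.mad_k, scale=scale)
        if bad.all():
            raise ValueError(f"all windows outlying for feature {f!r}")
        outlier_mask[f] = bad
    if not config.per_feature:
        any_bad = np.logical_or.reduce([outlier_mask[f] for f in features])
        outlier_mask = {f: any_bad for f in features}
    for f in features:
        x = out[f].to_numpy(dtype=float)
        bad = outlier_mask[f] | ~np.isfinite(x)
        if bad.all():
            raise ValueError(f"no surviving windows for feature {f!r}")
        idx = np.arange(len(x))
        filled = x.copy()
        filled[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
        out[f] = filled
        flags[f"interpolated_{f}"] = bad
    for k, v in flags.items():
        out[k] = v
    n_interp = int(np.sum([v.sum() for v in flags.values()]))
    if n_interp:
        logger.info("window outlier removal: %d window values interpolated", n_interp)
    return out


def run_fusion(
    breaths: pd.DataFrame,
    duration: float | None = None,
    config: FusionConfig | None = None,
    scaled_mad: bool = True,
) -> pd.DataFrame:
    """Windowed averaging followed by window-level outlier interpolation."""
    config = config or FusionConfig()
    series = build_timeseries(breaths, duration=duration, config=config)
    if series.empty:
        return series
    return remove_window_outliers(series, config, scaled=scaled_mad)
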