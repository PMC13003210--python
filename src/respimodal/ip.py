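"""Impedance-pneumography branch: conditioning, breath detection,
signal quality, per-breath timing features, and timing outlier removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from respimodal.config import IPConfig
from respimodal.outliers import MAD_SCALE, mad_outliers_sliding

logger = logging.getLogger(__name__)

TIMING_FEATURES = ["RR", "Ti", "Te", "TeTi", "TiIBI"]


@dataclass
class ImpedanceTrace:
    """Uniformly sampled bioimpedance trace for one excitation frequency."""

    samples: np.ndarray
    sample_rate: float
    excitation_khz: float = 150.0
    #: True where a sample was replaced by interpolation
    interpolation_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.interpolation_mask is None:
            self.interpolation_mask = np.zeros(len(self.samples), dtype=bool)
        else:
            self.interpolation_mask = np.asarray(self.interpolation_mask, dtype=bool)
            if len(self.interpolation_mask) != len(self.samples):
                raise ValueError("interpolation_mask length mismatch")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate


def _rational_ratio(target: float, current: float) -> tuple[int, int]:
    frac = Fraction(target / current).limit_denominator(10_000)
    return frac.numerator, frac.denominator


def resample_to_100hz(trace: ImpedanceTrace, target_hz: float = 100.0) -> ImpedanceTrace:
    """Polyphase FIR antialiasing resampling to the working rate.

    DC and passband content below the original Nyquist are preserved.
    """
    if len(trace.samples) == 0:
        raise ValueError("cannot resample an empty trace")
    if trace.sample_rate == target_hz:
        return trace
    up, down = _rational_ratio(target_hz, trace.sample_rate)
    # "line" edge padding: zero padding would drag the edges toward 0,
    # a huge transient for traces riding on a large baseline
    y = signal.resample_poly(trace.samples, up, down, padtype="line")
    mask = (
        signal.resample_poly(trace.interpolation_mask.astype(float), up, down) > 0.5
    )
    return ImpedanceTrace(
        samples=y,
        sample_rate=trace.sample_rate * up / down,
        excitation_khz=trace.excitation_khz,
        interpolation_mask=mask,
    )


def remove_amplitude_artifacts(
    trace: ImpedanceTrace, hi: float = 1.5, lo: float = 0.5
) -> ImpedanceTrace:
    """Replace transient high/low-amplitude samples by linear interpolation.

    A sample is flagged when it exceeds ``hi`` x median or falls below
    ``lo`` x median, the median being taken over the full recording
    before any replacement.  Flagged runs are refilled by linear
    interpolation between the nearest surviving samples (edges extended).
    """
    x = trace.samples
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    med = np.median(x)
    bad = (x > hi * med) | (x < lo * med)
    if bad.all():
        raise ValueError("all samples flagged; no anchor points to interpolate")
    if not bad.any():
        return ImpedanceTrace(
            x.copy(), trace.sample_rate, trace.excitation_khz,
            trace.interpolation_mask.copy(),
        )
    idx = np.arange(len(x))
    y = x.copy()
    y[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    frac = bad.mean()
    logger.info("amplitude artifact removal: %.3f%% of samples interpolated", 100 * frac)
    return ImpedanceTrace(
        y, trace.sample_rate, trace.excitation_khz,
        trace.interpolation_mask | bad,
    )


def _kaiser_bandpass(fs: float, f_lo: float, f_hi: float,
                     width_hz: float, atten_db: float = 40.0) -> np.ndarray:
    numtaps, beta = signal.kaiserord(atten_db, width_hz / (fs / 2))
    numtaps |= 1  # odd length, type-I linear phase
    return signal.firwin(
        numtaps, [f_lo, f_hi], window=("kaiser", beta), pass_zero=False, fs=fs
    )


def bandpass_ip(
    trace: ImpedanceTrace, f_lo: float = 0.1, f_hi: float = 1.0
) -> ImpedanceTrace:
    """Zero-phase Kaiser-window FIR bandpass isolating respiratory content.

    Forward-backward filtering removes the group delay so breath timing
    is undistorted; stopband attenuation is >= 40 dB per pass.
    """
    fs = trace.sample_rate
    if not (0 < f_lo < f_hi < fs / 2):
        raise ValueError("need 0 < f_lo < f_hi < Nyquist")
    taps = _kaiser_bandpass(fs, f_lo, f_hi, width_hz=f_lo)
    n = len(trace.samples)
    padlen = min(3 * (len(taps) - 1), n - 1)
    # demean first: the large DC baseline would otherwise leak into the
    # edge padding and create boundary transients
    x = trace.samples - trace.samples.mean()
    y = signal.filtfilt(taps, 1.0, x, padlen=padlen)
    return ImpedanceTrace(y, fs, trace.excitation_khz, trace.interpolation_mask.copy())


# ---------------------------------------------------------------------------
# breath detection


@dataclass
class BreathSegmentation:
    """Per-breath fiducials (seconds) with quality and outlier flags.

    Breaths run trough-to-trough; the intervening peak marks the
    inspiration-to-expiration transition.
    """

    inspiration_onsets: np.ndarray
    expiration_onsets: np.ndarray
    breath_ends: np.ndarray
    quality_ok: np.ndarray = field(default=None)  # type: ignore[assignment]
    outlier: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.inspiration_onsets = np.asarray(self.inspiration_onsets, dtype=float)
        self.expiration_onsets = np.asarray(self.expiration_onsets, dtype=float)
        self.breath_ends = np.asarray(self.breath_ends, dtype=float)
        n = len(self.inspiration_onsets)
        if self.quality_ok is None:
            self.quality_ok = np.zeros(n, dtype=bool)
        if self.outlier is None:
            self.outlier = np.zeros(n, dtype=bool)
        ok = (self.inspiration_onsets < self.expiration_onsets) & (
            self.expiration_onsets < self.breath_ends
        )
        if n and not ok.all():
            raise ValueError("breath fiducials must satisfy insp < exp < end")

    def __len__(self) -> int:
        return len(self.inspiration_onsets)

    @property
    def breath_ids(self) -> np.ndarray:
        return np.arange(len(self))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "breath_id": self.breath_ids,
                "inspiration_onset_s": self.inspiration_onsets,
                "expiration_onset_s": self.expiration_onsets,
                "breath_end_s": self.breath_ends,
                "quality_ok": self.quality_ok,
                "outlier": self.outlier,
            }
        )


def _window_starts(duration: float, win: float, hop: float) -> np.ndarray:
    if duration <= win:
        return np.array([0.0])
    starts = np.arange(0.0, duration - win + 1e-9, hop)
    if starts[-1] + win < duration - 1e-9:
        starts = np.append(starts, duration - win)
    return starts


def detect_breaths(ip: ImpedanceTrace, config: IPConfig | None = None) -> BreathSegmentation:
    """Windowed peak detection with a hard minimum inter-peak distance.

    Peaks (end-inspiration) are found per 32-s window with inter-peak
    distance >= ``min_peak_dist_s``; overlapping-window detections are
    merged by deduplicating peaks closer than ``peak_dedup_s``.  Breath
    boundaries are the troughs between consecutive peaks; only troughs
    that are genuine local minima delimit breaths, and any breath with
    IBI below the minimum distance is discarded.
    """
    config = config or IPConfig()
    x = ip.samples
    fs = ip.sample_rate
    n = len(x)
    dist = max(int(np.ceil(config.min_peak_dist_s * fs)), 1)
    win = config.detect_win_s
    hop = win - config.detect_overlap_s

    peaks: list[int] = []
    for start in _window_starts(n / fs, win, hop):
        i0 = int(round(start * fs))
        i1 = min(int(round((start + win) * fs)), n)
        p, _ = signal.find_peaks(x[i0:i1], distance=dist)
        peaks.extend(int(q) + i0 for q in p)
    if not peaks:
        logger.info("breath detection: no peaks found")
        return BreathSegmentation(np.array([]), np.array([]), np.array([]))

    # merge duplicates from overlapping windows, keeping the taller peak
    peaks = sorted(set(peaks))
    tol = int(round(config.peak_dedup_s * fs))
    merged: list[int] = []
    for p in peaks:
        if merged and p - merged[-1] <= tol:
            if x[p] > x[merged[-1]]:
                merged[-1] = p
            continue
        merged.append(p)
    # enforce the global minimum distance across window joins
    kept: list[int] = []
    for p in merged:
        if kept and p - kept[-1] < dist:
            if x[p] > x[kept[-1]]:
                kept[-1] = p
            continue
        kept.append(p)
    pk = np.array(kept)

    def is_local_min(i: int) -> bool:
        return 0 < i < n - 1 and x[i] <= x[i - 1] and x[i] <= x[i + 1]

    # candidate troughs: before the first peak, between consecutive
    # peaks, and after the last peak; only genuine local minima qualify
    troughs: list[int | None] = []
    t0 = int(np.argmin(x[: pk[0]])) if pk[0] > 0 else 0
    troughs.append(t0 if is_local_min(t0) else None)
    for a, b in zip(pk[:-1], pk[1:]):
        tm = a + int(np.argmin(x[a:b]))
        troughs.append(tm if is_local_min(tm) else None)
    tl = pk[-1] + int(np.argmin(x[pk[-1] :]))
    troughs.append(tl if is_local_min(tl) else None)

    insp, expi, ends = [], [], []
    for k, p in enumerate(pk):
        t_prev, t_next = troughs[k], troughs[k + 1]
        if t_prev is None or t_next is None:
            continue
        insp.append(t_prev)
        expi.append(int(p))
        ends.append(t_next)

    insp_t = np.array(insp) / fs
    expi_t = np.array(expi) / fs
    ends_t = np.array(ends) / fs
    valid = (insp_t < expi_t) & (expi_t < ends_t)
    valid &= (ends_t - insp_t) >= config.min_peak_dist_s
    return BreathSegmentation(insp_t[valid], expi_t[valid], ends_t[valid])


# ---------------------------------------------------------------------------
# signal quality


def _breath_waveform(
    x: np.ndarray, fs: float, t0: float, t1: float, length: int,
    time_normalize: bool,
) -> np.ndarray:
    i0 = int(round(t0 * fs))
    if time_normalize:
        i1 = int(round(t1 * fs))
        seg = x[i0 : max(i1, i0 + 2)]
        pos = np.linspace(0, len(seg) - 1, length)
        return np.interp(pos, np.arange(len(seg)), seg)
    seg = x[i0 : i0 + length]
    if len(seg) < length:
        seg = np.pad(seg, (0, length - len(seg)))
    return seg


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def assess_signal_quality(
    ip: ImpedanceTrace, seg: BreathSegmentation, config: IPConfig | None = None
) -> BreathSegmentation:
    """Template-correlation signal quality over sliding windows.

    Each 32-s window (75% overlap) passes when (a) the coefficient of
    variation of breath durations is <= ``sqi_cov``, (b) the mean
    correlation of each breath against the window's mean-breath template
    exceeds ``sqi_corr``, and (c) detected breaths cover >=
    ``sqi_coverage`` of the window.  Breaths are start-aligned at the
    median-IBI length for the template (per-breath time normalization is
    available via ``sqi_time_normalize``).  A breath is good if any
    window it belongs to passes.
    """
    config = config or IPConfig()
    if len(seg) == 0:
        return seg
    x = ip.samples
    fs = ip.sample_rate
    win = config.sqi_win_s
    hop = win * (1 - config.sqi_overlap)
    quality = np.zeros(len(seg), dtype=bool)

    for start in _window_starts(ip.duration, win, hop):
        end = start + win
        overlap = np.minimum(seg.breath_ends, end) - np.maximum(
            seg.inspiration_onsets, start
        )
        members = np.where(overlap > 0)[0]
        if len(members) < 2:
            continue
        ibis = seg.breath_ends[members] - seg.inspiration_onsets[members]
        cov = ibis.std() / ibis.mean()
        if cov > config.sqi_cov:
            continue
        coverage = overlap[members].sum() / win
        if coverage < config.sqi_coverage:
            continue
        length = max(int(round(np.median(ibis) * fs)), 4)
        waves = np.stack(
            [
                _breath_waveform(
                    x, fs, seg.inspiration_onsets[m], seg.breath_ends[m], length,
                    config.sqi_time_normalize,
                )
                for m in members
            ]
        )
        template = waves.mean(axis=0)
        corr = np.mean([_pearson(w, template) for w in waves])
        if corr > config.sqi_corr:
            quality[members] = True

    return BreathSegmentation(
        seg.inspiration_onsets,
        seg.expiration_onsets,
        seg.breath_ends,
        quality_ok=quality,
        outlier=seg.outlier.copy(),
    )


# ---------------------------------------------------------------------------
# timing features


def extract_timing_features(seg: BreathSegmentation) -> pd.DataFrame:
    """Per-breath timing feature table for quality-passing breaths.

    Columns: breath_id, inspiration onset, RR, Ti, Te, TeTi, TiIBI, IBI.
    """
    if len(seg) and not np.all(
        (seg.inspiration_onsets < seg.expiration_onsets)
        & (seg.expiration_onsets < seg.breath_ends)
    ):
        raise ValueError("non-monotone breath fiducials")
    keep = seg.quality_ok.astype(bool)
    ti = seg.expiration_onsets[keep] - seg.inspiration_onsets[keep]
    te = seg.breath_ends[keep] - seg.expiration_onsets[keep]
    ibi = ti + te
    return pd.DataFrame(
        {
            "breath_id": seg.breath_ids[keep],
            "inspiration_onset_s": seg.inspiration_onsets[keep],
            "RR": 60.0 / ibi,
            "Ti": ti,
            "Te": te,
            "TeTi": te / ti,
            "TiIBI": ti / ibi,
            "IBI": ibi,
        }
    ).reset_index(drop=True)


def remove_timing_outliers(
    feats: pd.DataFrame, config: IPConfig | None = None, scaled: bool = True
) -> pd.DataFrame:
    """Flag breaths whose RR, Te or Ti deviates > ``mad_k`` MADs from the
    median over a centered sliding window of ``mad_window`` breaths."""
    config = config or IPConfig()
    if len(feats) == 0:
        out = feats.copy()
        out["outlier"] = pd.Series([], dtype=bool)
        return out
    values = feats[["RR", "Te", "Ti"]].to_numpy()
    scale = MAD_SCALE if scaled else 1.0
    flags = mad_outliers_sliding(values, config.mad_k, config.mad_window, scale=scale)
    out = feats.copy()
    out["outlier"] = flags
    return out


def run_ip_pipeline(
    trace: ImpedanceTrace, config: IPConfig | None = None, scaled_mad: bool = True
) -> tuple[pd.DataFrame, BreathSegmentation]:
    """Full IP branch: condition, detect, quality-check, feature-extract,
    outlier-filter.  Returns (timing feature table, segmentation)."""
    config = config or IPConfig()
    trace = resample_to_100hz(trace, config.resample_hz)
    trace = remove_amplitude_artifacts(trace, config.artifact_hi, config.artifact_lo)
    filtered = bandpass_ip(trace, config.bp_lo_hz, config.bp_hi_hz)
    seg = detect_breaths(filtered, config)
    seg = assess_signal_quality(filtered, seg, config)
    feats = extract_timing_features(seg)
    feats = remove_timing_outliers(feats, config, scaled=scaled_mad)
    logger.info(
        "ip pipeline: %d breaths detected, %d quality_ok, %d after outlier removal",
        len(seg), int(seg.quality_ok.sum()), int((~feats["outlier"]).sum()),
    )
    return feats, seg
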