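"""Lung-sound branch: audio conditioning, IP-driven phase segmentation,
per-phase subband spectral integrated intensities (SIs), and the
acoustic outlier filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from respimodal.config import LSConfig, band_edges
from respimodal.outliers import MAD_SCALE, mad_outliers_sliding

logger = logging.getLogger(__name__)

PHASES = ("inspiration", "expiration")

#: canonical SI column names, inspiration first
SI_FEATURES = [
    f"SI_{int(lo)}_{int(hi)}_{suffix}"
    for suffix in ("I", "E")
    for lo, hi in ((100, 300), (300, 500), (500, 800), (800, 1000))
]


@dataclass
class AudioTrace:
    """Single-channel breath-sound audio."""

    samples: np.ndarray
    sample_rate: float
    channel: str = "anterior-right"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


def resample_audio(
    audio: AudioTrace, target_hz: float = 4000.0, allow_upsample: bool = False
) -> AudioTrace:
    """FIR antialiasing polyphase resampling to the working audio rate."""
    if audio.sample_rate == target_hz:
        return audio
    if target_hz > audio.sample_rate and not allow_upsample:
        raise ValueError(
            f"refusing to upsample {audio.sample_rate} -> {target_hz} Hz "
            "(pass allow_upsample=True to override)"
        )
    frac = Fraction(target_hz / audio.sample_rate).limit_denominator(10_000)
    y = signal.resample_poly(audio.samples, frac.numerator, frac.denominator)
    return AudioTrace(
        samples=y,
        sample_rate=audio.sample_rate * frac.numerator / frac.denominator,
        channel=audio.channel,
    )


def bandpass_audio(
    audio: AudioTrace, low: float = 100.0, high: float = 1000.0
) -> AudioTrace:
    """Zero-phase FIR bandpass; suppresses heart sounds below ``low`` and
    ambient noise above ``high`` without shifting event timing."""
    fs = audio.sample_rate
    if high >= fs / 2:
        raise ValueError("high cutoff must be below Nyquist")
    width = min(low, 0.1 * fs / 2 - 1e-9, (fs / 2 - high)) if low < fs / 2 else low
    width = max(width, 1.0)
    numtaps, beta = signal.kaiserord(40.0, width / (fs / 2))
    numtaps |= 1
    taps = signal.firwin(
        numtaps, [low, high], window=("kaiser", beta), pass_zero=False, fs=fs
    )
    n = len(audio.samples)
    padlen = min(3 * (numtaps - 1), n - 1)
    y = signal.filtfilt(taps, 1.0, audio.samples, padlen=padlen)
    return AudioTrace(samples=y, sample_rate=fs, channel=audio.channel)


# ---------------------------------------------------------------------------
# phase segmentation


def segment_phases(audio: AudioTrace, seg) -> pd.DataFrame:
    """Map breath fiducials to half-open audio sample intervals per phase.

    Only quality-passing, non-outlier breaths are segmented; breaths
    extending past the end of the audio are dropped (logged).
    Returns columns: breath_id, phase, start_sample, stop_sample.
    """
    fs = audio.sample_rate
    n = len(audio.samples)
    rows = []
    dropped = 0
    for bid, t0, t1, t2, ok, out in zip(
        seg.breath_ids,
        seg.inspiration_onsets,
        seg.expiration_onsets,
        seg.breath_ends,
        seg.quality_ok,
        seg.outlier,
    ):
        if not ok or out:
            continue
        i0, i1, i2 = (int(round(t * fs)) for t in (t0, t1, t2))
        if i2 > n:
            dropped += 1
            continue
        rows.append((int(bid), "inspiration", i0, i1))
        rows.append((int(bid), "expiration", i1, i2))
    if dropped:
        logger.info("segment_phases: dropped %d breaths past audio end", dropped)
    return pd.DataFrame(
        rows, columns=["breath_id", "phase", "start_sample", "stop_sample"]
    )


# ---------------------------------------------------------------------------
# spectral integrated intensities


def _frame(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    n_frames = 1 + (len(x) - win) // hop
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def segment_si(
    x: np.ndarray, fs: float, config: LSConfig | None = None
) -> tuple[np.ndarray, float] | None:
    """Subband SIs and raw cumulative intensity of one audio segment.

    Per 64-ms Hamming window (75% overlap) the modified periodogram is
    max-normalized, integrated over each band and divided by the
    integral over the full analysis range; per-window SIs are averaged
    across windows.  The raw intensity is the summed unnormalized PSD
    integral over the full range.  Returns None when the segment is
    shorter than one window.
    """
    config = config or LSConfig()
    win = int(round(config.psd_win_ms * 1e-3 * fs))
    hop = max(int(round(win * (1 - config.psd_overlap))), 1)
    if len(x) < win:
        return None
    frames = _frame(np.asarray(x, dtype=float), win, hop)
    taper = np.hamming(win)
    scale = 1.0 / (fs * (taper**2).sum())
    spec = np.fft.rfft(frames * taper, axis=1)
    psd = (spec.real**2 + spec.imag**2) * scale
    if win % 2:
        psd[:, 1:] *= 2.0
    else:
        psd[:, 1:-1] *= 2.0
    freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    df = fs / win

    lo_all, hi_all = band_edges(config.bands)
    bands = list(config.bands)
    band_sel = [
        (freqs >= lo) & (freqs < hi) if (lo, hi) != tuple(bands[-1])
        else (freqs >= lo) & (freqs <= hi)
        for lo, hi in bands
    ]
    total_sel = (freqs >= lo_all) & (freqs <= hi_all)

    raw_total = float((psd[:, total_sel].sum(axis=1) * df).sum())

    if config.per_window_si:
        peak = psd.max(axis=1, keepdims=True)
        peak[peak == 0] = 1.0
        psd_norm = psd / peak
        denom = psd_norm[:, total_sel].sum(axis=1)
        good = denom > 0
        if not good.any():
            sis = np.full(len(bands), np.nan)
        else:
            per_win = np.stack(
                [psd_norm[good][:, sel].sum(axis=1) / denom[good] for sel in band_sel],
                axis=1,
            )
            sis = per_win.mean(axis=0)
    else:
        mean_psd = psd.mean(axis=0)
        peak = mean_psd.max() or 1.0
        psd_norm = mean_psd / peak
        denom = psd_norm[total_sel].sum()
        sis = (
            np.array([psd_norm[sel].sum() / denom for sel in band_sel])
            if denom > 0
            else np.full(len(bands), np.nan)
        )
    return sis, raw_total


def compute_phase_si(
    audio: AudioTrace, intervals: pd.DataFrame, config: LSConfig | None = None
) -> pd.DataFrame:
    """Per-breath, per-phase SIs and raw intensities.

    One row per breath with both phases present; breaths whose phase
    segment is shorter than one analysis window are dropped (logged).
    Also computes the whole-breath raw intensity used by the acoustic
    outlier filter.
    """
    config = config or LSConfig()
    x = audio.samples
    fs = audio.sample_rate
    rows: dict[int, dict] = {}
    for bid, grp in intervals.groupby("breath_id"):
        entry: dict = {"breath_id": int(bid)}
        complete = True
        lo = hi = None
        for _, r in grp.iterrows():
            seg = x[r.start_sample : r.stop_sample]
            res = segment_si(seg, fs, config)
            if res is None:
                logger.info(
                    "compute_phase_si: breath %d %s shorter than one window",
                    bid, r.phase,
                )
                complete = False
                break
            sis, raw = res
            suffix = "I" if r.phase == "inspiration" else "E"
            for (blo, bhi), v in zip(config.bands, sis):
                entry[f"SI_{int(blo)}_{int(bhi)}_{suffix}"] = float(v)
            entry[f"raw_intensity_{suffix}"] = raw
            lo = r.start_sample if lo is None else min(lo, r.start_sample)
            hi = r.stop_sample if hi is None else max(hi, r.stop_sample)
        if not complete:
            continue
        res = segment_si(x[lo:hi], fs, config)
        entry["raw_intensity_breath"] = res[1] if res is not None else np.nan
        rows[int(bid)] = entry
    cols = (
        ["breath_id"]
        + SI_FEATURES
        + ["raw_intensity_I", "raw_intensity_E", "raw_intensity_breath"]
    )
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([rows[k] for k in sorted(rows)])[cols]


def remove_acoustic_outliers(
    acoustics: pd.DataFrame, config: LSConfig | None = None, scaled: bool = True
) -> pd.DataFrame:
    """Flag breaths whose raw intensities (breath, inspiration,
    expiration) deviate > ``mad_k`` MADs from the median over a centered
    sliding window of ``mad_window`` breaths."""
    config = config or LSConfig()
    out = acoustics.copy()
    if len(acoustics) == 0:
        out["outlier"] = pd.Series([], dtype=bool)
        return out
    values = acoustics[
        ["raw_intensity_breath", "raw_intensity_I", "raw_intensity_E"]
    ].to_numpy()
    scale = MAD_SCALE if scaled else 1.0
    out["outlier"] = mad_outliers_sliding(
        values, config.mad_k, config.mad_window, scale=scale
    )
    return out


# ---------------------------------------------------------------------------
# multimodal fusion of breath tables


def match_multimodal_breaths(
    timing: pd.DataFrame, acoustics: pd.DataFrame
) -> pd.DataFrame:
    """Inner join of breaths surviving both the IP and LS filter cascades.

    Output rows carry exactly 13 feature columns: RR, Ti, Te, TeTi,
    TiIBI plus the 8 per-phase subband SIs.
    """
    t = timing[~timing.get("outlier", False)] if "outlier" in timing else timing
    a = (
        acoustics[~acoustics.get("outlier", False)]
        if "outlier" in acoustics
        else acoustics
    )
    keep_t = ["breath_id", "inspiration_onset_s", "RR", "Ti", "Te", "TeTi", "TiIBI"]
    keep_a = ["breath_id"] + SI_FEATURES
    merged = pd.merge(t[keep_t], a[keep_a], on="breath_id", how="inner")
    if merged.empty:
        logger.info("match_multimodal_breaths: empty intersection")
    return merged.reset_index(drop=True)


#: the 13 multimodal feature columns, in canonical order
MULTIMODAL_FEATURES = ["RR", "Ti", "Te", "TeTi", "TiIBI"] + SI_FEATURES


def run_ls_pipeline(
    audio: AudioTrace, seg, config: LSConfig | None = None, scaled_mad: bool = True
) -> pd.DataFrame:
    """Full LS branch: resample, bandpass, segment phases, compute SIs,
    flag acoustic outliers."""
    config = config or LSConfig()
    if audio.sample_rate > config.resample_hz:
        audio = resample_audio(audio, config.resample_hz)
    audio = bandpass_audio(audio, config.bp_lo_hz, config.bp_hi_hz)
    intervals = segment_phases(audio, seg)
    acoustics = compute_phase_si(audio, intervals, config)
    acoustics = remove_acoustic_outliers(acoustics, config, scaled=scaled_mad)
    logger.info(
        "ls pipeline: %d breaths with acoustics, %d after outlier removal",
        len(acoustics), int((~acoustics["outlier"]).sum()) if len(acoustics) else 0,
    )
    return acoustics
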