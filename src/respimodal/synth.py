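"""Synthetic IP and lung-sound recordings with ground-truth annotations.

Generates quasi-periodic impedance traces (raised-cosine breath
excursions over a drifting baseline, with optional multiplicative
artifact transients) and phase-locked band-limited audio (inspiration
gain, optional wheeze tones), plus whole labeled cohorts whose
feature distributions approximate configurable group targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from respimodal.ip import ImpedanceTrace
from respimodal.ls import AudioTrace

Phase = Literal["inspiration", "expiration"]


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class ArtifactEvent:
    """Multiplicative step transient on the impedance trace."""

    onset_s: float
    duration_s: float
    scale: float  # multiplier of the local signal; must differ from 1

    def __post_init__(self) -> None:
        if self.scale == 1.0:
            raise ValueError("artifact scale must differ from 1")
        if self.duration_s <= 0:
            raise ValueError("artifact duration must be positive")


@dataclass(frozen=True)
class BreathPlan:
    """Per-breath (Ti, Te, amplitude) triples plus global nuisance terms.

    The breath list is cycled to fill the requested duration.
    """

    breaths: tuple[tuple[float, float, float], ...]
    baseline_ohm: float = 30.0
    drift_amplitude_ohm: float = 0.0
    drift_period_s: float = 60.0
    noise_sd_ohm: float = 0.0
    artifact_events: tuple[ArtifactEvent, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.breaths:
            raise ValueError("breath plan needs at least one breath")
        for ti, te, amp in self.breaths:
            if ti <= 0 or te <= 0:
                raise ValueError("Ti and Te must be positive")
            if amp <= 0:
                raise ValueError("breath amplitude must be positive")

    @classmethod
    def constant(cls, ti: float, te: float, amplitude: float = 1.0, **kw) -> "BreathPlan":
        return cls(breaths=((ti, te, amplitude),), **kw)

    @classmethod
    def random(
        cls,
        n_breaths: int,
        ti_range: tuple[float, float],
        te_range: tuple[float, float],
        amplitude: float = 1.0,
        seed: int = 0,
        **kw,
    ) -> "BreathPlan":
        rng = np.random.default_rng(seed)
        tis = rng.uniform(*ti_range, size=n_breaths)
        tes = rng.uniform(*te_range, size=n_breaths)
        breaths = tuple((float(a), float(b), amplitude) for a, b in zip(tis, tes))
        return cls(breaths=breaths, seed=seed, **kw)


@dataclass(frozen=True)
class WheezeComponent:
    frequency_hz: float
    phase: Phase
    snr_db: float


@dataclass(frozen=True)
class AcousticSpec:
    """Band-limited breath-sound noise with phase-dependent intensity."""

    base_noise_band: tuple[float, float] = (100.0, 1000.0)
    inspiration_gain_db: float = 6.0
    wheeze_components: tuple[WheezeComponent, ...] = ()
    sample_rate: float = 4000.0
    noise_rms: float = 0.05
    #: optional relative spectral power per band of ``band_partition``;
    #: None means flat within ``base_noise_band``
    band_powers: tuple[float, ...] | None = None
    band_partition: tuple[tuple[float, float], ...] = (
        (100.0, 300.0),
        (300.0, 500.0),
        (500.0, 800.0),
        (800.0, 1000.0),
    )
    ramp_s: float = 0.05  # raised-cosine ramp at phase boundaries
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.base_noise_band
        nyq = self.sample_rate / 2
        if not (0 < lo < hi <= nyq):
            raise ValueError("base_noise_band must lie within (0, Nyquist]")
        if not np.isfinite(self.inspiration_gain_db):
            raise ValueError("inspiration_gain_db must be finite")
        for w in self.wheeze_components:
            if w.frequency_hz >= nyq:
                raise ValueError(
                    f"wheeze frequency {w.frequency_hz} Hz >= Nyquist {nyq} Hz"
                )


@dataclass(frozen=True)
class GroundTruth:
    """Exact construction timings of every generated breath."""

    inspiration_onsets: np.ndarray
    expiration_onsets: np.ndarray
    breath_ends: np.ndarray

    def __post_init__(self) -> None:
        insp, expi, ends = (
            np.asarray(self.inspiration_onsets, dtype=float),
            np.asarray(self.expiration_onsets, dtype=float),
            np.asarray(self.breath_ends, dtype=float),
        )
        object.__setattr__(self, "inspiration_onsets", insp)
        object.__setattr__(self, "expiration_onsets", expi)
        object.__setattr__(self, "breath_ends", ends)
        if not (len(insp) == len(expi) == len(ends)):
            raise ValueError("onset arrays must have equal length")
        if len(insp) and not np.all((insp < expi) & (expi < ends)):
            raise ValueError("onsets must interleave: insp < exp < end")

    @property
    def ti(self) -> np.ndarray:
        return self.expiration_onsets - self.inspiration_onsets

    @property
    def te(self) -> np.ndarray:
        return self.breath_ends - self.expiration_onsets

    @property
    def ibi(self) -> np.ndarray:
        return self.breath_ends - self.inspiration_onsets

    @property
    def rr(self) -> np.ndarray:
        return 60.0 / self.ibi

    def __len__(self) -> int:
        return len(self.inspiration_onsets)


# ---------------------------------------------------------------------------
# signal generators


def generate_ip(
    plan: BreathPlan, fs: float, duration: float
) -> tuple[ImpedanceTrace, GroundTruth]:
    """Sampled impedance trace plus the exact breath timings used to build it.

    The trace is baseline + slow sinusoidal drift + per-breath
    raised-cosine excursions (monotone rise over Ti, monotone fall over
    Te) + Gaussian noise; artifact events multiply the local signal by
    their scale.  Identical (plan, fs, duration) gives bit-identical
    output.
    """
    if fs <= 0:
        raise ValueError(f"sample rate must be positive, got {fs}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)

    insp, expi, ends = [], [], []
    onset = 0.0
    k = 0
    while True:
        ti, te, amp = plan.breaths[k % len(plan.breaths)]
        if onset + ti + te > duration + 1e-12:
            break
        insp.append(onset)
        expi.append(onset + ti)
        ends.append(onset + ti + te)
        i0 = int(np.ceil(onset * fs - 1e-9))
        i1 = int(np.ceil((onset + ti) * fs - 1e-9))
        i2 = int(np.ceil((onset + ti + te) * fs - 1e-9))
        i2 = min(i2, n)
        tt = t[i0:i1] - onset
        x[i0:i1] = amp * 0.5 * (1 - np.cos(np.pi * tt / ti))
        tt = t[i1:i2] - (onset + ti)
        x[i1:i2] = amp * 0.5 * (1 + np.cos(np.pi * tt / te))
        onset += ti + te
        k += 1

    truth = GroundTruth(np.array(insp), np.array(expi), np.array(ends))

    rng = np.random.default_rng(plan.seed)
    x += plan.baseline_ohm
    if plan.drift_amplitude_ohm:
        x += plan.drift_amplitude_ohm * np.sin(2 * np.pi * t / plan.drift_period_s)
    if plan.noise_sd_ohm:
        x += rng.normal(0.0, plan.noise_sd_ohm, size=n)
    for ev in plan.artifact_events:
        j0 = int(round(ev.onset_s * fs))
        j1 = int(round((ev.onset_s + ev.duration_s) * fs))
        x[max(j0, 0) : min(j1, n)] *= ev.scale

    trace = ImpedanceTrace(samples=x, sample_rate=fs, excitation_khz=150.0)
    return trace, truth


def _phase_envelope(
    n: int, fs: float, intervals: Sequence[tuple[float, float]],
    inside: float, outside: float, ramp_s: float,
) -> np.ndarray:
    """Step envelope smoothed by a raised-cosine (Hann) kernel."""
    env = np.full(n, outside)
    for t0, t1 in intervals:
        j0 = max(int(round(t0 * fs)), 0)
        j1 = min(int(round(t1 * fs)), n)
        env[j0:j1] = inside
    m = int(round(ramp_s * fs))
    if m >= 2:
        kern = np.hanning(m)
        kern /= kern.sum()
        env = np.convolve(env, kern, mode="same")
    return env


def _shaped_noise(rng: np.random.Generator, n: int, fs: float, spec: AcousticSpec) -> np.ndarray:
    """Gaussian noise spectrally shaped to the spec's band profile."""
    white = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    lo, hi = spec.base_noise_band
    if spec.band_powers is None:
        amp[(freqs >= lo) & (freqs <= hi)] = 1.0
    else:
        for (blo, bhi), p in zip(spec.band_partition, spec.band_powers):
            blo_eff, bhi_eff = max(blo, lo), min(bhi, hi)
            if bhi_eff <= blo_eff:
                continue
            sel = (freqs >= blo_eff) & (freqs < bhi_eff)
            amp[sel] = np.sqrt(max(p, 0.0) / (bhi - blo))
    shaped = np.fft.irfft(np.fft.rfft(white) * amp, n=n)
    rms = np.sqrt(np.mean(shaped**2))
    if rms > 0:
        shaped *= spec.noise_rms / rms
    else:
        shaped[:] = 0.0
    return shaped


def generate_lung_sound(
    truth: GroundTruth, spec: AcousticSpec, duration: float
) -> AudioTrace:
    """Phase-gated band-limited noise with optional wheeze tones.

    Inspiration intervals are amplified by ``inspiration_gain_db``
    (raised-cosine ramps at phase boundaries avoid clicks); each wheeze
    component adds a sinusoid during its phase at the specified SNR
    relative to the noise power of that phase.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    fs = spec.sample_rate
    n = int(round(duration * fs))
    rng = np.random.default_rng(spec.seed)

    noise = _shaped_noise(rng, n, fs, spec)
    insp_intervals = list(zip(truth.inspiration_onsets, truth.expiration_onsets))
    exp_intervals = list(zip(truth.expiration_onsets, truth.breath_ends))
    gain = 10.0 ** (spec.inspiration_gain_db / 20.0)
    env = _phase_envelope(n, fs, insp_intervals, gain, 1.0, spec.ramp_s)
    audio = noise * env

    t = np.arange(n) / fs
    for w in spec.wheeze_components:
        intervals = insp_intervals if w.phase == "inspiration" else exp_intervals
        level = gain if w.phase == "inspiration" else 1.0
        p_noise = (spec.noise_rms * level) ** 2
        if p_noise == 0:
            p_noise = 1.0  # reference power when noise is silent
        amp = np.sqrt(2.0 * 10.0 ** (w.snr_db / 10.0) * p_noise)
        tone = amp * np.sin(2 * np.pi * w.frequency_hz * t + rng.uniform(0, 2 * np.pi))
        mask = _phase_envelope(n, fs, intervals, 1.0, 0.0, spec.ramp_s)
        audio = audio + tone * mask

    return AudioTrace(samples=audio, sample_rate=fs, channel="anterior-right")


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class GroupSpec:
    """Feature targets for one cohort group at one time point."""

    time_point: str  # "T1", "T2" or "control"
    n: int
    rr_bpm: float
    ti_ibi: float = 0.45
    band_powers_insp: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    band_powers_exp: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    inspiration_gain_db: float = 4.0
    wheezes: tuple[WheezeComponent, ...] = ()
    rr_sd_bpm: float = 1.0  # between-participant spread
    ti_ibi_sd: float = 0.01
    breath_jitter_cv: float = 0.03  # within-recording Ti/Te jitter

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if self.rr_bpm <= 0:
            raise ValueError("RR target must be positive")
        if not 0 < self.ti_ibi < 1:
            raise ValueError("ti_ibi must be in (0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    duration_s: float = 90.0
    ip_fs_hz: float = 16.0
    audio_fs_hz: float = 4000.0
    breath_amplitude_ohm: float = 1.0
    baseline_ohm: float = 30.0
    ip_noise_sd_ohm: float = 0.01
    noise_rms: float = 0.05


@dataclass
class RawRecording:
    """One measurement session: bioimpedance channels, audio, labels."""

    recording_id: str
    participant_id: str
    group: str  # "patient" | "control"
    time_point: str  # "T1" | "T2" | "single"
    bioz: dict[str, ImpedanceTrace]
    audio: dict[str, AudioTrace]
    truth: GroundTruth | None = None


def _recording_for(
    spec: CohortSpec,
    grp: GroupSpec,
    rec_id: str,
    participant: str,
    rr: float,
    ti_ibi: float,
    seed: int,
) -> RawRecording:
    rng = np.random.default_rng(seed)
    ibi = 60.0 / rr
    n_breaths = int(np.ceil(spec.duration_s / ibi)) + 2
    tis = ti_ibi * ibi * (1 + grp.breath_jitter_cv * rng.standard_normal(n_breaths))
    tes = (1 - ti_ibi) * ibi * (1 + grp.breath_jitter_cv * rng.standard_normal(n_breaths))
    tis = np.clip(tis, 0.2, None)
    tes = np.clip(tes, 0.2, None)
    breaths = tuple(
        (float(a), float(b), spec.breath_amplitude_ohm) for a, b in zip(tis, tes)
    )
    plan = BreathPlan(
        breaths=breaths,
        baseline_ohm=spec.baseline_ohm,
        drift_amplitude_ohm=0.1 * spec.breath_amplitude_ohm,
        noise_sd_ohm=spec.ip_noise_sd_ohm,
        seed=seed,
    )
    trace, truth = generate_ip(plan, spec.ip_fs_hz, spec.duration_s)

    # secondary excitation channel: scaled copy + noise, no extra content
    aux = ImpedanceTrace(
        samples=0.8 * trace.samples
        + 0.02 * rng.standard_normal(len(trace.samples)),
        sample_rate=trace.sample_rate,
        excitation_khz=5.0,
    )

    # per-phase spectral tilt: shape inspiration and expiration noise
    # separately, then gate each to its own phase
    insp_spec = AcousticSpec(
        base_noise_band=(100.0, 1000.0),
        inspiration_gain_db=grp.inspiration_gain_db,
        sample_rate=spec.audio_fs_hz,
        noise_rms=spec.noise_rms,
        band_powers=grp.band_powers_insp,
        wheeze_components=tuple(w for w in grp.wheezes if w.phase == "inspiration"),
        seed=seed + 1,
    )
    exp_spec = replace(
        insp_spec,
        band_powers=grp.band_powers_exp,
        wheeze_components=tuple(w for w in grp.wheezes if w.phase == "expiration"),
        seed=seed + 2,
    )
    n = int(round(spec.duration_s * spec.audio_fs_hz))
    fs = spec.audio_fs_hz
    insp_iv = list(zip(truth.inspiration_onsets, truth.expiration_onsets))
    exp_iv = list(zip(truth.expiration_onsets, truth.breath_ends))
    gain = 10.0 ** (grp.inspiration_gain_db / 20.0)
    rng_i = np.random.default_rng(seed + 1)
    rng_e = np.random.default_rng(seed + 2)
    noise_i = _shaped_noise(rng_i, n, fs, insp_spec) * gain
    noise_e = _shaped_noise(rng_e, n, fs, exp_spec)
    mask_i = _phase_envelope(n, fs, insp_iv, 1.0, 0.0, insp_spec.ramp_s)
    mask_e = _phase_envelope(n, fs, exp_iv, 1.0, 0.0, insp_spec.ramp_s)
    samples = noise_i * mask_i + noise_e * mask_e
    t = np.arange(n) / fs
    for w in grp.wheezes:
        iv = insp_iv if w.phase == "inspiration" else exp_iv
        level = gain if w.phase == "inspiration" else 1.0
        p_noise = (spec.noise_rms * level) ** 2
        amp = np.sqrt(2.0 * 10.0 ** (w.snr_db / 10.0) * p_noise)
        tone = amp * np.sin(2 * np.pi * w.frequency_hz * t + rng_i.uniform(0, 2 * np.pi))
        samples += tone * _phase_envelope(n, fs, iv, 1.0, 0.0, insp_spec.ramp_s)
    audio = AudioTrace(samples=samples, sample_rate=fs, channel="anterior-right")

    return RawRecording(
        recording_id=rec_id,
        participant_id=participant,
        group="control" if grp.time_point == "control" else "patient",
        time_point="single" if grp.time_point == "control" else grp.time_point,
        bioz={"150khz": trace, "5khz": aux},
        audio={"anterior-right": audio},
        truth=truth,
    )


def generate_cohort(spec: CohortSpec, seed: int = 0) -> list[RawRecording]:
    """Labeled synthetic recordings whose downstream feature medians
    approximate the per-group targets.

    Patient groups (time points T1/T2) share participant identities so
    paired analyses are possible; controls get their own participants.
    Deterministic for identical (spec, seed).
    """
    rng = np.random.default_rng(seed)
    recordings: list[RawRecording] = []

    patient_groups = [g for g in spec.groups if g.time_point != "control"]
    control_groups = [g for g in spec.groups if g.time_point == "control"]
    n_patients = max((g.n for g in patient_groups), default=0)

    # per-participant physiology offsets are drawn once and shared by
    # the participant's time points, then shifted by the group targets
    pat_rr_z = rng.standard_normal(n_patients)
    pat_ti_z = rng.standard_normal(n_patients)

    for grp in patient_groups:
        for i in range(grp.n):
            participant = f"P{i + 1:02d}"
            rr = max(grp.rr_bpm + grp.rr_sd_bpm * pat_rr_z[i], 5.0)
            ti_ibi = float(np.clip(grp.ti_ibi + grp.ti_ibi_sd * pat_ti_z[i], 0.2, 0.8))
            rec_id = f"{participant}_{grp.time_point}"
            rec_seed = int(rng.integers(0, 2**31 - 1))
            recordings.append(
                _recording_for(spec, grp, rec_id, participant, rr, ti_ibi, rec_seed)
            )
    for grp in control_groups:
        for i in range(grp.n):
            participant = f"C{i + 1:02d}"
            rr = max(grp.rr_bpm + grp.rr_sd_bpm * rng.standard_normal(), 5.0)
            ti_ibi = float(
                np.clip(grp.ti_ibi + grp.ti_ibi_sd * rng.standard_normal(), 0.2, 0.8)
            )
            rec_id = f"{participant}_single"
            rec_seed = int(rng.integers(0, 2**31 - 1))
            recordings.append(
                _recording_for(spec, grp, rec_id, participant, rr, ti_ibi, rec_seed)
            )
    return recordings


def table4_cohort_spec(
    n_t1: int = 10, n_t2: int = 9, n_control: int = 9, duration_s: float = 90.0
) -> CohortSpec:
    """Cohort spec whose group targets follow the reported T1/T2/control
    medians: fast shallow breathing with low-band-dominant sounds for
    T1, intermediate T2, slower breathing with a flatter spectrum for
    controls."""
    groups = (
        GroupSpec(
            time_point="T1", n=n_t1, rr_bpm=35.0, ti_ibi=0.48,
            band_powers_insp=(0.820, 0.100, 0.062, 0.021),
            band_powers_exp=(0.806, 0.112, 0.063, 0.024),
        ),
        GroupSpec(
            time_point="T2", n=n_t2, rr_bpm=32.3, ti_ibi=0.47,
            band_powers_insp=(0.757, 0.123, 0.075, 0.034),
            band_powers_exp=(0.768, 0.124, 0.077, 0.028),
        ),
        GroupSpec(
            time_point="control", n=n_control, rr_bpm=22.4, ti_ibi=0.41,
            band_powers_insp=(0.678, 0.155, 0.121, 0.045),
            band_powers_exp=(0.695, 0.155, 0.116, 0.044),
        ),
    )
    return CohortSpec(groups=groups, duration_s=duration_s)
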