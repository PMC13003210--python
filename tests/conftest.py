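"""Shared fixtures and synthetic-input helpers."""

from __future__ import annotations

import numpy as np
import pytest

from respimodal.synth import AcousticSpec, BreathPlan, generate_ip, generate_lung_sound


def jittered_plan(
    rr_bpm: float,
    duration: float,
    ti_ibi: float = 0.45,
    jitter_cv: float = 0.02,
    amplitude: float = 1.0,
    noise_sd: float = 0.005,
    seed: int = 0,
    **kw,
) -> BreathPlan:
    """Breath plan around an RR target with mild physiological jitter
    (keeps window MADs nonzero so clean breaths are never degenerate)."""
    rng = np.random.default_rng(seed)
    ibi = 60.0 / rr_bpm
    n = int(np.ceil(duration / ibi)) + 2
    tis = ti_ibi * ibi * (1 + jitter_cv * rng.standard_normal(n))
    tes = (1 - ti_ibi) * ibi * (1 + jitter_cv * rng.standard_normal(n))
    breaths = tuple(
        (float(max(a, 0.2)), float(max(b, 0.2)), amplitude) for a, b in zip(tis, tes)
    )
    return BreathPlan(breaths=breaths, noise_sd_ohm=noise_sd, seed=seed, **kw)


@pytest.fixture(scope="session")
def clean_ip_recording():
    """120-s clean IP recording at ~20 bpm with ground truth."""
    plan = jittered_plan(rr_bpm=20.0, duration=120.0, seed=42)
    trace, truth = generate_ip(plan, fs=16.0, duration=120.0)
    return trace, truth


@pytest.fixture(scope="session")
def clean_multimodal_recording():
    """120-s clean IP + audio recording pair with ground truth."""
    plan = jittered_plan(rr_bpm=20.0, duration=120.0, seed=42)
    trace, truth = generate_ip(plan, fs=16.0, duration=120.0)
    spec = AcousticSpec(inspiration_gain_db=6.0, seed=43)
    audio = generate_lung_sound(truth, spec, duration=120.0)
    return trace, audio, truth
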