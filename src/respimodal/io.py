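"""Readers and writers: bioimpedance CSV, 16-bit PCM WAV audio,
ground-truth tables and cohort manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from respimodal.ip import ImpedanceTrace
from respimodal.ls import AudioTrace

MANIFEST_VERSION = 1


def write_bioz_csv(path: str | Path, trace: ImpedanceTrace) -> None:
    df = pd.DataFrame({"time_s": trace.times, "value_ohm": trace.samples})
    df.to_csv(path, index=False)


def read_bioz_csv(path: str | Path, excitation_khz: float = 150.0) -> ImpedanceTrace:
    df = pd.read_csv(path)
    if not {"time_s", "value_ohm"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s,value_ohm")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    fs = 1.0 / np.median(np.diff(t))
    return ImpedanceTrace(
        samples=df["value_ohm"].to_numpy(dtype=float),
        sample_rate=float(fs),
        excitation_khz=excitation_khz,
    )


def write_wav(path: str | Path, audio: AudioTrace) -> None:
    """16-bit PCM WAV; samples are scaled to 90% full scale."""
    x = np.asarray(audio.samples, dtype=float)
    peak = np.max(np.abs(x)) if len(x) else 0.0
    scaled = x * (0.9 / peak) if peak > 0 else x
    wavfile.write(path, int(round(audio.sample_rate)), (scaled * 32767).astype(np.int16))


def read_wav(path: str | Path, channel: str = "anterior-right") -> AudioTrace:
    fs, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data.astype(float) / 32767.0
    else:
        samples = data.astype(float)
    return AudioTrace(samples=samples, sample_rate=float(fs), channel=channel)


def write_ground_truth(path: str | Path, truth) -> None:
    pd.DataFrame(
        {
            "inspiration_onset_s": truth.inspiration_onsets,
            "expiration_onset_s": truth.expiration_onsets,
            "breath_end_s": truth.breath_ends,
            "Ti": truth.ti,
            "Te": truth.te,
            "RR": truth.rr,
        }
    ).to_csv(path, index=False)


def read_ground_truth(path: str | Path):
    from respimodal.synth import GroundTruth

    df = pd.read_csv(path)
    return GroundTruth(
        df["inspiration_onset_s"].to_numpy(),
        df["expiration_onset_s"].to_numpy(),
        df["breath_end_s"].to_numpy(),
    )


def write_manifest(path: str | Path, recordings: list[dict]) -> None:
    payload = {"version": MANIFEST_VERSION, "recordings": recordings}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_manifest(path: str | Path) -> list[dict]:
    payload = json.loads(Path(path).read_text())
    if payload.get("version") != MANIFEST_VERSION:
        raise ValueError(f"{path}: unsupported manifest version")
    return payload["recordings"]
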