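"""End-to-end orchestration of the multimodal pipeline for one
recording and for whole cohorts."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from respimodal.config import PipelineConfig
from respimodal.fusion import run_fusion
from respimodal.ip import BreathSegmentation, ImpedanceTrace, run_ip_pipeline
from respimodal.ls import AudioTrace, match_multimodal_breaths, run_ls_pipeline
from respimodal.stats import aggregate_cohort, run_cohort_stats

logger = logging.getLogger(__name__)


@dataclass
class RecordingResult:
    """All per-recording pipeline outputs."""

    segmentation: BreathSegmentation
    timing: pd.DataFrame
    acoustics: pd.DataFrame
    multimodal: pd.DataFrame
    series: pd.DataFrame
    retention: dict[str, float] = field(default_factory=dict)


def process_recording(
    bioz: ImpedanceTrace,
    audio: AudioTrace,
    config: PipelineConfig | None = None,
    recording_id: str = "recording",
) -> RecordingResult:
    """Run the IP branch, LS branch, multimodal matching and windowed
    fusion on one recording; logs retention at each filter stage."""
    config = (config or PipelineConfig()).validate()
    timing, seg = run_ip_pipeline(bioz, config.ip, scaled_mad=config.scaled_mad)
    # propagate timing outlier flags onto the segmentation so the LS
    # branch only sees surviving breaths
    seg_flagged = BreathSegmentation(
        seg.inspiration_onsets,
        seg.expiration_onsets,
        seg.breath_ends,
        quality_ok=seg.quality_ok,
    )
    if len(timing):
        bad = set(timing.loc[timing["outlier"], "breath_id"])
        seg_flagged.outlier[[int(b) in bad for b in seg_flagged.breath_ids]] = True
    acoustics = run_ls_pipeline(audio, seg_flagged, config.ls, scaled_mad=config.scaled_mad)
    multimodal = match_multimodal_breaths(timing, acoustics)
    series = run_fusion(
        multimodal, duration=bioz.duration, config=config.fusion,
        scaled_mad=config.scaled_mad,
    )
    n_det = len(seg)
    retention = {
        "detected": float(n_det),
        "quality_ok": float(seg.quality_ok.sum()) / n_det if n_det else 0.0,
        "after_timing_outliers": float((~timing["outlier"]).sum()) / n_det
        if n_det
        else 0.0,
        "multimodal": float(len(multimodal)) / n_det if n_det else 0.0,
    }
    logger.info(
        "[%s] retention: detected=%d quality=%.1f%% timing=%.1f%% multimodal=%.1f%%",
        recording_id,
        n_det,
        100 * retention["quality_ok"],
        100 * retention["after_timing_outliers"],
        100 * retention["multimodal"],
    )
    return RecordingResult(
        segmentation=seg_flagged,
        timing=timing,
        acoustics=acoustics,
        multimodal=multimodal,
        series=series,
        retention=retention,
    )


def process_cohort(
    recordings: list,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, RecordingResult]]:
    """Process synthetic RawRecording objects and aggregate the cohort.

    Returns the aggregated cohort table plus per-recording results.
    """
    config = config or PipelineConfig()
    results: dict[str, RecordingResult] = {}
    agg_inputs = []
    for rec in recordings:
        res = process_recording(
            rec.bioz["150khz"],
            next(iter(rec.audio.values())),
            config,
            recording_id=rec.recording_id,
        )
        results[rec.recording_id] = res
        agg_inputs.append(
            {
                "participant_id": rec.participant_id,
                "group": rec.group,
                "time_point": rec.time_point,
                "series": res.series,
            }
        )
    table = aggregate_cohort(agg_inputs)
    return table, results


def analyze_cohort(table: pd.DataFrame, config: PipelineConfig | None = None):
    """Cohort statistics + PCA on an aggregated cohort table."""
    config = config or PipelineConfig()
    return run_cohort_stats(table, config.stats)
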