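# respimodal

Multimodal respiratory feature extraction from wearable impedance
pneumography (IP) and lung-sound (LS) recordings, with a synthetic-data
generator, cohort-level nonparametric statistics and PCA.

The pipeline mirrors a two-branch design:

- **IP branch** (`respimodal.ip`): FIR antialiasing resampling to
  100 Hz, median-based amplitude artifact removal with linear
  interpolation, zero-phase Kaiser FIR bandpass (0.1–1 Hz nominal,
  configurable up to 1.4 Hz), windowed breath detection (32-s windows,
  0.67-s minimum inter-peak distance, i.e. RR < 89.55 bpm), a
  template-correlation signal quality index (CoV ≤ 0.3, correlation
  > 0.7, coverage ≥ 60%), per-breath timing features (RR, Ti, Te,
  Te:Ti, Ti/IBI) and a 5-MAD / 30-breath sliding outlier filter.
- **LS branch** (`respimodal.ls`): resampling to 4 kHz, zero-phase
  100–1000 Hz FIR bandpass, IP-driven inspiration/expiration
  segmentation, per-phase subband spectral integrated intensities
  (64-ms Hamming windows, 75% overlap; bands 100–300, 300–500,
  500–800, 800–1000 Hz), a 4-MAD acoustic outlier filter on
  unnormalized intensities, and multimodal matching into a 13-feature
  per-breath table.
- **Fusion** (`respimodal.fusion`): 32-s / 75%-overlap windowed feature
  time series with 5-MAD window-level outlier interpolation.
- **Statistics** (`respimodal.stats`): per-time-point aggregation,
  paired Wilcoxon signed-rank tests, rank-sum tests vs control with
  Benjamini–Hochberg correction across the two comparisons, and 2-D
  PCA on z-scored features with PC1 loading ranking.
- **Synthetic recordings** (`respimodal.synth`): ground-truthed
  quasi-periodic IP traces (raised-cosine breaths, drift, noise,
  multiplicative artifacts), phase-gated band-shaped lung-sound noise
  with optional wheeze tones, and whole labeled cohorts whose feature
  distributions approximate configurable group targets.

## CLI

```bash
# generate a synthetic cohort (WAV + CSV + ground truth + manifest)
respimodal simulate --out data/ --seed 1 [--cohort cohort.yaml]

# run the full pipeline on every recording in the manifest
respimodal process data/manifest.json [--config config.yaml]

# cohort statistics and PCA from the processed feature files
respimodal analyze data/manifest.json --out data/analysis

# or everything at once
respimodal all --out data/ --seed 1
```

Exit codes: 0 success, 1 configuration error, 2 partial batch failure.
All tunables (filter edges, SQI thresholds, MAD parameters, PSD bands)
live in `respimodal.config.PipelineConfig` and can be supplied as
YAML/JSON via `--config`.

## Python API sketch

```python
from respimodal.synth import BreathPlan, AcousticSpec, generate_ip, generate_lung_sound
from respimodal.pipeline import process_recording

plan = BreathPlan.constant(ti=1.0, te=1.6, amplitude=1.0, noise_sd_ohm=0.01)
trace, truth = generate_ip(plan, fs=16.0, duration=300.0)
audio = generate_lung_sound(truth, AcousticSpec(inspiration_gain_db=6.0), 300.0)
result = process_recording(trace, audio)
result.multimodal   # per-breath 13-feature table
result.series       # 32-s windowed feature time series
```
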