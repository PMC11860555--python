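# wearanx

Anxiety-state detection from multimodal wearable physiology — a tested,
fully synthetic re-implementation of a feature-based detection pipeline for
researchers in digital mental health and wearable signal processing.

Consumer and research wearables (a chest garment recording ECG, respiration
and acceleration; a wrist device recording blood volume pulse, electrodermal
activity, skin temperature and acceleration) can in principle flag acute
anxiety episodes outside the laboratory. Doing that requires a pipeline that
survives motion artifact and environmental noise: robust beat detection,
noise-aware feature extraction, class rebalancing, and honest evaluation of
how models trained under controlled conditions transfer to uncontrolled
ones. `wearanx` implements that pipeline end to end on synthetic cohorts
with known ground truth, so every stage is testable without any proprietary
study data.

## What is inside

- **`wearanx.simulate`** — generates multimodal recordings (ECG 256 Hz,
  RESP 128 Hz, chest ACC 64 Hz, BVP 64 Hz, EDA 4 Hz, TEMP 4 Hz, wrist ACC
  32 Hz) in which an anxious state shifts heart rate, heart-rate
  variability, respiration rate, skin-conductance response rate and skin
  temperature by configurable deltas. Three cohort subsets mirror
  increasingly uncontrolled conditions: `calibration` (seated),
  `in_lab` (seated/standing/walking) and `in_the_wild` (variable activity,
  extra noise, ~19.3% anxious time).
- **`wearanx.preprocess`** — zero-phase Butterworth low-pass filtering
  (5 Hz for EDA, 13 Hz for ACC), Hampel outlier removal, min–max
  normalization, anti-aliased downsampling, mean imputation with segment
  dropping, and Gaussian noise injection calibrated to a linear
  signal-to-noise ratio: `noise_var = var(x) / SNR`.
- **`wearanx.peaks`** — automatic multiscale-based peak detection (AMPD).
  For scales `k = 1..⌈n/2⌉−1` a scalogram entry is 0 where
  `x[i] > x[i±k]` and `α + U(0,1)` otherwise; the scale `λ` minimizing the
  row sum selects the dominant peak scale, and peaks are columns that are
  maxima at every scale up to `λ`. Long records run in 6-s windows with 50%
  overlap and a 0.25-s refractory merge; `qrs_select` then applies
  amplitude-based artifact rejection before RR statistics.
- **`wearanx.features`** — 60 s / 30 s sliding windows over 21 features in
  six modalities (`ECG_bpm`…`ACC_x_C_std`), labeled by the condition
  interval covering the window midpoint.
- **`wearanx.dataset`** — STAI Y6 dichotomization at a cutoff of 11
  (range 6–24), subset assembly, and majority-class undersampling that
  keeps `round(n_min·(1−p)/p)` majority rows for a target minority
  fraction `p`.
- **`wearanx.models`** — seven classifier families (DT, RF, LDA, KNN, AB,
  SVM, gradient-boosted trees) behind a sklearn-style
  `AnxietyClassifier`, evaluated by stratified 5-fold cross-validation
  with an inner 80/20 train/validation split and 5 seeded iterations.
  Per-model feature importances are aggregated by the weighted rule
  `w_f = Σ_m i_{f,m}² / Σ_f Σ_m i_{f,m}²`, then rolled up per modality.
- **`wearanx.transfer`** — train on a (optionally noise-augmented) source
  cohort, evaluate on target subsets with **no fine-tuning**, sweeping the
  injected noise over linear SNRs in [0.0001, 0.6].

## Worked example

```python
import numpy as np
from wearanx import CohortConfig, ModelSpec, generate_cohort
from wearanx.features import cohort_to_table
from wearanx.models import crossval_evaluate

cfg = CohortConfig(n_subjects=4, subset="calibration",
                   session_duration_s=600, label_noise=0.0, seed=1)
table = cohort_to_table(generate_cohort(cfg))
print(table.groupby("label")[["ECG_bpm", "Resp_rate", "TEMP_mean"]].mean().round(2))

res = crossval_evaluate(table, ModelSpec(family="RF", seed=0), iters=2,
                        compute_importance=False)
print(f"RF: accuracy={res.mean_accuracy:.2f} f1={res.mean_f1:.2f}")
```

prints

```
       ECG_bpm  Resp_rate  TEMP_mean
label
0        74.95      13.32      32.83
1        85.68      16.97      32.43
RF: accuracy=1.00 f1=1.00
```

The non-anxious rows recover the cohort's baseline physiology (mean heart
rate ≈ 75 bpm, ≈ 13 breaths/min); anxious windows show the configured
shifts (+12 bpm, +4 breaths/min, −0.5 °C), and with zero label noise the
classes are cleanly separable, so cross-validated accuracy sits at the
ceiling. Raising `label_noise` produces the sub-ceiling accuracies typical
of real questionnaire-derived labels.

A command-line interface wraps the same pipeline:
`wearanx simulate|features|train|transfer --help`.

## Acceptance benchmark

`scripts/acceptance.py` regenerates the headline beat-detection benchmark
from scratch: 20 five-minute synthetic ECG records (heart rates 60–100 bpm,
RR standard deviation 0.05 s, 0.2 Hz baseline wander, Gaussian noise at
linear SNR 10), windowed AMPD detection, and greedy one-to-one matching of
detected against ground-truth beats within ±50 ms:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The JSON output reports the mean matched-beats percentage and the number of
records used. All randomness derives from `--seed`.
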