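# Methods

This note documents the models, numerical choices and limitations behind
`wearanx`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The synthetic world

Real multimodal anxiety studies are not publicly depositable, so the package
ships a generator whose *ground truth is the point*: every downstream claim
(beat-detection accuracy, feature recovery, classifier sanity, transfer
behavior) is validated against quantities the generator knows exactly.

**Subject model.** A `SubjectProfile` holds baseline physiology: heart rate
(beats/min), RR-interval standard deviation `sdnn` (s), respiration rate
(breaths/min), inhale/exhale duration ratio, tonic skin conductance (µS),
skin-conductance response (SCR) rate (per min), and wrist skin temperature
(°C). Cohorts draw profiles from population-typical distributions
(HR ~ N(70, 7), sdnn ~ N(0.05, 0.01), resp ~ N(14, 2), …, all clipped to
physiological ranges).

**Anxious state.** Acute anxiety is modelled as additive shifts
(`AnxietyDeltas`): +12 beats/min, −0.015 s sdnn, +4 breaths/min,
+4 SCR/min, −0.5 °C (peripheral vasoconstriction lowers wrist skin
temperature). No public effect sizes exist for the target population; these
are plausible placeholder magnitudes exposed in configuration, not
empirical claims. Every test that depends on them tests *recovery of the
configured value*, not the value itself.

**Channels.**

- *ECG*: RR intervals drawn i.i.d. from a normal distribution (mean
  `60/hr`, sd `sdnn`) truncated to [0.3, 2.0] s by rejection sampling; the
  beat train is phase-shifted by half an interval so no apex falls exactly
  on the record boundary. Each beat renders as a Gaussian bump (σ = 10 ms,
  ≈ 40 ms support, amplitude 1), plus a 0.2 Hz sinusoidal baseline wander
  (amplitude 0.05) and white measurement noise (σ = 0.01 by default).
  Morphological realism (P/T waves, 12-lead geometry) is deliberately out
  of scope — only peak structure matters downstream.
- *BVP* shares the ECG's RR sequence for the same seed (identical draw
  order) and renders a systolic plus smaller dicrotic bump per beat, so its
  dominant spectral frequency equals the heart rate in Hz.
- *EDA*: tonic level + slow sinusoidal drift + a Poisson SCR train
  (bi-exponential kernel, rise 0.5 s, decay 4 s, peak 0.3 µS), clipped at
  zero.
- *RESP* is a lung-volume-like waveform: each breath rises trough→peak over
  the inhale (cycle fraction `ie/(1+ie)`) and falls back over the exhale as
  half-cosine segments; cycle durations jitter with CV 0.05.
- *ACC* is a constant gravity vector (z on the chest, tilted x on the
  wrist) plus an activity component: seated ≈ white noise σ 0.01 g;
  standing adds slow sway; walking adds a 2 Hz step oscillation (0.3 g)
  with a first harmonic; `variable` alternates regimes on exponential dwell
  times (mean 30 s).
- *TEMP*: base level + Gaussian random-walk drift + white noise.

Sampling rates follow the two-device convention: chest ECG 256 Hz, RESP
128 Hz, ACC 64 Hz; wrist BVP 64 Hz, EDA 4 Hz, TEMP 4 Hz, ACC 32 Hz (wrist
rates follow public device documentation since the study hardware reports
"varying" rates; they are echoed in recording metadata and overridable).

**Sessions and labels.** A session is a contiguous plan of condition
intervals. Calibration alternates relaxation (290 s) with cold-pressor
blocks (210 s), a 58/42 duty cycle matching the reported calibration class
balance; the in-lab plan cycles relaxation with three induction tasks
(standing social-stress, seated and walking Stroop; ≈ 41% anxious time);
in-the-wild sessions use random 200–400 s intervals whose anxious subset is
chosen greedily to hit the target anxious-time fraction (default 19.34%)
per session, so the cohort-level fraction concentrates tightly around the
target. Each interval receives a STAI Y6 score consistent with its
ground-truth state (anxious ⇒ ≥ 11, else < 11), *except* with a label-noise
probability (default 0.05) where the score crosses the cutoff — this is
what keeps classification below ceiling, emulating questionnaire
unreliability. Labels are recomputed downstream from the scores, never
copied from the truth bit.

**What the generator does not emulate.** Motion-artifact structure that is
correlated with physiology, sensor detachment, EDA saturation in humid
environments, circadian temperature cycles, and between-task waveform
morphology changes. A green test therefore establishes that the *pipeline
arithmetic* is correct and robust to stationary Gaussian noise at the
stated SNRs, not that the models would reach the same accuracy on real
wearable data.

## 2. Preprocessing

Filters are order-4 Butterworth applied forward–backward (`sosfiltfilt`),
so phase is zero and the net magnitude response is the squared single-pass
response `1/(1+(f/fc)^{2·4})`. EDA uses fc = 5 Hz, accelerometry 13 Hz;
with a 4 Hz EDA channel the 5 Hz cutoff exceeds Nyquist and the filter is
skipped (the band is already limited by sampling). The filter order is a
common biosignal default; only the two cutoffs are externally specified.

The Hampel rule (centered rolling median, window ≈ 1 s, 4 scaled MADs)
marks outliers as missing; when the local MAD is zero only exact duplicates
of the median pass. Missing points are replaced by the segment's observed
mean when the missing fraction is ≤ 0.2 (configurable; the source procedure
says only "a significant portion"), else the segment is flagged dropped.
Mean imputation preserves the observed-sample mean exactly.

Noise injection interprets SNR as a **linear power ratio**
(`σ² = var(x)/SNR`): the stated grid 0.0001–0.6 is dimensionless and below
1, which is meaningless in dB (0.0001 dB would be a no-op). `SNR = ∞` is
the exact zero-noise limit.

## 3. Beat detection

AMPD is implemented exactly as defined (scalogram over all scales
`1..⌈n/2⌉−1`, uniform-random fill `α + U(0,1)` with α = 1, `λ = argmin`
of row sums, peaks = columns that are maxima at all scales ≤ λ), with
three documented engineering choices:

1. **Seeded fill.** The random fill only affects the choice of λ; seeding
   it makes the detector reproducible and lets a brute-force transcription
   of the definition serve as an exact oracle (shared seed).
2. **Tie guard.** Strict-maximum comparisons use a tolerance of
   `1e-9 · range(x)`; otherwise linear-detrend floating-point residue
   (~1e-16) fabricates maxima on monotone or constant segments.
3. **Windowing.** The scalogram is O(n²) in memory, so long records run in
   6-s windows with 50% overlap; pooled peaks are deduplicated and merged
   under a 0.25 s refractory period (240 bpm physiological ceiling),
   keeping the higher-amplitude member of a conflicting pair.

Detection **accuracy** is defined as matched/true under greedy one-to-one
matching within ±50 ms, since the source of the 98% headline does not
define its metric; sensitivity and positive predictive value are reported
alongside. On noisy records AMPD's all-scales-≤-λ criterion admits
low-amplitude inter-beat maxima (λ settles at small scales), so PPV falls
well below accuracy while matched/true stays ≈ 1. For RR-interval work,
`qrs_select` removes those: peak amplitudes are measured above a 0.6-s
rolling-median baseline and peaks below 0.4 × the 90th-percentile amplitude
are discarded — standard artifact rejection ahead of time-domain HRV
statistics (on synthetic records at SNR 10 it restores PPV ≈ 1 without
losing true beats).

## 4. Features

Windows default to 60 s with a 30 s shift (the source never states a window
size; both are configurable). Each emitted row carries all 21 features or
is dropped and counted. Choices where the source's feature list prints no
definitions:

- `ECG_min/max/std` are statistics of the **instantaneous heart-rate
  series** (60/RR within the window), not raw ECG voltage: they co-occur
  with `ECG_bpm` and follow time-domain HRV convention. Population (not
  sample) standard deviations are used throughout.
- Respiration: cycles are delimited by rising zero-crossings of the
  smoothed, mean-removed signal; within each cycle the peak marks
  end-of-inhale and the following trough end-of-exhale, so
  `Resp_IE = mean(inhale)/mean(exhale)`. Crossings come from the smoothed
  signal (1.5 Hz, order 2, zero-phase) but peak/trough positions are
  refined on the raw signal: smoothing a flat-bottomed trough whose flanks
  have unequal curvature biases its argmin, which at ie = 0.5 shifts the
  measured ratio by ~12% — refinement brings recovery within ~2%.
- `BVP_peak_freq` is the periodogram argmax over the plausible pulse band
  0.5–3.5 Hz; windows shorter than 10 s are dropped (frequency resolution).
- `ACC_net w` is read as the wrist-device net acceleration and `ACC_x C` as
  the chest x-axis (w = wrist, C = chest), matching the two-device setup.
- Window labels come from the condition interval covering the window
  **midpoint** — unambiguous for straddling windows.

## 5. Labels, balancing, models

STAI Y6 scores (6–24) dichotomize at 11 with the boundary labeled anxious
(≥ 11, consistent with the score being "indicative" of anxiety); a
`strict` flag flips the boundary. Undersampling keeps
`round(n_min(1−p)/p)` uniformly sampled majority rows (seeded, optionally
subject-stratified) and never touches minority rows; the in-the-wild table
is assembled at its raw imbalance plus 30% and 41% rebalanced variants.
Balancing operates on the windowed feature table (whether the source
balanced before or after windowing is unstated).

The seven families map to scikit-learn estimators (`DecisionTree`,
`RandomForest(100)`, `LDA`, scaled `KNeighbors`, `AdaBoost`, scaled
rbf-`SVC`, `GradientBoostingClassifier` for the gradient-boosted family —
the xgboost library is not a dependency). Hyperparameters are not specified
by the source; each family carries a fixed seeded default plus a minimal
grid (tree depth, k, SVM C) selected on the inner 80/20 validation split.
Cross-validation is stratified 5-fold at the row level (subject-grouped
folds would change results materially on real data; rows here are windows
and the flag-controlled `group_col` machinery in `undersample` covers the
subject-aware variant). F1 is binary with the anxious class positive.

**Importance.** Impurity importances (tree families), `|coef| · std(X)`
(LDA, linear SVM), permutation importance with 20 seeded shuffles (KNN,
kernel SVM; negative values clipped at zero). Each model's vector is
normalized to sum to 1 before aggregation. The weighted aggregate squares
each feature's importance within a model, sums across models, and divides
by the total of those sums — the denominator choice makes the weights a
proper distribution (the alternative raw-total denominator sits behind
`squared_denominator=False`). The claim that evenly-distributed importance
aids transfer is *not* asserted as a test; the package instead reports the
Shannon entropy of each model's weights next to its transfer scores.

## 6. Transfer protocol

`train_source` fits on the full source table; `evaluate_transfer` aligns
target columns by name and only predicts — target rows can never reach a
fit routine, and a mutation sentinel test asserts it. The SNR sweep injects
noise into raw source recordings and re-extracts features (augmentation
upstream of learning); a feature-space noise mode exists for ablation. The
default grid {0.0001, 0.001, 0.01, 0.1, 0.3, 0.6} spans the stated
endpoints with log-ish spacing (the interior points are not externally
specified). The real source dataset is replaced by a synthetic in-lab-style
cohort with its own seed stream, so source/target shift is a generator
knob; orderings among model families reported for real data are therefore
not asserted on synthetic analogs — only self-consistency properties are.

## 7. Numerical and runtime notes

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; cohorts are bit-for-bit reproducible under a fixed config.
- Filter validation measures steady-state amplitude by quadrature
  demodulation on the interior of the record (forward–backward filtering
  has edge transients), and compares in dB against the analog closed form;
  the bilinear-transform response deviates from the analog prototype near
  Nyquist, which the 10%-in-dB tolerance absorbs.
- Acceptance-scale simulations are sized for a single CPU: the suite uses
  2 CV iterations where the protocol default is 5, and transfer
  self-consistency uses 3-subject, 500-s cohorts over 10 seeds.
- The undersampling no-op case (already at target) returns the table
  unchanged rather than erroring; targets *below* the current minority
  fraction raise.

## 8. Known limitations

- Gaussian channel noise is stationary and uncorrelated across channels;
  real motion artifact is neither.
- The RR model is an i.i.d. truncated normal — no autonomic
  autocorrelation, respiratory sinus arrhythmia, or ectopy; `sdnn` is the
  only HRV knob, which is exactly what the extracted time-domain features
  measure.
- STAI label noise is symmetric and state-independent.
- AMPD's scale selection degrades gracefully but not monotonically per
  record at extreme noise; only median-over-seeds monotonicity is asserted.
- With 4 Hz EDA the stated 5 Hz low-pass is unusable; results for EDA rest
  on the raw channel plus window statistics.
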