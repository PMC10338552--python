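# Methods

## Perfusion-curve model

A single ROI's noiseless time–fluorescence curve is piecewise:

* **Inflow** (gamma-variate bolus transit), for onset ≤ t ≤ peak:
  `F(t) = P · (τ/τ_p)^α · exp(α(1 − τ/τ_p))` with τ = t − onset, shape
  α = 2, peaking at `F = P` when τ = τ_p. This is the standard empirical
  shape for contrast-agent first-pass curves; it rises from zero at dye
  arrival and is continuous (value `P`) at the peak.
* **Washout**, for t beyond the peak:
  `F(t) = P · (plateau + (1 − plateau) · exp(−k·Δt))`, Δt = time since peak.
  `plateau ∈ [0, 1]` is the non-washing residual and models ICG retention in
  malignant tissue; `k ≥ 0` is the washout rate. `k = 0` gives a flat tail.

The quantity reported clinically is the **normalized downslope**
`ds_N = (f(N) − 1)/N` where `f` is the tail normalized to the peak. The
generator is therefore parameterized by `ds_10` (and plateau), converting to
`k` analytically; class presets anchor `ds_10` at −0.0065 (healthy), −0.004
(benign) and −0.001 s⁻¹ (cancer) with a 20% coefficient of variation across
ROIs. Inflow presets (onset 5/6/8 s, time-to-peak 20/25/30 s, peak 180/150/
120 greyscale units for healthy/benign/cancer, ±20%) encode the slower,
dimmer enhancement of malignant tissue; time-to-peak is deliberately
class-informative because it ranks as the most important classification
feature in clinical practice.

### Artifacts

Applied in a fixed order: kinetics → double bolus → movement noise/spike →
clip to the greyscale ceiling (255 by default).

* **Saturation**: peak amplitudes above the 8-bit ceiling (over-dosing)
  produce clipped plateaus; QC flags runs of samples ≥ 254 lasting ≥ 2 s.
  The "> 255" detector reading is unreachable on an 8-bit scale, so "at the
  ceiling" is the operational definition. Saturated traces are excluded
  from classification by default (their curve shape is destroyed).
* **Double bolus**: a second additive pulse delayed ~10–14 s. The first
  pulse clears at first-pass speed (default 0.2 s⁻¹) and the second rises
  with a steeper gamma exponent (α = 4); without these two choices the
  pulses merge into a single hump (the slow tissue-washout tail leaves no
  valley between peaks, ~0.3% dip) and no detector could resolve them.
  Twin peaks closer than the rise time (≲9 s at these kinetics) merge
  physically and are not reliably detectable — the QC detection-rate checks
  use ≥10-s separations, matching the observed twin-peak morphology
  (~15 s and ~25 s).
* **Movement**: white Gaussian noise plus a low-frequency sinusoid
  (0.2–0.5 Hz), both with amplitude 2% of the trace's peak by default, and
  an optional transient Gaussian "camera lurch" spike.
* **Truncation**: per-trace duration control. The default cohort plan makes
  exactly 11, 72 and 106 of 251 ROIs end before peak+200/300/400 s (with
  ±15 s guard margins around the horizon boundaries so peak-detection
  jitter on near-flat curves cannot move a trace across a horizon
  boundary), emulating interrupted recordings.

### Default cohort

37 patients (13 benign, 24 cancer lesions), 251 ROIs total (79 healthy
controls spread over all patients, 52 benign, 120 cancer), 5 Hz sampling.
The video sampling cadence of clinical trackers varies; 5 Hz is exposed in
config. Identical config + seed ⇒ bit-identical cohorts (a single
`numpy.random.Generator` consumed in fixed order).

### Frame rendering

`render_frame_stack` paints traces into non-overlapping boxes over a noisy
background, pixels ~ Normal(trace value, pixel noise), clipped to [0, 255].
It exists to test extraction round-trips, not to look like NIR video.

## Conditioning

Smoothing **precedes** normalization so a noise spike cannot set the
normalization divisor. Savitzky–Golay defaults: 11-s window (odd sample
count at the trace's rate), cubic polynomial — wide enough to suppress
0.2–0.5 Hz movement oscillation while preserving peaks tens of seconds
wide. QC peak *detection* uses a lighter 5-s window because an 11-s window
begins to merge twin peaks ~10 s apart. Normalization divides by the curve
maximum and records the divisor; it is idempotent and makes every milestone
invariant to pre-normalization intensity scaling — the testable core of the
distance–intensity mitigation.

## Milestones

* First peak: earliest local maximum with prominence ≥ 0.15 × global max
  (so a double-bolus curve reports its *first* peak); fallback to the
  earliest global argmax for prominence-free (plateau-topped) curves; a
  trace whose maximum is its last sample raises "peak not reached".
* T½max: first upward crossing of half the peak value on the rise, linearly
  interpolated. Time ratio := T½max / Tmax, both from recording start.
* Upslope: least-squares slope of the normalized curve between the first
  0.1 crossing and the peak (robust to onset noise). "Time ratio" and
  "upslope" lack a single canonical definition in the field; these choices
  are documented here and isolated in one function each.
* Downslopes: linear interpolation at t_peak + N; horizons beyond the
  recording are **missing**, never extrapolated (extrapolation is the
  imputation module's job). Kurtosis: Fisher excess kurtosis of the full
  normalized series (raw-vs-normalized choice is immaterial up to the
  normalization constant only for centred moments; normalized is used).

On noiseless traces whose analytic peak lies on the sample grid, every
milestone matches its closed form to machine precision (times limited only
by the sampling interval). Off-grid peaks add an O(k·Δt) slope error
(~1e-5 s⁻¹ at 5 Hz) from anchoring the downslope at the nearest sample; the
oracle test sets therefore snap onset + time-to-peak to the grid.

## Imputation

* **Training tables (KNN)**: features standardized to zero mean/unit
  variance; masked Euclidean distances on jointly observed coordinates
  (scikit-learn's `nan_euclidean_distances`); each missing cell becomes the
  mean of its column over the k = 5 nearest rows observing it; a donor log
  records provenance. Verified cell-for-cell against
  `sklearn.impute.KNNImputer` on standardized inputs.
* **Single test curves (exponential fit)**: bounded least squares of
  `a·e^{−b·Δt} + c` to the observed post-peak samples (≥5 required), two
  deterministic starts (log-linear pure-decay reading; offset reading
  anchored at the tail floor). The offset `c` (retention plateau) is only
  fitted when identifiable: the pure-decay reading must show at least one
  e-folding inside the observed window (`b·span ≥ 1`), and the offset model
  must then win on AIC. On shorter windows the three-parameter model
  degenerates to "small fast transient + constant" and extrapolates flat,
  which is badly wrong; the two-parameter decay extrapolates the local
  slope and is kept instead. Consequence: extrapolation error grows with
  the ratio of horizon to observed window — from ~0.02% median (50-s window
  → 200-s horizon, noiseless exact) through ~4–9% (movement noise, full
  windows) to ~30% median for the slowest-washout class when only 10 s of
  tail is observed, where the true decay is comparable to residual noise.

Test-time imputation uses only the trace's own samples — a deliberate API
separation, because a single prospective video has no cohort neighbours.

## Classification

Fivefold stratified cross-validation (80:20 per fold, no holdout), ROI-level
by default to mirror how such cohorts are usually analysed; patient-grouped
folds (`grouping="patient_level"`) are offered because ROI-level splitting
lets ROIs of one patient straddle folds. Within each fold: KNN imputation
is fitted on training rows only; test rows are completed from their own
exponential-fit values (computed per trace, no neighbours, hence no
leakage); standardization lives inside each candidate pipeline and is fitted
on training folds only. Candidates — bagged KNN (k ∈ {3,5,7}, 10 bags,
80% subsampling), logistic regression (C ∈ {0.1, 1}), random forest (100
trees) — are compared by inner 3-fold CV AUC; an exhaustive classifier/
hyper-parameter search is deliberately replaced by this fixed, documented
slate for reproducibility. Two-way AUC is standard binary AUC-ROC with
"cancer" positive; three-way is macro-averaged one-vs-rest (a multiclass
AUC needs a convention; OvR-macro is the most common).

Experiment drivers: `incremental_feature_experiment` adds downslope
horizons cumulatively (50 → 400 s) to the base features (time to first
peak, time ratio, 10-s downslope, upslope, kurtosis), in complete-rows-only
and imputed modes; `truncation_inference_simulation` discards every
downslope beyond a kept post-peak window (default 10 s), re-imputes from an
exponential fit to the kept tail (the truncated recording renormalized by
its own peak reading), and re-runs the classification against the full-data
arm.

## What the synthetic cohort does and does not show

The generator reproduces the *structure* the analysis relies on — bolus
kinetics with class-dependent washout, the reported normalized tail slopes,
acquisition artifacts, interrupted durations — but not tissue heterogeneity
within lesions, ROI-tracking drift, inter-patient pharmacokinetic
correlation, or detector nonlinearity. Under the default presets the
classes are strongly separated (cross-validated AUC ≈ 1.0, comfortably in
the >0.9 regime reported for clinical cohorts), so passing tests demonstrate
correctness of the pipeline and robustness of the imputation strategy, not
expected clinical effect sizes. The washout-gap dial test (classes
identical except washout) shows AUC rising monotonically with the class
gap, which is the behaviour a perfusion-based classifier must have.

## Numerical choices and degenerate inputs

* Sampling 5 Hz; smoothing window forced odd in samples; traces shorter
  than the window are a hard error suggesting a smaller window.
* Saturation ceiling 254 gs, minimum run 2 s; peak prominence 0.15 of max.
* All-zero traces cannot be normalized (error); monotone-rising traces have
  no peak (error); equal-height peaks: earliest wins.
* Curve-fit bounds a ∈ [0,2], b ∈ [0,1] s⁻¹, c ∈ [−0.5, 1.5]; tolerances
  1e-15 so noiseless fits reach machine precision.
* KNN imputation requires k < number of complete rows and at least one
  observed value per column.
* Seeds: every stochastic component takes a seed or `numpy` Generator;
  cohort generation, fold splitting and ensemble classifiers are all
  reproducible bit-for-bit under a fixed seed.

## Problem sizes

Tests and the acceptance script run the full 251-ROI cohort for
classification experiments, 100–200 traces for oracle sweeps, and 40–90-ROI
cohorts for properties that need several seeds × settings; these sizes give
stable statistics while keeping the whole suite fast on a single CPU.
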