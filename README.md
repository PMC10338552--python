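# icgflow

Quantitative analysis of indocyanine-green (ICG) fluorescence angiography
for dynamic tissue characterisation.

After an intravenous ICG bolus, a near-infrared (NIR) camera renders tissue
fluorescence as an 8-bit greyscale video. Tracking a user-drawn box region of
interest (a "digital biopsy") over time yields a time–fluorescence curve
F(t) whose inflow/washout kinetics reflect tissue perfusion: healthy tissue
clears the dye quickly, malignant tissue retains it. `icgflow` implements
the full analysis chain needed to turn such curves into a tissue classifier:

1. **Trace extraction & I/O** — mean pixel intensity per ROI per frame from
   greyscale frame stacks (multi-page TIFF or PNG directories); traces as
   `time_s,intensity_gs` CSV.
2. **QC** — detection of detector-ceiling saturation plateaus (over-dosing)
   and twin inflow peaks from split ("double bolus") administration.
3. **Conditioning** — Savitzky–Golay smoothing (movement oscillation), then
   peak normalization `F/max F`, which cancels the camera-distance intensity
   confound.
4. **Milestone features** — time to first peak T<sub>max</sub>, time to half
   max T<sub>½max</sub>, time ratio T<sub>½max</sub>/T<sub>max</sub>, rise
   slope, Fisher kurtosis, and normalized downslopes
   `ds_N = (F(t_peak+N) − F(t_peak))/N` for N ∈ {10, 50, 100, 200, 300, 400} s.
5. **Imputation of interrupted series** — K-nearest-neighbour imputation
   inside training tables; for single test curves (which have no neighbours)
   extrapolation from an exponential tail fit `a·e^{−b·Δt} + c`.
6. **Classification** — fivefold cross-validated two-way (cancer vs
   not-cancer) and three-way (cancer / benign / healthy) AUC-ROC with a fixed
   candidate slate (bagged-KNN ensemble, logistic regression, random
   forest) tuned by inner CV; per-fold imputation with no train/test leakage.

Because clinical videos cannot be redistributed, the package ships a
first-class **synthetic cohort generator**: gamma-variate inflow to a peak,
class-dependent exponential washout anchored to clinically reported
normalized tail slopes (healthy ≈ −0.0065 s⁻¹, benign ≈ −0.004 s⁻¹, cancer ≈
−0.001 s⁻¹), movement noise, saturation and double-bolus artifacts, and
controlled per-trace truncation. Every analysis stage is validated against
the generator's closed-form ground truth.

## Worked example

```python
import icgflow as icg

# 251 ROIs over 37 patients; durations arranged so 11/72/106 ROIs end
# before peak+200/300/400 s (interrupted recordings)
traces, truth = icg.generate_cohort(icg.default_cohort_config(seed=1))
res = icg.prepare_cohort(traces)          # QC -> smooth -> normalize -> features
print("missing downslopes:", res.missingness)
print(res.features.groupby("class")[["ttfp_s", "ds10", "ds200"]].mean().round(4))

spec = icg.ExperimentSpec(split_mode="two_way",
                          added_horizons=(50, 100, 200, 300, 400), seed=1)
report = icg.run_cv(res.features, spec, test_imputation=res.exp_imputed)
print("per-fold AUC:", [round(a, 3) for a in report.per_fold_auc])
print("mean AUC-ROC:", round(report.mean_auc, 3), "| classifier:", report.classifier_chosen)
```

prints

```
missing downslopes: {10: 0, 50: 0, 100: 0, 200: 11, 300: 72, 400: 106}
          ttfp_s    ds10   ds200
class
benign   31.9077 -0.0040 -0.0026
cancer   40.0283 -0.0014 -0.0009
healthy  25.3443 -0.0064 -0.0036
per-fold AUC: [1.0, 1.0, 1.0, 1.0, 1.0]
mean AUC-ROC: 1.0 | classifier: bagged_knn_k3
```

The class-mean 10-s downslopes recover the generator's clinically anchored
values; cancer washes out an order of magnitude slower than healthy tissue
(dye retention), and the cross-validated classifier separates the classes
essentially perfectly under these cohort conditions. Truncating every trace
to 10 s after its peak and re-imputing the longer downslopes
(`icg.truncation_inference_simulation`) reproduces the classification with
minimal AUC loss — the case for imputation when recordings are interrupted.

A command-line interface mirrors the library:

```bash
icgflow simulate --out cohort/ --seed 1
icgflow qc --traces cohort/ --out qc.csv
icgflow features --traces cohort/ --out features.csv
icgflow classify --traces cohort/ --split two_way --seed 1
icgflow experiment truncation --traces cohort/ --keep 10
```

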