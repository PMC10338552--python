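"""Cross-validated classification: sanity, determinism, leakage, experiments."""
import numpy as np
import pandas as pd
import pytest
from joblib import hash as jhash

import icgflow as icg
from icgflow.classify import StratificationError, eval_fold, fit_fold

from conftest import light_candidates, separable_cohort_config

HORIZONS = (50, 100, 200, 300, 400)


def spec_for(seed=0, **kw):
    kw.setdefault("split_mode", "two_way")
    kw.setdefault("added_horizons", HORIZONS)
    return icg.ExperimentSpec(seed=seed, **kw)


class TestRunCv:
    def test_separable_cohort_perfect_auc(self, separable_features):
        rep = icg.run_cv(separable_features.features, spec_for(seed=0))
        assert rep.mean_auc == pytest.approx(1.0, abs=0.01)
        assert len(rep.per_fold_auc) == 5
        assert rep.mean_auc == pytest.approx(np.mean(rep.per_fold_auc))

    def test_three_way_macro_auc(self, separable_features):
        rep = icg.run_cv(separable_features.features, spec_for(seed=0, split_mode="three_way"))
        assert 0.9 <= rep.mean_auc <= 1.0

    def test_permuted_labels_chance_level(self, separable_features):
        rng = np.random.default_rng(0)
        aucs = []
        for r in range(5):
            perm = separable_features.features.copy()
            perm["class"] = rng.permutation(perm["class"].to_numpy())
            rep = icg.run_cv(perm, spec_for(seed=r), candidates=light_candidates())
            aucs.append(rep.mean_auc)
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_deterministic_under_seed(self, separable_features):
        a = icg.run_cv(separable_features.features, spec_for(seed=5))
        b = icg.run_cv(separable_features.features, spec_for(seed=5))
        assert a.per_fold_auc == b.per_fold_auc
        assert a.per_fold_classifier == b.per_fold_classifier

    def test_auc_in_unit_interval(self, default_features):
        rep = icg.run_cv(
            default_features.features,
            spec_for(seed=2),
            test_imputation=default_features.exp_imputed,
        )
        assert all(0.0 <= a <= 1.0 for a in rep.per_fold_auc)

    def test_single_class_rejected(self, separable_features):
        df = separable_features.features
        only = df[df["class"] == "cancer"]
        with pytest.raises(StratificationError):
            icg.run_cv(only, spec_for(seed=0))

    def test_complete_only_equals_imputed_when_nothing_missing(self, separable_features):
        df = separable_features.features
        assert not df[[f"ds{h}" for h in HORIZONS]].isna().any().any()
        a = icg.run_cv(df, spec_for(seed=1, imputation_mode="complete_only"),
                       candidates=light_candidates())
        b = icg.run_cv(df, spec_for(seed=1, imputation_mode="imputed"),
                       candidates=light_candidates())
        assert a.per_fold_auc == b.per_fold_auc

    def test_patient_level_grouping_runs(self, separable_features):
        rep = icg.run_cv(
            separable_features.features,
            spec_for(seed=0, grouping="patient_level"),
            candidates=light_candidates(),
        )
        assert 0.0 <= rep.mean_auc <= 1.0


class TestNoLeakage:
    def test_fold_state_invariant_to_test_rows(self, default_features):
        df = default_features.features.sample(frac=1, random_state=0).reset_index(drop=True)
        spec = spec_for(seed=3)
        train = df.iloc[:200]
        cols = list(spec.feature_columns)
        state = fit_fold(train, spec, inner_seed=3)
        probe = state.completed_train[cols].head(20).to_numpy(dtype=float)
        digest = (jhash(state.completed_train), jhash(state.model.predict_proba(probe)))
        # evaluating different test sets must not change the fitted behaviour
        test_full = df.iloc[200:]
        test_minus_one = df.iloc[201:]
        eval_fold(state, test_full, spec, default_features.exp_imputed)
        eval_fold(state, test_minus_one, spec, default_features.exp_imputed)
        assert (jhash(state.completed_train), jhash(state.model.predict_proba(probe))) == digest
        # refitting on the same training rows reproduces it bit-for-bit
        state2 = fit_fold(train, spec, inner_seed=3)
        assert (jhash(state2.completed_train), jhash(state2.model.predict_proba(probe))) == digest

    def test_train_imputation_ignores_test_rows(self, default_features):
        df = default_features.features.sample(frac=1, random_state=0).reset_index(drop=True)
        spec = spec_for(seed=3)
        state_a = fit_fold(df.iloc[:200], spec, inner_seed=3)
        # dropping rows outside the training fold changes nothing
        state_b = fit_fold(pd.concat([df.iloc[:200]]), spec, inner_seed=3)
        assert jhash(state_a.completed_train) == jhash(state_b.completed_train)


class TestIncrementalExperiment:
    def test_table_layout(self, separable_features):
        out = icg.incremental_feature_experiment(
            separable_features.features,
            split_mode="two_way",
            seed=0,
            candidates=light_candidates(),
        )
        assert len(out) == 5 * 2  # horizons x imputation modes
        assert set(out["horizon_added_s"]) == set(HORIZONS)
        assert set(out["imputation_mode"]) == {"complete_only", "imputed"}

    def test_imputed_mode_counts_missing_cells(self, default_features):
        out = icg.incremental_feature_experiment(
            default_features.features,
            split_mode="two_way",
            horizons=(400,),
            imputation_modes=("imputed",),
            seed=0,
            test_imputation=default_features.exp_imputed,
            candidates=light_candidates(),
        )
        assert int(out.loc[0, "n_imputed_cells"]) >= 106

    def test_complete_only_drops_short_traces(self, default_features):
        out = icg.incremental_feature_experiment(
            default_features.features,
            split_mode="two_way",
            horizons=(400,),
            imputation_modes=("complete_only",),
            seed=0,
            candidates=light_candidates(),
        )
        assert int(out.loc[0, "n_rois"]) == 251 - 106


class TestTruncationSimulation:
    def test_noop_when_keep_exceeds_horizons(self, separable_features):
        cmp = icg.truncation_inference_simulation(
            separable_features.features,
            separable_features.normalized,
            separable_features.milestones,
            keep_post_peak_s=500.0,
            seed=0,
            candidates=light_candidates(),
        )
        assert cmp.full.per_fold_auc == cmp.truncated.per_fold_auc

    def test_plateau_cohort_truncation_equivalence(self):
        # zero-washout curves: observed and imputed downslopes are both ~0,
        # so the truncated arm reproduces the full arm
        rng = np.random.default_rng(0)
        traces = []
        for i in range(40):
            cls = "healthy" if i % 2 == 0 else "cancer"
            ttp = rng.uniform(12, 18) if cls == "healthy" else rng.uniform(28, 36)
            p = icg.KineticParams(rng.uniform(4, 8), ttp, rng.uniform(100, 200), 0.0, 1.0)
            traces.append(
                icg.generate_trace(
                    p, icg.ArtifactConfig(), 5.0, p.peak_time_s + 420.0, seed=i,
                    trace_id=f"t{i}", patient_id=f"P{i % 8}", class_label=cls,
                )
            )
        res = icg.prepare_cohort(traces)
        ds_cols = [f"ds{h}" for h in (10,) + HORIZONS]
        # smoothing the rise->flat corner leaves |ds| up to ~5e-4 residual slope
        assert np.allclose(res.features[ds_cols].to_numpy(dtype=float), 0.0, atol=1e-3)
        cmp = icg.truncation_inference_simulation(
            res.features, res.normalized, res.milestones,
            keep_post_peak_s=10.0, seed=0, candidates=light_candidates(),
        )
        trunc_ds = cmp.truncated_table[ds_cols].to_numpy(dtype=float)
        assert np.allclose(trunc_ds, res.features[ds_cols].to_numpy(dtype=float), atol=2e-3)
        assert abs(cmp.full.mean_auc - cmp.truncated.mean_auc) <= 0.05


class TestSeparabilityDial:
    @staticmethod
    def _gap_config(seed, gap):
        base = -0.006
        kin = {}
        for cls, sign in (("healthy", +1), ("cancer", -1)):
            s = base * (1 + sign * gap)
            kin[cls] = icg.KineticDistribution(
                onset_time_s=(6.0, 1.0),
                time_to_peak_s=(24.0, 5.0),
                peak_intensity_gs=(150.0, 30.0),
                downslope10_per_s=(s, 0.3 * abs(base)),
                plateau_fraction=(0.1, 0.02),
            )
        kin["benign"] = kin["healthy"]
        return icg.SyntheticCohortConfig(
            n_patients=10,
            n_benign_patients=1,
            class_counts={"healthy": 30, "cancer": 30},
            class_kinetics=kin,
            movement_noise_frac=0.03,
            durations=icg.DurationSpec(missing_counts={}, complete_post_peak_s=(225.0, 255.0)),
            seed=seed,
        )

    def test_wider_washout_gap_raises_auc(self):
        """Classes identical except washout: separability tracks the gap."""
        means = []
        for gap in (0.1, 0.3, 0.6):
            aucs = []
            for seed in range(5):
                traces, _ = icg.generate_cohort(self._gap_config(seed, gap))
                res = icg.prepare_cohort(traces)
                rep = icg.run_cv(
                    res.features,
                    icg.ExperimentSpec(
                        split_mode="two_way", added_horizons=(50, 100, 200), seed=seed
                    ),
                    test_imputation=res.exp_imputed,
                    candidates=light_candidates(),
                )
                aucs.append(rep.mean_auc)
            means.append(float(np.mean(aucs)))
        assert means[0] <= means[1] + 0.02
        assert means[1] <= means[2] + 0.02
        assert means[2] > means[0]
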