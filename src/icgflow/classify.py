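"""Cross-validated tissue classification from curve-milestone features.

Two-way (cancer vs not-cancer) and three-way (cancer vs benign vs healthy)
classification with fivefold cross-validation (80:20 per fold, no holdout).
Within each fold, KNN imputation is fitted on the training rows only, and
test rows are completed from per-trace exponential-tail fits (which use only
the trace's own data), so no information crosses the fold boundary.

Candidate classifiers are a fixed, documented set — a bagged K-nearest-
neighbours ensemble, logistic regression and a random forest — tuned by
inner 3-fold cross-validation on the training fold and selected by AUC-ROC.
Three-way AUC is macro-averaged one-vs-rest.

Also implements two experiment drivers: the incremental-downslope feature
experiment (base features plus downslopes added at growing horizons, with
and without imputation) and the truncation-and-impute inference simulation
(all downslope records beyond a short post-peak window discarded and
re-imputed from exponential fits before re-running the classification).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .features import IMPUTED, MilestoneFeatures
from .imputation import ImputationError, exp_impute_test, knn_impute_train
from .preprocess import NormalizedTrace

ALL_HORIZONS_S = (10, 50, 100, 200, 300, 400)
BASE_FEATURES = ("ttfp_s", "time_ratio", "ds10", "upslope", "kurtosis")


class StratificationError(ValueError):
    """A CV fold lost a class; AUC is undefined."""


@dataclass(frozen=True)
class ExperimentSpec:
    """One classification run: class split, feature set, imputation policy."""

    split_mode: str = "two_way"  # two_way | three_way
    base_features: tuple[str, ...] = BASE_FEATURES
    added_horizons: tuple[int, ...] = ()
    imputation_mode: str = "imputed"  # imputed | complete_only
    n_folds: int = 5
    grouping: str = "roi_level"  # roi_level | patient_level
    knn_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.split_mode not in ("two_way", "three_way"):
            raise ValueError(f"unknown split_mode {self.split_mode!r}")
        if self.imputation_mode not in ("imputed", "complete_only"):
            raise ValueError(f"unknown imputation_mode {self.imputation_mode!r}")
        if self.grouping not in ("roi_level", "patient_level"):
            raise ValueError(f"unknown grouping {self.grouping!r}")

    @property
    def feature_columns(self) -> tuple[str, ...]:
        return self.base_features + tuple(f"ds{h}" for h in self.added_horizons)


@dataclass(frozen=True)
class ClassificationReport:
    spec: ExperimentSpec
    per_fold_auc: tuple[float, ...]
    mean_auc: float
    classifier_chosen: str
    per_fold_classifier: tuple[str, ...]
    n_rois: int
    n_imputed_cells: int

    def to_dict(self) -> dict:
        return {
            "split_mode": self.spec.split_mode,
            "features": list(self.spec.feature_columns),
            "imputation_mode": self.spec.imputation_mode,
            "per_fold_auc": list(self.per_fold_auc),
            "mean_auc": self.mean_auc,
            "classifier_chosen": self.classifier_chosen,
            "n_rois": self.n_rois,
            "n_imputed_cells": self.n_imputed_cells,
        }


def default_candidates(seed: int = 0) -> list[tuple[str, Pipeline]]:
    """The fixed classifier slate; every candidate standardizes its inputs
    inside the pipeline so scaling is fitted on training folds only."""

    def mk(est) -> Pipeline:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])

    cands: list[tuple[str, Pipeline]] = []
    for k in (3, 5, 7):
        cands.append(
            (
                f"bagged_knn_k{k}",
                mk(
                    BaggingClassifier(
                        KNeighborsClassifier(n_neighbors=k),
                        n_estimators=10,
                        max_samples=0.8,
                        random_state=seed,
                    )
                ),
            )
        )
    for c in (0.1, 1.0):
        cands.append((f"logreg_C{c}", mk(LogisticRegression(C=c, max_iter=2000))))
    cands.append(
        ("random_forest", mk(RandomForestClassifier(n_estimators=100, random_state=seed)))
    )
    return cands


def _labels(df: pd.DataFrame, split_mode: str) -> np.ndarray:
    cls = df["class"].astype(str).to_numpy()
    if split_mode == "two_way":
        return (cls == "cancer").astype(int)
    return cls


def _auc(y_true: np.ndarray, proba: np.ndarray, classes: np.ndarray) -> float:
    if len(classes) == 2:
        pos = int(np.argmax(classes == 1)) if 1 in classes else 1
        return float(roc_auc_score(y_true, proba[:, pos]))
    return float(
        roc_auc_score(y_true, proba, multi_class="ovr", average="macro", labels=classes)
    )


@dataclass(frozen=True)
class FoldState:
    """Everything fitted from one training fold (and nothing else)."""

    train_ids: tuple[str, ...]
    completed_train: pd.DataFrame
    model: Pipeline
    classifier_name: str
    n_imputed_cells: int


def fit_fold(
    train_df: pd.DataFrame,
    spec: ExperimentSpec,
    candidates: Sequence[tuple[str, Pipeline]] | None = None,
    inner_seed: int = 0,
) -> FoldState:
    """Impute (training rows only), select a classifier by inner CV, fit it."""
    cols = list(spec.feature_columns)
    work = train_df[["trace_id", "class"] + cols].reset_index(drop=True)
    n_imp = 0
    if spec.imputation_mode == "imputed" and work[cols].isna().any().any():
        completed, log = knn_impute_train(work, k=spec.knn_k, value_cols=None)
        n_imp = len(log)
        work = completed
    if work[cols].isna().any().any():
        raise ImputationError("training fold still has missing cells")
    X = work[cols].to_numpy(dtype=float)
    y = _labels(work, spec.split_mode)
    if len(np.unique(y)) < 2:
        raise StratificationError("training fold contains a single class")
    if candidates is None:
        candidates = default_candidates(seed=spec.seed)
    inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=inner_seed)
    best_name, best_est, best_score = None, None, -np.inf
    for name, est in candidates:
        scores = []
        for tr, te in inner.split(X, y):
            m = clone(est).fit(X[tr], y[tr])
            scores.append(_auc(y[te], m.predict_proba(X[te]), m.classes_))
        score = float(np.mean(scores))
        if score > best_score + 1e-12:
            best_name, best_est, best_score = name, est, score
    model = clone(best_est).fit(X, y)
    return FoldState(
        train_ids=tuple(work["trace_id"].astype(str)),
        completed_train=work,
        model=model,
        classifier_name=best_name,
        n_imputed_cells=n_imp,
    )


def eval_fold(
    state: FoldState,
    test_df: pd.DataFrame,
    spec: ExperimentSpec,
    test_imputation: pd.DataFrame | None = None,
) -> tuple[float, int]:
    """Score one held-out fold; missing test cells come from the per-trace
    exponential-fit table (each trace's own tail, no neighbours)."""
    cols = list(spec.feature_columns)
    work = test_df[["trace_id", "class"] + cols].reset_index(drop=True)
    n_imp = 0
    if work[cols].isna().any().any():
        if test_imputation is None:
            raise ImputationError(
                "test fold has missing cells but no exponential-fit imputation table"
            )
        for i in range(len(work)):
            tid = str(work.at[i, "trace_id"])
            for c in cols:
                if pd.isna(work.at[i, c]):
                    if tid not in test_imputation.index or pd.isna(test_imputation.at[tid, c]):
                        raise ImputationError(f"no imputed value for {tid}/{c}")
                    work.at[i, c] = float(test_imputation.at[tid, c])
                    n_imp += 1
    y = _labels(work, spec.split_mode)
    if len(np.unique(y)) < 2:
        raise StratificationError("test fold contains a single class")
    proba = state.model.predict_proba(work[cols].to_numpy(dtype=float))
    return _auc(y, proba, state.model.classes_), n_imp


def run_cv(
    feature_table: pd.DataFrame,
    spec: ExperimentSpec,
    test_imputation: pd.DataFrame | None = None,
    candidates: Sequence[tuple[str, Pipeline]] | None = None,
) -> ClassificationReport:
    """Fivefold stratified cross-validation of one experiment spec.

    ``complete_only`` drops rows missing any selected feature before
    splitting; ``imputed`` keeps all rows and imputes within folds.
    Deterministic for a fixed table, spec and candidate set.
    """
    cols = list(spec.feature_columns)
    missing_cols = [c for c in cols if c not in feature_table.columns]
    if missing_cols:
        raise ValueError(f"feature table lacks columns {missing_cols}")
    df = feature_table.reset_index(drop=True)
    if spec.imputation_mode == "complete_only":
        df = df.dropna(subset=cols).reset_index(drop=True)
    y = _labels(df, spec.split_mode)
    if len(np.unique(y)) < 2:
        raise StratificationError("need at least two classes")
    if spec.grouping == "patient_level":
        splitter = StratifiedGroupKFold(
            n_splits=spec.n_folds, shuffle=True, random_state=spec.seed
        )
        splits = splitter.split(df, y, groups=df["patient_id"])
    else:
        splitter = StratifiedKFold(
            n_splits=spec.n_folds, shuffle=True, random_state=spec.seed
        )
        splits = splitter.split(df, y)

    fold_aucs: list[float] = []
    fold_names: list[str] = []
    n_imputed = 0
    for fold_i, (tr_idx, te_idx) in enumerate(splits):
        state = fit_fold(
            df.iloc[tr_idx], spec, candidates=candidates, inner_seed=spec.seed + 17 + fold_i
        )
        auc, n_imp_test = eval_fold(state, df.iloc[te_idx], spec, test_imputation)
        fold_aucs.append(auc)
        fold_names.append(state.classifier_name)
        n_imputed += state.n_imputed_cells + n_imp_test
    chosen = max(set(fold_names), key=lambda nm: (fold_names.count(nm), -fold_names.index(nm)))
    return ClassificationReport(
        spec=spec,
        per_fold_auc=tuple(fold_aucs),
        mean_auc=float(np.mean(fold_aucs)),
        classifier_chosen=chosen,
        per_fold_classifier=tuple(fold_names),
        n_rois=len(df),
        n_imputed_cells=n_imputed,
    )


def incremental_feature_experiment(
    feature_table: pd.DataFrame,
    split_mode: str = "two_way",
    horizons: Sequence[int] = (50, 100, 200, 300, 400),
    imputation_modes: Sequence[str] = ("complete_only", "imputed"),
    seed: int = 0,
    test_imputation: pd.DataFrame | None = None,
    base_features: tuple[str, ...] = BASE_FEATURES,
    candidates: Sequence[tuple[str, Pipeline]] | None = None,
) -> pd.DataFrame:
    """Downslope horizons added cumulatively to the base feature set; one
    classification per (horizon, imputation mode).  Returns a tidy table with
    one row per run (pivot on ``imputation_mode`` to get the two-column
    complete/imputed layout)."""
    rows = []
    for h in horizons:
        added = tuple(x for x in horizons if x <= h)
        for mode in imputation_modes:
            spec = ExperimentSpec(
                split_mode=split_mode,
                base_features=base_features,
                added_horizons=added,
                imputation_mode=mode,
                seed=seed,
            )
            rep = run_cv(feature_table, spec, test_imputation=test_imputation,
                         candidates=candidates)
            rows.append(
                {
                    "split_mode": split_mode,
                    "horizon_added_s": h,
                    "imputation_mode": mode,
                    "mean_auc": rep.mean_auc,
                    "per_fold_auc": list(rep.per_fold_auc),
                    "classifier_chosen": rep.classifier_chosen,
                    "n_rois": rep.n_rois,
                    "n_imputed_cells": rep.n_imputed_cells,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TruncationComparison:
    full: ClassificationReport
    truncated: ClassificationReport
    truncated_table: pd.DataFrame


def truncation_inference_simulation(
    feature_table: pd.DataFrame,
    normalized: Mapping[str, NormalizedTrace],
    milestones: Mapping[str, MilestoneFeatures],
    keep_post_peak_s: float = 10.0,
    split_mode: str = "two_way",
    seed: int = 0,
    horizons: Sequence[int] = (50, 100, 200, 300, 400),
    test_imputation: pd.DataFrame | None = None,
    candidates: Sequence[tuple[str, Pipeline]] | None = None,
) -> TruncationComparison:
    """Discard every downslope beyond ``keep_post_peak_s`` after the peak and
    re-impute it from an exponential fit to the kept tail, then re-run the
    classification; returns the full-data and truncated+imputed reports."""
    spec = ExperimentSpec(
        split_mode=split_mode,
        added_horizons=tuple(horizons),
        imputation_mode="imputed",
        seed=seed,
    )
    full_report = run_cv(feature_table, spec, test_imputation=test_imputation,
                         candidates=candidates)

    trunc = feature_table.copy().reset_index(drop=True)
    beyond = [h for h in ALL_HORIZONS_S if h > keep_post_peak_s]
    for i in range(len(trunc)):
        tid = str(trunc.at[i, "trace_id"])
        if not beyond:
            continue
        ms = milestones[tid]
        nt = normalized[tid]
        t_peak_abs = nt.time_s[0] + ms.time_to_first_peak_s
        i_peak = int(np.argmin(np.abs(nt.time_s - t_peak_abs)))
        mask = nt.time_s <= t_peak_abs + keep_post_peak_s + 1e-9
        kept = nt.intensity[mask]
        # a truncated recording is normalized by its own peak reading
        nt_short = NormalizedTrace(
            trace_id=nt.trace_id,
            time_s=nt.time_s[mask],
            intensity=kept / kept.max(),
            normalization_peak_gs=nt.normalization_peak_gs * float(kept.max()),
            patient_id=nt.patient_id,
            class_label=nt.class_label,
        )
        # mark everything beyond the kept window missing, then refill
        ms_gap = dc_replace(
            ms,
            downslopes={h: (np.nan if h in beyond else v) for h, v in ms.downslopes.items()},
            provenance={h: ("missing" if h in beyond else p) for h, p in ms.provenance.items()},
        )
        ms_filled, _fit = exp_impute_test(nt_short, ms_gap, i_peak=i_peak)  # fills all missing
        fill_horizons = [h for h, p in ms_filled.provenance.items() if p == IMPUTED]
        for h in fill_horizons:
            col = f"ds{h}"
            if col in trunc.columns:
                trunc.at[i, col] = ms_filled.downslopes[h]
                prov_col = f"{col}_provenance"
                if prov_col in trunc.columns:
                    trunc.at[i, prov_col] = IMPUTED
    truncated_report = run_cv(
        trunc,
        spec,
        test_imputation=None if beyond else test_imputation,
        candidates=candidates,
    )
    return TruncationComparison(
        full=full_report, truncated=truncated_report, truncated_table=trunc
    )
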