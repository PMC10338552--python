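"""End-to-end conditioning: raw cohort -> QC -> smoothed, normalized traces
-> milestone feature table -> exponential-fit imputation candidates.

Pipeline order is deliberate: traces are smoothed on the raw greyscale scale
first (so a noise spike cannot set the normalization divisor), then peak
normalized, then milestoned.  Saturated traces are flagged by QC and dropped
from the feature table by default — a ceiling plateau destroys curve shape —
but can be kept with ``drop_saturated=False``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .features import (
    DEFAULT_HORIZONS_S,
    MISSING,
    MilestoneFeatures,
    build_feature_table,
    extract_milestones,
)
from .imputation import InsufficientTailError, exp_impute_test
from .preprocess import NormalizedTrace, normalize, qc_report, smooth
from .trace import FluorescenceTrace


@dataclass(frozen=True)
class CohortFeatures:
    features: pd.DataFrame
    missingness: dict[int, int]
    qc: pd.DataFrame
    normalized: dict[str, NormalizedTrace]
    milestones: dict[str, MilestoneFeatures]
    exp_imputed: pd.DataFrame  # per-trace exponential-fit values for missing cells


def exp_imputation_candidates(
    normalized: Mapping[str, NormalizedTrace],
    milestones: Mapping[str, MilestoneFeatures],
) -> pd.DataFrame:
    """Per-trace test-time imputation table: every missing downslope filled
    from that trace's own exponential tail fit (no neighbours involved).
    Indexed by trace_id; cells for observed horizons stay NaN."""
    rows = {}
    for tid, ms in milestones.items():
        gaps = [h for h, p in ms.provenance.items() if p == MISSING]
        if not gaps:
            continue
        filled, _fit = exp_impute_test(normalized[tid], ms, horizons_to_fill=gaps)
        rows[tid] = {f"ds{h}": filled.downslopes[h] for h in gaps}
    cols = [f"ds{h}" for h in DEFAULT_HORIZONS_S]
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df.reindex(columns=cols)


def prepare_cohort(
    traces: Iterable[FluorescenceTrace],
    smooth_window_s: float = 11.0,
    polyorder: int = 3,
    drop_saturated: bool = True,
    ceiling_gs: float = 254.0,
    min_run_s: float = 2.0,
    prominence_frac: float = 0.15,
    downslope_horizons_s: Sequence[int] = DEFAULT_HORIZONS_S,
) -> CohortFeatures:
    """Run QC + conditioning + feature extraction over a cohort."""
    qc_rows = []
    normalized: dict[str, NormalizedTrace] = {}
    milestones: dict[str, MilestoneFeatures] = {}
    for tr in traces:
        rep = qc_report(
            tr,
            ceiling_gs=ceiling_gs,
            min_run_s=min_run_s,
            prominence_frac=prominence_frac,
        )
        qc_rows.append(
            {
                "trace_id": rep.trace_id,
                "saturated": rep.saturated,
                "saturated_span_s": rep.saturated_span_s,
                "double_peak": rep.double_peak,
                "n_peaks": len(rep.peak_times_s),
                "max_intensity_gs": rep.max_intensity_gs,
                "usable_post_peak_s": rep.usable_post_peak_s,
            }
        )
        if drop_saturated and rep.saturated:
            continue
        nt = normalize(smooth(tr, window_s=smooth_window_s, polyorder=polyorder))
        normalized[tr.trace_id] = nt
        milestones[tr.trace_id] = extract_milestones(
            nt, downslope_horizons_s=downslope_horizons_s, prominence_frac=prominence_frac
        )
    features, missingness = build_feature_table(
        milestones.values(), downslope_horizons_s=downslope_horizons_s
    )
    try:
        exp_imputed = exp_imputation_candidates(normalized, milestones)
    except InsufficientTailError:
        exp_imputed = pd.DataFrame(columns=[f"ds{h}" for h in downslope_horizons_s])
    return CohortFeatures(
        features=features,
        missingness=missingness,
        qc=pd.DataFrame(qc_rows),
        normalized=normalized,
        milestones=milestones,
        exp_imputed=exp_imputed,
    )
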