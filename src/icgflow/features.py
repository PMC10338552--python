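"""Curve-milestone feature extraction from normalized traces.

The feature vector summarizes one perfusion curve with scalar "milestones":

* ``time_to_first_peak_s`` (Tmax) — recording start to the first prominent
  local maximum (a double-bolus curve reports the *first* peak, even when the
  second is higher);
* ``time_to_half_max_s`` (T1/2max) — first crossing of half the peak value on
  the rising limb, linearly interpolated;
* ``time_ratio`` — T1/2max / Tmax, a shape descriptor of the inflow limb;
* ``upslope_per_s`` — least-squares slope of the normalized rise between the
  first 0.1 crossing and the peak (robust to onset noise);
* ``downslope_N`` for N in {10, 50, 100, 200, 300, 400} s — normalized
  intensity change per second between the peak and N seconds after it,
  ``(F(t_peak + N) - F(t_peak)) / N`` with linear interpolation at the
  horizon; horizons beyond the recording are *missing* (never extrapolated
  here — extrapolation is the imputation module's job);
* ``kurtosis`` — Fisher excess kurtosis of the full normalized series.

Every downslope carries a provenance mark: observed, missing or imputed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import kurtosis as _fisher_kurtosis

from .preprocess import NormalizedTrace

DEFAULT_HORIZONS_S = (10, 50, 100, 200, 300, 400)

OBSERVED = "observed"
MISSING = "missing"
IMPUTED = "imputed"


class PeakNotReachedError(ValueError):
    """The trace is still rising at its end; no peak to anchor milestones."""


class FeatureTableError(ValueError):
    pass


def detect_first_peak(
    trace: NormalizedTrace, prominence_frac: float = 0.15
) -> tuple[float, int]:
    """Earliest local maximum with prominence >= prominence_frac * max.

    Falls back to the global argmax when no local maximum is prominent (e.g.
    a curve that plateaus at its peak); a trace whose maximum is its final
    sample is rejected as "peak not reached".
    """
    y = trace.intensity
    peaks, _ = find_peaks(y, prominence=prominence_frac * float(y.max()))
    if len(peaks):
        idx = int(peaks[0])
    else:
        idx = int(np.argmax(y))  # earliest occurrence of the max wins
        if idx == len(y) - 1:
            raise PeakNotReachedError(
                f"trace {trace.trace_id!r} is monotone increasing: peak not reached"
            )
    return float(trace.time_s[idx] - trace.time_s[0]), idx


def _first_crossing_time(t: np.ndarray, y: np.ndarray, level: float, i_peak: int) -> float:
    """Linearly interpolated time of the first upward crossing of ``level``
    on the rise (indices 0..i_peak), relative to recording start."""
    rise = y[: i_peak + 1]
    above = np.nonzero(rise >= level)[0]
    if len(above) == 0:
        return float(t[i_peak] - t[0])
    j = int(above[0])
    if j == 0:
        return 0.0
    frac = (level - y[j - 1]) / (y[j] - y[j - 1])
    return float(t[j - 1] + frac * (t[j] - t[j - 1]) - t[0])


@dataclass(frozen=True)
class MilestoneFeatures:
    trace_id: str
    time_to_first_peak_s: float
    time_to_half_max_s: float
    time_ratio: float
    upslope_per_s: float
    kurtosis: float
    downslopes: Mapping[int, float]  # horizon_s -> slope (nan when missing)
    provenance: Mapping[int, str]  # horizon_s -> observed | missing | imputed
    patient_id: str = ""
    class_label: str = "unknown"

    def to_row(self) -> dict:
        row = {
            "trace_id": self.trace_id,
            "patient_id": self.patient_id,
            "class": self.class_label,
            "ttfp_s": self.time_to_first_peak_s,
            "t_half_s": self.time_to_half_max_s,
            "time_ratio": self.time_ratio,
            "upslope": self.upslope_per_s,
        }
        for h in sorted(self.downslopes):
            row[f"ds{h}"] = self.downslopes[h]
        row["kurtosis"] = self.kurtosis
        for h in sorted(self.downslopes):
            row[f"ds{h}_provenance"] = self.provenance[h]
        return row


def extract_milestones(
    trace: NormalizedTrace,
    downslope_horizons_s: Sequence[int] = DEFAULT_HORIZONS_S,
    prominence_frac: float = 0.15,
) -> MilestoneFeatures:
    """Extract the milestone vector from a smoothed, normalized trace."""
    t = trace.time_s
    y = trace.intensity
    ttfp, i_peak = detect_first_peak(trace, prominence_frac=prominence_frac)
    peak_val = float(y[i_peak])

    t_half = _first_crossing_time(t, y, 0.5 * peak_val, i_peak)
    time_ratio = t_half / ttfp if ttfp > 0 else np.nan

    # upslope: least-squares fit between the 0.1 crossing and the peak
    j10 = int(np.nonzero(y[: i_peak + 1] >= 0.1 * peak_val)[0][0]) if i_peak > 0 else 0
    if i_peak - j10 >= 1:
        coeffs = np.polyfit(t[j10 : i_peak + 1], y[j10 : i_peak + 1], 1)
        upslope = float(coeffs[0])
    else:
        upslope = np.nan

    downslopes: dict[int, float] = {}
    provenance: dict[int, str] = {}
    t_peak_abs = t[i_peak]
    for h in downslope_horizons_s:
        target = t_peak_abs + h
        if target > t[-1] + 1e-9:
            downslopes[h] = np.nan
            provenance[h] = MISSING
        else:
            f_h = float(np.interp(target, t, y))
            downslopes[h] = (f_h - peak_val) / h
            provenance[h] = OBSERVED

    kurt = float(_fisher_kurtosis(y, fisher=True, bias=True))
    return MilestoneFeatures(
        trace_id=trace.trace_id,
        time_to_first_peak_s=ttfp,
        time_to_half_max_s=t_half,
        time_ratio=time_ratio,
        upslope_per_s=upslope,
        kurtosis=kurt,
        downslopes=downslopes,
        provenance=provenance,
        patient_id=trace.patient_id,
        class_label=trace.class_label,
    )


def build_feature_table(
    cohort: Iterable[NormalizedTrace | MilestoneFeatures],
    downslope_horizons_s: Sequence[int] = DEFAULT_HORIZONS_S,
) -> tuple[pd.DataFrame, dict[int, int]]:
    """One row per ROI plus a per-horizon missingness summary.

    Accepts normalized traces (milestones are extracted here) or
    ready-made milestone records.
    """
    milestones: list[MilestoneFeatures] = []
    for item in cohort:
        if isinstance(item, MilestoneFeatures):
            milestones.append(item)
        else:
            milestones.append(extract_milestones(item, downslope_horizons_s))
    if not milestones:
        raise FeatureTableError("empty cohort: no traces to tabulate")
    ids = [m.trace_id for m in milestones]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FeatureTableError(f"duplicate trace_id(s): {dupes}")
    df = pd.DataFrame([m.to_row() for m in milestones])
    summary = {
        h: int((df[f"ds{h}_provenance"] == MISSING).sum()) for h in downslope_horizons_s
    }
    return df, summary
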