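"""QC and conditioning of raw traces: saturation / double-peak detection,
Savitzky-Golay smoothing, peak normalization."""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .trace import GREYSCALE_CEILING, FluorescenceTrace, TraceValidationError


class SmoothingError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizedTrace:
    """A trace divided by its own peak intensity (dimensionless, max 1.0).

    Peak normalization removes the distance-intensity confound: two curves of
    identical shape but different absolute brightness normalize identically.
    """

    trace_id: str
    time_s: np.ndarray
    intensity: np.ndarray
    normalization_peak_gs: float
    patient_id: str = ""
    class_label: str = "unknown"

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "intensity", y)
        if t.shape != y.shape or t.ndim != 1 or t.size < 2:
            raise TraceValidationError("invalid normalized trace arrays")
        if abs(y.max() - 1.0) > 1e-9 or y.min() < -1e-12:
            raise TraceValidationError("normalized intensities must lie in [0, 1] with max 1")

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time_s)))

    def __len__(self) -> int:
        return int(self.time_s.size)


@dataclass(frozen=True)
class SaturationResult:
    saturated: bool
    saturated_span_s: float
    onset_s: float | None


@dataclass(frozen=True)
class DoublePeakResult:
    double_peak: bool
    peak_times_s: tuple[float, ...]


@dataclass(frozen=True)
class QCReport:
    trace_id: str
    saturated: bool
    saturated_span_s: float
    double_peak: bool
    peak_times_s: tuple[float, ...]
    max_intensity_gs: float
    usable_post_peak_s: float


def detect_saturation(
    trace: FluorescenceTrace,
    ceiling_gs: float = 254.0,
    min_run_s: float = 2.0,
) -> SaturationResult:
    """Flag a ceiling plateau: a run of samples at/above ``ceiling_gs``
    lasting at least ``min_run_s``.  Reports the longest such run."""
    at = trace.intensity_gs >= ceiling_gs
    best_span, best_onset = 0.0, None
    i = 0
    n = len(at)
    while i < n:
        if at[i]:
            j = i
            while j + 1 < n and at[j + 1]:
                j += 1
            span = float(trace.time_s[j] - trace.time_s[i])
            if span > best_span:
                best_span, best_onset = span, float(trace.time_s[i])
            i = j + 1
        else:
            i += 1
    flagged = best_span >= min_run_s
    return SaturationResult(
        saturated=flagged,
        saturated_span_s=best_span if flagged else 0.0,
        onset_s=best_onset if flagged else None,
    )


def detect_double_peak(
    trace: FluorescenceTrace,
    prominence_frac: float = 0.15,
    window_s: float = 60.0,
) -> DoublePeakResult:
    """Flag two or more prominent local maxima inside the inflow window.

    Prominence threshold is ``prominence_frac`` of the global maximum; a
    pre-smoothed trace is recommended so movement noise does not fake peaks.
    """
    y = trace.intensity_gs
    peaks, _ = find_peaks(y, prominence=prominence_frac * float(y.max()))
    times = tuple(
        float(trace.time_s[p]) for p in peaks if trace.time_s[p] <= trace.time_s[0] + window_s
    )
    return DoublePeakResult(double_peak=len(times) >= 2, peak_times_s=times)


def smooth(
    trace: FluorescenceTrace,
    window_s: float = 11.0,
    polyorder: int = 3,
    ceiling_gs: float = GREYSCALE_CEILING,
) -> FluorescenceTrace:
    """Savitzky-Golay filter with the window given in seconds (forced to an
    odd sample count).  Output clipped back to the greyscale range."""
    window = int(round(window_s * trace.sampling_rate_hz))
    if window % 2 == 0:
        window += 1
    if window <= polyorder:
        raise SmoothingError(
            f"window of {window} samples must exceed polyorder {polyorder}"
        )
    if window > len(trace):
        raise SmoothingError(
            f"trace has {len(trace)} samples < window {window}; reduce window_s"
        )
    y = savgol_filter(trace.intensity_gs, window, polyorder, mode="interp")
    y = np.clip(y, 0.0, ceiling_gs)
    return replace(trace, intensity_gs=y)


def normalize(trace: FluorescenceTrace | NormalizedTrace) -> NormalizedTrace:
    """Divide every sample by the curve's peak intensity reading."""
    y = trace.intensity_gs if isinstance(trace, FluorescenceTrace) else trace.intensity
    peak = float(y.max())
    if peak <= 0:
        raise NormalizationError(f"trace {trace.trace_id!r} has no positive peak")
    return NormalizedTrace(
        trace_id=trace.trace_id,
        time_s=trace.time_s.copy(),
        intensity=y / peak,
        normalization_peak_gs=peak,
        patient_id=trace.patient_id,
        class_label=trace.class_label,
    )


def qc_report(
    trace: FluorescenceTrace,
    ceiling_gs: float = 254.0,
    min_run_s: float = 2.0,
    prominence_frac: float = 0.15,
    window_s: float = 60.0,
    peak_smooth_window_s: float = 5.0,
) -> QCReport:
    """Per-trace QC: saturation on the raw trace, double-peak on a lightly
    smoothed copy (a shorter window than slope estimation so close twin peaks
    survive the filter)."""
    sat = detect_saturation(trace, ceiling_gs=ceiling_gs, min_run_s=min_run_s)
    try:
        sm = smooth(trace, window_s=peak_smooth_window_s)
    except SmoothingError:
        sm = trace
    dp = detect_double_peak(sm, prominence_frac=prominence_frac, window_s=window_s)
    i_max = int(np.argmax(sm.intensity_gs))
    usable = float(trace.time_s[-1] - trace.time_s[i_max])
    return QCReport(
        trace_id=trace.trace_id,
        saturated=sat.saturated,
        saturated_span_s=sat.saturated_span_s,
        double_peak=dp.double_peak,
        peak_times_s=dp.peak_times_s,
        max_intensity_gs=float(trace.intensity_gs.max()),
        usable_post_peak_s=usable,
    )
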