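"""Synthetic ICG perfusion-curve and frame-stack generation.

Clinical ICG angiography videos are rarely shareable, so every downstream
stage of this package is exercised against cohorts generated here.  The
kinetic model is the standard bolus-transit shape used for contrast agents:

* a gamma-variate inflow ``F(t) = P * (tau/tau_p)**alpha * exp(alpha * (1 -
  tau/tau_p))`` with ``alpha = 2`` rising from the onset of dye arrival to the
  peak ``P`` at ``tau = tau_p`` (``tau`` is time since onset), and
* a washout tail ``F = P * (plateau + (1 - plateau) * exp(-k * dt))`` after
  the peak, continuous at the peak.

``plateau`` models ICG retention: malignant tissue holds dye (slow, incomplete
washout), healthy tissue clears it.  Class presets anchor the *normalized*
10-second post-peak downslope to the values observed clinically (healthy
about -0.0065 1/s, benign about -0.004 1/s, cancer about -0.001 1/s) with a
20% coefficient of variation across ROIs.

Acquisition artifacts are layered on top in a fixed, documented order:
kinetics -> double-bolus second pulse -> movement noise / spike -> clip to
the greyscale ceiling.  Peak intensities above the 8-bit ceiling emulate
overdosing and produce saturation plateaus after clipping.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .trace import (
    GREYSCALE_CEILING,
    FluorescenceTrace,
    RoiBox,
    TraceValidationError,
)

RISE_SHAPE_ALPHA = 2.0  # gamma-variate shape exponent of the inflow limb
DOWNSLOPE_HORIZONS_S = (10, 50, 100, 200, 300, 400)


# ---------------------------------------------------------------------------
# Kinetic model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParams:
    """Parameters of one ROI's noiseless inflow/washout curve.

    peak_intensity_gs may exceed the 8-bit ceiling (255): emitted samples are
    clipped, which is exactly how an overdosed acquisition saturates.
    """

    onset_time_s: float
    time_to_peak_s: float
    peak_intensity_gs: float
    washout_rate_per_s: float
    plateau_fraction: float

    def __post_init__(self) -> None:
        checks = [
            ("onset_time_s", self.onset_time_s, self.onset_time_s >= 0),
            ("time_to_peak_s", self.time_to_peak_s, self.time_to_peak_s > 0),
            ("peak_intensity_gs", self.peak_intensity_gs, self.peak_intensity_gs > 0),
            ("washout_rate_per_s", self.washout_rate_per_s, self.washout_rate_per_s >= 0),
            ("plateau_fraction", self.plateau_fraction, 0 <= self.plateau_fraction <= 1),
        ]
        for name, v, ok in checks:
            if not (np.isfinite(v) and ok):
                raise TraceValidationError(f"KineticParams.{name} out of range: {v!r}")

    @property
    def peak_time_s(self) -> float:
        return self.onset_time_s + self.time_to_peak_s


def kinetic_curve(
    t_s: np.ndarray, params: KineticParams, rise_alpha: float = RISE_SHAPE_ALPHA
) -> np.ndarray:
    """Noiseless curve value (greyscale units) at times ``t_s``."""
    t = np.asarray(t_s, dtype=float)
    tau = t - params.onset_time_s
    a = rise_alpha
    x = np.clip(tau / params.time_to_peak_s, 0.0, None)
    rise = x**a * np.exp(a * (1.0 - x))
    dt = tau - params.time_to_peak_s
    pl = params.plateau_fraction
    tail = pl + (1.0 - pl) * np.exp(-params.washout_rate_per_s * np.clip(dt, 0.0, None))
    y = np.where(tau <= 0.0, 0.0, np.where(dt <= 0.0, rise, tail))
    return params.peak_intensity_gs * y


def washout_rate_for_downslope10(
    downslope10_per_s: float, plateau_fraction: float, horizon_s: float = 10.0
) -> float:
    """Invert the normalized tail so its ``horizon_s`` downslope hits a target.

    The normalized tail is ``f(dt) = plateau + (1-plateau) exp(-k dt)`` and the
    downslope over N seconds is ``(f(N) - 1) / N``; solve for k.
    """
    target = 1.0 + horizon_s * downslope10_per_s
    if not 0 < target <= 1:
        raise TraceValidationError(
            f"downslope {downslope10_per_s} over {horizon_s}s leaves no valid tail value"
        )
    if plateau_fraction >= 1.0:
        if downslope10_per_s != 0:
            raise TraceValidationError("plateau_fraction=1 admits only zero downslope")
        return 0.0
    frac = (target - plateau_fraction) / (1.0 - plateau_fraction)
    if not 0 < frac <= 1:
        raise TraceValidationError(
            f"target downslope {downslope10_per_s} unreachable below plateau "
            f"{plateau_fraction}"
        )
    return -math.log(frac) / horizon_s


def analytic_downslope(params: KineticParams, horizon_s: float) -> float:
    """Closed-form normalized downslope ``(f(N) - 1)/N`` of the model tail."""
    pl = params.plateau_fraction
    f_n = pl + (1.0 - pl) * math.exp(-params.washout_rate_per_s * horizon_s)
    return (f_n - 1.0) / horizon_s


def analytic_time_to_peak(params: KineticParams) -> float:
    return params.peak_time_s


def analytic_half_max_time(params: KineticParams) -> float:
    """Time (from recording start) of the first 0.5 crossing on the rise."""
    a = RISE_SHAPE_ALPHA

    def g(x: float) -> float:
        return x**a * math.exp(a * (1.0 - x)) - 0.5

    x_half = brentq(g, 1e-9, 1.0, xtol=1e-12)
    return params.onset_time_s + x_half * params.time_to_peak_s


# ---------------------------------------------------------------------------
# Artifacts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoubleBolus:
    """Split ('double bolus') dye administration.

    The first pulse clears at first-pass speed (``first_pulse_washout_per_s``)
    before the second pulse arrives, and the second pulse rises with a
    steeper gamma-variate exponent (``second_pulse_rise_alpha``), producing
    the twin-peak morphology with a visible valley between the peaks; the
    second (main) pulse carries the tissue's washout tail.
    """

    second_peak_delay_s: float
    second_peak_relative_amplitude: float = 0.7
    first_pulse_washout_per_s: float = 0.2
    second_pulse_rise_alpha: float = 4.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.second_peak_delay_s) and self.second_peak_delay_s > 0):
            raise TraceValidationError("DoubleBolus.second_peak_delay_s must be > 0")
        if not 0 < self.second_peak_relative_amplitude <= 1:
            raise TraceValidationError(
                "DoubleBolus.second_peak_relative_amplitude must be in (0, 1]"
            )


@dataclass(frozen=True)
class MovementSpike:
    """Transient camera lurch toward the target (brief intensity surge)."""

    time_s: float
    amplitude_gs: float
    width_s: float


@dataclass(frozen=True)
class ArtifactConfig:
    """Acquisition artifacts layered onto the noiseless kinetics."""

    saturation_ceiling_gs: float = GREYSCALE_CEILING
    enable_saturation: bool = True
    double_bolus: DoubleBolus | None = None
    movement_noise_sd_gs: float = 0.0
    movement_freq_hz: float = 0.3
    movement_spike: MovementSpike | None = None
    truncation_time_s: float | None = None

    def __post_init__(self) -> None:
        if self.movement_noise_sd_gs < 0:
            raise TraceValidationError("movement_noise_sd_gs must be >= 0")
        if not 0 < self.saturation_ceiling_gs <= GREYSCALE_CEILING:
            raise TraceValidationError("saturation_ceiling_gs must be in (0, 255]")


NO_ARTIFACTS = ArtifactConfig()


def generate_trace(
    params: KineticParams,
    artifacts: ArtifactConfig = NO_ARTIFACTS,
    sampling_rate_hz: float = 5.0,
    duration_s: float = 420.0,
    seed: int | np.random.Generator = 0,
    trace_id: str = "trace",
    patient_id: str = "",
    class_label: str = "unknown",
) -> FluorescenceTrace:
    """Sample one trace on a uniform grid, artifacts applied in fixed order:
    kinetics -> double bolus -> movement noise/spike -> clip to ceiling."""
    if not (np.isfinite(sampling_rate_hz) and sampling_rate_hz > 0):
        raise TraceValidationError("sampling_rate_hz must be > 0")
    dur = duration_s
    if artifacts.truncation_time_s is not None:
        dur = min(dur, artifacts.truncation_time_s)
    if dur <= params.peak_time_s:
        raise TraceValidationError(
            "duration_s must exceed onset_time_s + time_to_peak_s"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(math.floor(dur * sampling_rate_hz)) + 1
    t = np.arange(n) / sampling_rate_hz
    y = kinetic_curve(t, params)

    db = artifacts.double_bolus
    if db is not None:
        first = replace(
            params,
            washout_rate_per_s=max(params.washout_rate_per_s, db.first_pulse_washout_per_s),
            plateau_fraction=min(params.plateau_fraction, 0.2),
        )
        second = replace(
            params,
            onset_time_s=params.onset_time_s + db.second_peak_delay_s,
            peak_intensity_gs=params.peak_intensity_gs * db.second_peak_relative_amplitude,
        )
        y = kinetic_curve(t, first) + kinetic_curve(
            t, second, rise_alpha=db.second_pulse_rise_alpha
        )

    if artifacts.movement_noise_sd_gs > 0:
        sd = artifacts.movement_noise_sd_gs
        phase = rng.uniform(0.0, 2.0 * math.pi)
        y = y + rng.normal(0.0, sd, size=n)
        y = y + sd * np.sin(2.0 * math.pi * artifacts.movement_freq_hz * t + phase)

    sp = artifacts.movement_spike
    if sp is not None:
        y = y + sp.amplitude_gs * np.exp(-0.5 * ((t - sp.time_s) / sp.width_s) ** 2)

    ceiling = artifacts.saturation_ceiling_gs if artifacts.enable_saturation else GREYSCALE_CEILING
    y = np.clip(y, 0.0, ceiling)
    return FluorescenceTrace(
        trace_id=trace_id,
        time_s=t,
        intensity_gs=y,
        patient_id=patient_id,
        class_label=class_label,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticDistribution:
    """Per-class sampling distribution: (mean, sd) per kinetic field.

    The washout rate is parameterized through the normalized 10-s downslope
    (the quantity reported clinically) and converted per trace.
    """

    onset_time_s: tuple[float, float]
    time_to_peak_s: tuple[float, float]
    peak_intensity_gs: tuple[float, float]
    downslope10_per_s: tuple[float, float]
    plateau_fraction: tuple[float, float]

    def sample(self, rng: np.random.Generator) -> KineticParams:
        onset = float(np.clip(rng.normal(*self.onset_time_s), 0.5, 30.0))
        ttp = float(np.clip(rng.normal(*self.time_to_peak_s), 5.0, 90.0))
        peak = float(np.clip(rng.normal(*self.peak_intensity_gs), 20.0, GREYSCALE_CEILING))
        plateau = float(np.clip(rng.normal(*self.plateau_fraction), 0.0, 0.9))
        lo = max(-0.02, (plateau - 1.0) / 10.0 + 1e-4)
        slope = float(np.clip(rng.normal(*self.downslope10_per_s), lo, -1e-4))
        k = washout_rate_for_downslope10(slope, plateau)
        return KineticParams(onset, ttp, peak, k, plateau)


def preset_class_kinetics(
    downslope10_by_class: Mapping[str, float] | None = None,
    spread_frac: float = 0.2,
) -> dict[str, KineticDistribution]:
    """Clinically anchored class presets (downslopes healthy/benign/cancer =
    -0.0065 / -0.004 / -0.001 1/s), 20% CV unless overridden."""
    slopes = {"healthy": -0.0065, "benign": -0.004, "cancer": -0.001}
    if downslope10_by_class:
        slopes.update(downslope10_by_class)
    base = {
        "healthy": dict(onset=(5.0, 1.0), ttp=(20.0, 4.0), peak=(180.0, 36.0), pl=(0.05, 0.01)),
        "benign": dict(onset=(6.0, 1.2), ttp=(25.0, 5.0), peak=(150.0, 30.0), pl=(0.15, 0.03)),
        "cancer": dict(onset=(8.0, 1.6), ttp=(30.0, 6.0), peak=(120.0, 24.0), pl=(0.35, 0.07)),
    }
    out = {}
    for cls, b in base.items():
        s = slopes[cls]
        out[cls] = KineticDistribution(
            onset_time_s=b["onset"],
            time_to_peak_s=b["ttp"],
            peak_intensity_gs=b["peak"],
            downslope10_per_s=(s, abs(s) * spread_frac),
            plateau_fraction=b["pl"],
        )
    return out


CLASS_PRESETS = preset_class_kinetics()


@dataclass(frozen=True)
class DurationSpec:
    """Trace-length plan producing controlled downslope missingness.

    ``missing_counts[N]`` traces end before peak + N seconds (cumulative over
    increasing N, i.e. a trace missing the 200-s downslope also misses the
    300- and 400-s ones).  Remaining traces run past the longest horizon.
    """

    missing_counts: Mapping[int, int] = field(
        default_factory=lambda: {200: 11, 300: 72, 400: 106}
    )
    complete_post_peak_s: tuple[float, float] = (420.0, 470.0)
    margin_s: float = 15.0

    def sample_post_peak(self, n: int, rng: np.random.Generator) -> np.ndarray:
        horizons = sorted(self.missing_counts)
        counts = [self.missing_counts[h] for h in horizons]
        if any(c2 < c1 for c1, c2 in zip(counts, counts[1:])):
            raise TraceValidationError("missing_counts must be cumulative (non-decreasing)")
        if counts and counts[-1] > n:
            raise TraceValidationError("missing_counts exceed cohort size")
        standard = list(DOWNSLOPE_HORIZONS_S)
        out = np.empty(n)
        order = rng.permutation(n)
        pos = 0
        prev_count = 0
        for h, c in zip(horizons, counts):
            group = c - prev_count
            below = max(s for s in standard if s < h)
            lo, hi = below + self.margin_s, h - self.margin_s
            out[order[pos : pos + group]] = rng.uniform(lo, hi, size=group)
            pos += group
            prev_count = c
        rest = n - pos
        out[order[pos:]] = rng.uniform(*self.complete_post_peak_s, size=rest)
        return out


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full parameterization of a synthetic cohort.

    Defaults emulate the clinical rectal series: 251 ROIs over 37 patients
    (13 benign, 24 cancer lesions, healthy controls in every video), 5 Hz
    sampling, movement noise of 2% of each trace's peak, and durations
    arranged so 11/72/106 ROIs lack the 200/300/400-s downslopes.
    """

    n_patients: int = 37
    n_benign_patients: int = 13
    class_counts: Mapping[str, int] = field(
        default_factory=lambda: {"healthy": 79, "benign": 52, "cancer": 120}
    )
    class_kinetics: Mapping[str, KineticDistribution] = field(
        default_factory=preset_class_kinetics
    )
    movement_noise_frac: float = 0.02
    double_bolus_prob: float = 0.0
    saturation_prob: float = 0.0
    sampling_rate_hz: float = 5.0
    durations: DurationSpec = field(default_factory=DurationSpec)
    seed: int = 0


def _patient_roster(config: SyntheticCohortConfig) -> list[tuple[str, str]]:
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    benign_patients = patients[: config.n_benign_patients]
    cancer_patients = patients[config.n_benign_patients :]
    pools = {"healthy": patients, "benign": benign_patients, "cancer": cancer_patients}
    roster: list[tuple[str, str]] = []
    for cls, count in config.class_counts.items():
        if count < 1:
            raise TraceValidationError(f"class {cls!r} must have at least 1 ROI")
        pool = pools.get(cls)
        if not pool:
            raise TraceValidationError(f"no patients available for class {cls!r}")
        for i in range(count):
            roster.append((pool[i % len(pool)], cls))
    return roster


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[FluorescenceTrace], pd.DataFrame]:
    """Generate traces plus a ground-truth manifest (one row per trace).

    Deterministic: identical config + seed give bit-identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    roster = _patient_roster(config)
    n = len(roster)
    post_peak = config.durations.sample_post_peak(n, rng)
    counters: dict[tuple[str, str], int] = {}
    traces: list[FluorescenceTrace] = []
    rows: list[dict] = []
    for i, (pid, cls) in enumerate(roster):
        params = config.class_kinetics[cls].sample(rng)
        overdosed = bool(rng.random() < config.saturation_prob)
        if overdosed:
            params = replace(
                params, peak_intensity_gs=GREYSCALE_CEILING * rng.uniform(1.15, 1.5)
            )
        db = None
        if rng.random() < config.double_bolus_prob:
            db = DoubleBolus(
                second_peak_delay_s=rng.uniform(10.0, 14.0),
                second_peak_relative_amplitude=rng.uniform(0.6, 0.9),
            )
        sd = config.movement_noise_frac * min(params.peak_intensity_gs, GREYSCALE_CEILING)
        art = ArtifactConfig(
            double_bolus=db,
            movement_noise_sd_gs=sd,
            movement_freq_hz=rng.uniform(0.2, 0.5),
        )
        idx = counters.setdefault((pid, cls), 0)
        counters[(pid, cls)] = idx + 1
        tid = f"{pid}_{cls}_{idx}"
        duration = params.peak_time_s + post_peak[i]
        tr = generate_trace(
            params,
            art,
            sampling_rate_hz=config.sampling_rate_hz,
            duration_s=duration,
            seed=rng,
            trace_id=tid,
            patient_id=pid,
            class_label=cls,
        )
        traces.append(tr)
        row = {
            "trace_id": tid,
            "patient_id": pid,
            "class_label": cls,
            "onset_time_s": params.onset_time_s,
            "time_to_peak_s": params.time_to_peak_s,
            "peak_time_s": params.peak_time_s,
            "peak_intensity_gs": params.peak_intensity_gs,
            "washout_rate_per_s": params.washout_rate_per_s,
            "plateau_fraction": params.plateau_fraction,
            "post_peak_s": post_peak[i],
            "duration_s": duration,
            "double_bolus": db is not None,
            "overdosed": overdosed,
        }
        for h in DOWNSLOPE_HORIZONS_S:
            row[f"ds{h}_true"] = analytic_downslope(params, h)
        rows.append(row)
    return traces, pd.DataFrame(rows)


def default_cohort_config(seed: int = 0, **overrides) -> SyntheticCohortConfig:
    """The clinically anchored 251-ROI / 37-patient cohort configuration."""
    return SyntheticCohortConfig(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Frame stacks
# ---------------------------------------------------------------------------

def render_frame_stack(
    traces: Sequence[FluorescenceTrace],
    rois: Sequence[RoiBox],
    frame_shape: tuple[int, int] = (64, 64),
    pixel_noise_sd_gs: float = 0.0,
    background_gs: float = 5.0,
    background_noise_sd_gs: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paint traces into box ROIs of a greyscale frame stack.

    Inside each box, pixel values are Normal(trace value, pixel_noise_sd_gs);
    with zero pixel noise the box holds the exact trace value, so mean
    extraction round-trips the source trace.  All pixels clipped to [0, 255].
    """
    if len(traces) != len(rois):
        raise TraceValidationError("need exactly one ROI per trace")
    if not traces:
        raise TraceValidationError("need at least one trace")
    t0 = traces[0].time_s
    for tr in traces[1:]:
        if tr.time_s.shape != t0.shape or not np.allclose(tr.time_s, t0):
            raise TraceValidationError("all traces must share one time grid")
    for i, a in enumerate(rois):
        a.validate_within(frame_shape)
        for b in rois[i + 1 :]:
            if a.overlaps(b):
                raise TraceValidationError(f"ROIs {a.roi_id!r} and {b.roi_id!r} overlap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = t0.size
    h, w = frame_shape
    frames = rng.normal(background_gs, background_noise_sd_gs, size=(n, h, w))
    for tr, roi in zip(traces, rois):
        ys, xs = roi.slices
        block = np.broadcast_to(
            tr.intensity_gs[:, None, None], (n, roi.height, roi.width)
        ).copy()
        if pixel_noise_sd_gs > 0:
            block += rng.normal(0.0, pixel_noise_sd_gs, size=block.shape)
        frames[:, ys, xs] = block
    return np.clip(frames, 0.0, GREYSCALE_CEILING), t0.copy()
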