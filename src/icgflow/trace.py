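"""ROI time-fluorescence traces, box ROIs and their file formats.

The "digital biopsy" primitive: a rectangular region of interest drawn over a
greyscale NIR frame stack is reduced to a per-frame mean pixel intensity,
giving one time-fluorescence curve per ROI.  Traces travel as CSV
(``time_s,intensity_gs``), frame stacks as multi-page TIFF or a directory of
PNG frames with a ``frames.csv`` timestamp index, ROI boxes as CSV.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GREYSCALE_CEILING = 255.0
CLASS_LABELS = ("healthy", "benign", "cancer", "unknown")


class TraceValidationError(ValueError):
    """A trace, ROI or frame stack violates a structural contract."""


class TraceParseError(ValueError):
    """A file could not be parsed into a valid trace."""


@dataclass(frozen=True)
class FluorescenceTrace:
    """One ROI's raw time-intensity series in 8-bit greyscale units.

    ``time_s`` is strictly increasing, in seconds from recording start;
    ``intensity_gs`` is bounded to [0, 255] (the imager's display range).
    """

    trace_id: str
    time_s: np.ndarray
    intensity_gs: np.ndarray
    patient_id: str = ""
    class_label: str = "unknown"

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        y = np.asarray(self.intensity_gs, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "intensity_gs", y)
        if t.ndim != 1 or y.ndim != 1 or t.shape != y.shape:
            raise TraceValidationError(
                "time_s and intensity_gs must be 1-D arrays of equal length"
            )
        if t.size < 2:
            raise TraceValidationError("trace must contain at least 2 samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise TraceValidationError("trace contains non-finite values")
        bad = np.diff(t) <= 0
        if bad.any():
            i = int(np.argmax(bad)) + 1
            raise TraceValidationError(f"time_s not strictly increasing at sample {i}")
        if y.min() < 0 or y.max() > GREYSCALE_CEILING:
            raise TraceValidationError(
                "intensity_gs outside the 8-bit greyscale range [0, 255]"
            )
        if self.class_label not in CLASS_LABELS:
            raise TraceValidationError(f"unknown class_label {self.class_label!r}")

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time_s)))

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    def __len__(self) -> int:
        return int(self.time_s.size)


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned pixel box, 0-based origin, half-open extent."""

    roi_id: str
    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        for name in ("x0", "y0", "width", "height"):
            v = getattr(self, name)
            if int(v) != v:
                raise TraceValidationError(f"RoiBox.{name} must be an integer")
            object.__setattr__(self, name, int(v))
        if self.x0 < 0 or self.y0 < 0:
            raise TraceValidationError("RoiBox origin must be non-negative")
        if self.width < 1 or self.height < 1:
            raise TraceValidationError("RoiBox width and height must be >= 1 pixel")

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y0 + self.height), slice(self.x0, self.x0 + self.width)

    def validate_within(self, frame_shape: tuple[int, int]) -> None:
        h, w = frame_shape
        if self.y0 + self.height > h or self.x0 + self.width > w:
            raise TraceValidationError(
                f"ROI {self.roi_id!r} exceeds frame bounds {frame_shape}"
            )

    def overlaps(self, other: "RoiBox") -> bool:
        return not (
            self.x0 + self.width <= other.x0
            or other.x0 + other.width <= self.x0
            or self.y0 + self.height <= other.y0
            or other.y0 + other.height <= self.y0
        )


def extract_traces(
    frames: np.ndarray,
    timestamps: Sequence[float],
    rois: Sequence[RoiBox],
    statistic: str = "mean",
) -> list[FluorescenceTrace]:
    """Reduce each ROI of a greyscale frame stack to a per-frame statistic.

    ``frames`` has shape (n_frames, height, width).  Colour stacks are
    rejected: the NIR channel must be extracted to greyscale upstream.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 4:
        raise TraceValidationError(
            "multi-channel (colour) frame stacks are not supported; "
            "supply single-channel greyscale frames"
        )
    if frames.ndim != 3:
        raise TraceValidationError("frames must have shape (n_frames, height, width)")
    if frames.shape[0] == 0:
        raise TraceValidationError("empty frame stack")
    t = np.asarray(timestamps, dtype=float)
    if t.shape != (frames.shape[0],):
        raise TraceValidationError("timestamps length must match frame count")
    if statistic not in ("mean", "median"):
        raise TraceValidationError("statistic must be 'mean' or 'median'")
    reducer = np.mean if statistic == "mean" else np.median
    out = []
    for roi in rois:
        roi.validate_within(frames.shape[1:])
        ys, xs = roi.slices
        series = reducer(frames[:, ys, xs], axis=(1, 2))
        out.append(FluorescenceTrace(trace_id=roi.roi_id, time_s=t, intensity_gs=series))
    return out


# ---------------------------------------------------------------------------
# CSV formats
# ---------------------------------------------------------------------------

def write_trace_csv(trace: FluorescenceTrace, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": trace.time_s, "intensity_gs": trace.intensity_gs})
    df.to_csv(path, index=False, float_format="%.6f")


def read_trace_csv(
    path: str | Path,
    trace_id: str | None = None,
    patient_id: str = "",
    class_label: str = "unknown",
    intensity_col: str | None = None,
) -> FluorescenceTrace:
    """Read a ``time_s,intensity_gs`` CSV; errors carry 1-based file rows."""
    path = Path(path)
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise TraceParseError(f"{path.name}: missing required column 'time_s'")
    if intensity_col is None:
        others = [c for c in df.columns if c != "time_s"]
        if not others:
            raise TraceParseError(f"{path.name}: no intensity column found")
        intensity_col = "intensity_gs" if "intensity_gs" in others else others[0]
    elif intensity_col not in df.columns:
        raise TraceParseError(f"{path.name}: missing column {intensity_col!r}")

    # header is file row 1, first data row is file row 2
    for col in ("time_s", intensity_col):
        vals = pd.to_numeric(df[col], errors="coerce")
        nan_new = vals.isna() & df[col].notna()
        if nan_new.any():
            row = int(np.argmax(nan_new.to_numpy())) + 2
            raise TraceParseError(f"{path.name}: non-numeric {col!r} at row {row}")
        if vals.isna().any():
            row = int(np.argmax(vals.isna().to_numpy())) + 2
            raise TraceParseError(f"{path.name}: empty {col!r} cell at row {row}")
        df[col] = vals.to_numpy(dtype=float)

    t = df["time_s"].to_numpy()
    bad = np.diff(t) <= 0
    if bad.any():
        row = int(np.argmax(bad)) + 1 + 2  # offending (later) sample's file row
        raise TraceParseError(f"{path.name}: time_s not increasing at row {row}")
    y = df[intensity_col].to_numpy()
    if y.min() < 0 or y.max() > GREYSCALE_CEILING:
        row = int(np.argmax((y < 0) | (y > GREYSCALE_CEILING))) + 2
        raise TraceValidationError(
            f"{path.name}: intensity outside [0, 255] at row {row}"
        )
    return FluorescenceTrace(
        trace_id=trace_id if trace_id is not None else path.stem,
        time_s=t,
        intensity_gs=y,
        patient_id=patient_id,
        class_label=class_label,
    )


def write_rois_csv(rois: Sequence[RoiBox], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"roi_id": r.roi_id, "x0": r.x0, "y0": r.y0, "width": r.width, "height": r.height}
            for r in rois
        ]
    ).to_csv(path, index=False)


def read_rois_csv(path: str | Path) -> list[RoiBox]:
    df = pd.read_csv(path)
    required = {"roi_id", "x0", "y0", "width", "height"}
    missing = required - set(df.columns)
    if missing:
        raise TraceParseError(f"ROI file missing columns: {sorted(missing)}")
    return [
        RoiBox(str(r.roi_id), int(r.x0), int(r.y0), int(r.width), int(r.height))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Frame stacks
# ---------------------------------------------------------------------------

def write_frame_stack(frames: np.ndarray, path: str | Path) -> None:
    """Write a (T, H, W) stack as a float32 multi-page TIFF."""
    import tifffile

    tifffile.imwrite(str(path), np.asarray(frames, dtype=np.float32))


def read_frame_stack(
    path: str | Path, fps: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Read a multi-page TIFF (timestamps from ``fps``) or a PNG directory
    carrying a ``frames.csv`` index with columns ``filename,time_s``."""
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        index = path / "frames.csv"
        if not index.exists():
            raise TraceParseError(f"{path}: PNG frame directory needs frames.csv")
        df = pd.read_csv(index)
        frames = np.stack([iio.imread(path / fn) for fn in df["filename"]]).astype(float)
        return frames, df["time_s"].to_numpy(dtype=float)
    import tifffile

    frames = np.asarray(tifffile.imread(str(path)), dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if fps is None:
        raise TraceParseError("fps is required to timestamp a TIFF frame stack")
    return frames, np.arange(frames.shape[0]) / float(fps)


# ---------------------------------------------------------------------------
# Cohort directories
# ---------------------------------------------------------------------------

def write_cohort(
    traces: Iterable[FluorescenceTrace],
    manifest: pd.DataFrame,
    outdir: str | Path,
) -> None:
    """One CSV per trace plus a ``manifest.csv`` with metadata/ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for tr in traces:
        write_trace_csv(tr, outdir / f"{tr.trace_id}.csv")
    manifest.to_csv(outdir / "manifest.csv", index=False)


def read_cohort(indir: str | Path) -> tuple[list[FluorescenceTrace], pd.DataFrame | None]:
    indir = Path(indir)
    manifest_path = indir / "manifest.csv"
    manifest = pd.read_csv(manifest_path) if manifest_path.exists() else None
    meta: dict[str, tuple[str, str]] = {}
    if manifest is not None and "trace_id" in manifest.columns:
        for r in manifest.itertuples(index=False):
            meta[str(r.trace_id)] = (
                str(getattr(r, "patient_id", "")),
                str(getattr(r, "class_label", "unknown")),
            )
    traces = []
    for f in sorted(indir.glob("*.csv")):
        if f.name == "manifest.csv":
            continue
        pid, cls = meta.get(f.stem, ("", "unknown"))
        traces.append(read_trace_csv(f, patient_id=pid, class_label=cls))
    return traces, manifest
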