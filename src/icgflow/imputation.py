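"""Missing-downslope imputation.

Two routes, mirroring how the features are consumed:

* ``knn_impute_train`` — within a training table, each missing downslope is
  replaced by the mean of that column over the K nearest rows (Euclidean
  distance on standardized observed features).  Only valid when neighbours
  exist, i.e. at training time.
* ``exp_impute_test`` — a single test curve cannot be compared to
  neighbours, so its observed post-peak tail is fitted with
  ``F(dt) = a * exp(-b * dt) + c`` and the missing downslopes are read off
  the fitted model.  The offset ``c`` supports dye retention (a non-washing
  plateau); a pure two-parameter decay is available via ``with_offset=False``.

Test-time imputation never sees other traces' data.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.metrics.pairwise import nan_euclidean_distances

from .features import IMPUTED, MISSING, MilestoneFeatures, detect_first_peak
from .preprocess import NormalizedTrace


class ImputationError(ValueError):
    pass


class InsufficientTailError(ImputationError):
    """Fewer than the minimum post-peak samples needed to fit a tail."""


@dataclass(frozen=True)
class ExponentialTailFit:
    """Fitted post-peak model F(dt) = a * exp(-b * dt) + c, dt since peak."""

    a: float
    b: float
    c: float
    rmse: float

    def predict(self, dt_s: float | np.ndarray) -> np.ndarray:
        return self.a * np.exp(-self.b * np.asarray(dt_s, dtype=float)) + self.c


def _model(dt, a, b, c):
    return a * np.exp(-b * dt) + c


def _fit_exp(dt: np.ndarray, y: np.ndarray, with_offset: bool) -> ExponentialTailFit:
    """One bounded least-squares fit, trying two deterministic starts (a
    pure-decay log-linear reading and an offset reading anchored at the
    observed tail floor) and keeping the smaller residual."""
    guesses: list[tuple[float, float, float]] = []
    z = np.clip(y, 1e-12, None)
    slope, intercept = np.polyfit(dt, np.log(z), 1)
    guesses.append((float(np.clip(np.exp(intercept), 1e-6, 2.0)), max(-slope, 1e-8), 0.0))
    if with_offset:
        c0 = float(np.clip(y[-1], 0.0, 1.0))
        a0 = max(float(y[0]) - c0, 1e-6)
        zz = y - 0.95 * c0
        pos = zz > 1e-8
        if pos.sum() >= 2:
            s2, _ = np.polyfit(dt[pos], np.log(zz[pos]), 1)
            b0 = max(-s2, 1e-8)
        else:
            b0 = 0.01
        guesses.append((a0, b0, c0))
        bounds = ([0.0, 0.0, -0.5], [2.0, 1.0, 1.5])
    else:
        bounds = ([0.0, 0.0, -1e-12], [2.0, 1.0, 1e-12])

    best: ExponentialTailFit | None = None
    last_err: Exception | None = None
    for p0 in guesses:
        p0 = tuple(np.clip(p0, np.asarray(bounds[0]) + 1e-12, np.asarray(bounds[1]) - 1e-12))
        try:
            popt, _ = curve_fit(
                _model, dt, y, p0=p0, bounds=bounds,
                xtol=1e-15, ftol=1e-15, gtol=1e-15, maxfev=20000,
            )
        except RuntimeError as err:  # non-convergence from this start
            last_err = err
            continue
        rmse = float(np.sqrt(np.mean((_model(dt, *popt) - y) ** 2)))
        if best is None or rmse < best.rmse:
            best = ExponentialTailFit(float(popt[0]), float(popt[1]), float(popt[2]), rmse)
    if best is None:
        raise ImputationError(f"exponential fit failed to converge: {last_err}")
    return best


def fit_exponential_tail(
    trace: NormalizedTrace,
    i_peak: int | None = None,
    with_offset: bool = True,
    min_samples: int = 5,
) -> ExponentialTailFit:
    """Least-squares exponential fit to the observed post-peak samples.

    With ``with_offset`` the plateau offset is fitted only when it is
    identifiable: separating ``a`` from ``c`` requires the decaying component
    to have visibly levelled off inside the observed window (at least one
    e-folding, ``b * span >= 1`` under the pure-decay reading).  On shorter
    windows the three-parameter model degenerates to "small fast transient
    plus constant" and extrapolates flat, so the two-parameter decay is kept.
    When both are identifiable the winner is chosen by AIC.
    """
    if i_peak is None:
        _, i_peak = detect_first_peak(trace)
    dt = trace.time_s[i_peak:] - trace.time_s[i_peak]
    y = trace.intensity[i_peak:]
    if dt.size < min_samples:
        raise InsufficientTailError(
            f"trace {trace.trace_id!r}: only {dt.size} post-peak samples "
            f"(need >= {min_samples})"
        )
    pure = _fit_exp(dt, y, with_offset=False)
    span = float(dt[-1])
    if not with_offset or pure.b * span < 1.0:
        return pure
    offset = _fit_exp(dt, y, with_offset=True)
    n = dt.size

    def aic(fit: ExponentialTailFit, n_params: int) -> float:
        rss = max(n * fit.rmse**2, n * 1e-300)
        return n * float(np.log(rss / n)) + 2 * n_params

    return offset if aic(offset, 3) < aic(pure, 2) else pure


def exp_impute_test(
    trace: NormalizedTrace,
    milestones: MilestoneFeatures,
    horizons_to_fill: Sequence[int] | None = None,
    with_offset: bool = True,
    i_peak: int | None = None,
) -> tuple[MilestoneFeatures, ExponentialTailFit]:
    """Fill missing downslopes of a single curve from its own tail fit.

    ``downslope_N := (a * exp(-b * N) + c - 1) / N`` (the normalized peak is
    1 by construction).  Observed values are never altered.
    """
    fit = fit_exponential_tail(trace, i_peak=i_peak, with_offset=with_offset)
    if horizons_to_fill is None:
        horizons_to_fill = [h for h, p in milestones.provenance.items() if p == MISSING]
    downslopes = dict(milestones.downslopes)
    provenance = dict(milestones.provenance)
    for h in horizons_to_fill:
        if provenance.get(h) == "observed":
            continue
        downslopes[h] = (float(fit.predict(float(h))) - 1.0) / h
        provenance[h] = IMPUTED
    return (
        replace(milestones, downslopes=downslopes, provenance=provenance),
        fit,
    )


# ---------------------------------------------------------------------------
# KNN imputation within a training table
# ---------------------------------------------------------------------------

def knn_impute_train(
    table: pd.DataFrame,
    k: int = 5,
    value_cols: Sequence[str] | None = None,
    id_col: str = "trace_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Complete a training feature table by K-nearest-neighbour imputation.

    Distances are Euclidean on standardized features, restricted per row pair
    to their jointly observed columns (scaled for the missing coordinates).
    Each missing cell becomes the mean of the column over the k nearest rows
    that observe it.  Returns the completed table and a donor log with one
    row per imputed cell.
    """
    numeric_cols = [
        c for c in table.columns
        if c != id_col and pd.api.types.is_numeric_dtype(table[c])
    ]
    if value_cols is None:
        value_cols = [c for c in numeric_cols if table[c].isna().any()]
    for c in value_cols:
        if table[c].isna().all():
            raise ImputationError(f"column {c!r} is entirely missing: nothing to learn from")
    X = table[numeric_cols].to_numpy(dtype=float)
    n_complete = int((~np.isnan(X).any(axis=1)).sum())
    if k >= max(n_complete, 1) and np.isnan(X).any():
        raise ImputationError(f"k={k} must be smaller than the {n_complete} complete rows")

    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    D = nan_euclidean_distances(Xs, Xs)
    np.fill_diagonal(D, np.inf)
    D = np.where(np.isnan(D), np.inf, D)

    completed = table.copy()
    log_rows: list[dict] = []
    ids = table[id_col].astype(str).to_numpy() if id_col in table.columns else np.arange(len(table)).astype(str)
    for col in value_cols:
        j = numeric_cols.index(col)
        observed = ~np.isnan(X[:, j])
        for i in np.nonzero(np.isnan(X[:, j]))[0]:
            donors_mask = observed.copy()
            donors_mask[i] = False
            donor_idx = np.nonzero(donors_mask)[0]
            if donor_idx.size == 0:
                raise ImputationError(f"no donors observe column {col!r}")
            order = donor_idx[np.argsort(D[i, donor_idx], kind="stable")]
            chosen = order[: min(k, order.size)]
            value = float(np.mean(X[chosen, j]))
            completed.iloc[i, completed.columns.get_loc(col)] = value
            prov_col = f"{col}_provenance"
            if prov_col in completed.columns:
                completed.iloc[i, completed.columns.get_loc(prov_col)] = IMPUTED
            log_rows.append(
                {
                    id_col: ids[i],
                    "column": col,
                    "imputed_value": value,
                    "donors": ",".join(ids[chosen]),
                }
            )
    log = pd.DataFrame(log_rows, columns=[id_col, "column", "imputed_value", "donors"])
    return completed, log
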