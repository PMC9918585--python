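"""The seven affect-dynamics measures.

For one person's time-ordered affect record x_1..x_n these are:

* trait affect — the mean M = Σx_i / n;
* affect variability — the within-person standard deviation
  SD = sqrt(Σ(x_i − M)² / n) (population divisor), and its mean-corrected
  relative form rel_SD = SD / sqrt((M − l)(u − M)) for a scale bounded in
  [l, u], which removes the mechanical coupling between mean and maximal
  attainable spread on a bounded slider;
* affect instability — RMSSD = sqrt(Σ(x_i − x_{i+1})² / (n − 1)),
  the Teager–Kaiser energy operator
  TKEO = Σ(x_i² − x_{i−1}·x_{i+1}) / (n − 2), and the probability of acute
  change PAC = #{|x_{i+1} − x_i| > d90} / (n − 1), where d90 is the 90th
  percentile of absolute successive changes pooled over all persons in the
  sample;
* affect inertia — the lag-1 autocorrelation
  AR1 = Σ(x_i − M)(x_{i+1} − M) / Σ(x_i − M)².

All instability/inertia measures are order-based: any adjacent pair of
retained observations counts as successive regardless of the elapsed time
between them (overnight and multi-day gaps included).

Undefined results (series too short is an error; zero-variance AR1 and the
0/0 relative-SD corner are NaN) follow the conventions in
:mod:`esmpower.core`.  Row-wise kernels (``*_rows``) evaluate a measure
along axis 1 of a (replicates × n) matrix and power the Monte-Carlo
engines.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_BOUNDS,
    ESMDataset,
    InsufficientDataError,
    MEASURE_NAMES,
    MeasureSet,
    PACThreshold,
    PersonSeries,
)

__all__ = [
    "mean_affect",
    "sd_affect",
    "rel_sd",
    "rmssd",
    "tkeo",
    "pac",
    "ar1",
    "compute_d90",
    "compute_all",
    "measures_frame",
    "MIN_N",
    "measure_rows",
]

#: Minimum series length at which each measure is defined.
MIN_N = {"mean": 1, "sd": 2, "rel_sd": 2, "rmssd": 2, "tkeo": 3, "pac": 2, "ar1": 3}


def _values(series) -> np.ndarray:
    if isinstance(series, PersonSeries):
        return series.values
    return np.asarray(series, dtype=float)


def mean_affect(series) -> float:
    """Trait affect: the within-person mean."""
    x = _values(series)
    if len(x) < 1:
        raise InsufficientDataError("mean requires at least 1 observation")
    return float(np.mean(x))


def sd_affect(series, ddof: int = 0) -> float:
    """Affect variability: within-person standard deviation.

    The population divisor n (``ddof=0``) is the default; ``ddof=1`` gives
    the sample version.
    """
    x = _values(series)
    if len(x) < 2:
        raise InsufficientDataError("sd requires at least 2 observations")
    return float(np.std(x, ddof=ddof))


def rel_sd(series, bounds: tuple[float, float] = DEFAULT_BOUNDS, ddof: int = 0) -> float:
    """Mean-corrected relative standard deviation for a bounded scale.

    SD divided by the maximum standard deviation attainable at the observed
    mean, sqrt((M − lower)(upper − M)) (population form, independent of n).
    A constant series at a scale bound is the 0/0 corner and returns NaN.
    """
    x = _values(series)
    if len(x) < 2:
        raise InsufficientDataError("rel_sd requires at least 2 observations")
    lo, hi = bounds
    m = float(np.mean(x))
    s = float(np.std(x, ddof=ddof))
    max_sd = math.sqrt(max((m - lo) * (hi - m), 0.0))
    if max_sd == 0.0:
        if s > 0.0:  # mean at a bound forces all values to that bound
            raise AssertionError("positive SD with mean at a scale bound")
        return math.nan
    return s / max_sd


def rmssd(series) -> float:
    """Affect instability: root mean square of successive differences."""
    x = _values(series)
    if len(x) < 2:
        raise InsufficientDataError("rmssd requires at least 2 observations")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d * d)))


def tkeo(series) -> float:
    """Affect instability: mean Teager–Kaiser energy, Σ(x_i² − x_{i−1}x_{i+1})/(n−2).

    Sensitive to spikes: a single large excursion between two calm reports
    contributes a large positive term.
    """
    x = _values(series)
    if len(x) < 3:
        raise InsufficientDataError("tkeo requires at least 3 observations")
    return float(np.mean(x[1:-1] * x[1:-1] - x[:-2] * x[2:]))


def pac(series, threshold: PACThreshold | float) -> float:
    """Probability of acute change: share of successive changes exceeding d90."""
    x = _values(series)
    if len(x) < 2:
        raise InsufficientDataError("pac requires at least 2 observations")
    d90 = threshold.d90 if isinstance(threshold, PACThreshold) else float(threshold)
    return float(np.mean(np.abs(np.diff(x)) > d90))


def ar1(series) -> float:
    """Affect inertia: lag-1 autocorrelation about the series mean.

    Σ(x_i − M)(x_{i+1} − M) / Σ(x_i − M)² over the full-series denominator;
    a constant series (zero variance) returns NaN.
    """
    x = _values(series)
    if len(x) < 3:
        raise InsufficientDataError("ar1 requires at least 3 observations")
    c = x - np.mean(x)
    denom = float(np.sum(c * c))
    if denom == 0.0:
        return math.nan
    return float(np.sum(c[:-1] * c[1:]) / denom)


def compute_d90(
    dataset: ESMDataset | Mapping[str, np.ndarray],
    q: float = 90.0,
    method: str = "linear",
) -> PACThreshold:
    """Pool absolute successive changes across all persons and take their q-th percentile.

    ``method`` is any percentile interpolation accepted by
    :func:`numpy.percentile`; linear interpolation between order statistics
    is the default.
    """
    if isinstance(dataset, ESMDataset):
        arrays = [s.values for s in dataset]
    else:
        arrays = [np.asarray(v, dtype=float) for v in dataset.values()]
    diffs = [np.abs(np.diff(a)) for a in arrays if len(a) >= 2]
    if not diffs:
        raise InsufficientDataError("no successive differences in dataset")
    pooled = np.concatenate(diffs)
    if len(pooled) < 10:
        raise InsufficientDataError(
            f"need >= 10 pooled successive differences, got {len(pooled)}"
        )
    return PACThreshold(float(np.percentile(pooled, q, method=method)), len(pooled))


def compute_all(
    dataset: ESMDataset,
    threshold: PACThreshold | None = None,
    ddof: int = 0,
) -> dict[str, MeasureSet]:
    """All seven measures for every person in the dataset.

    PAC uses a single dataset-level d90 (recomputed here unless a fixed
    ``threshold`` is supplied).  A person too short for a given measure gets
    NaN for that measure; no person is dropped.
    """
    if threshold is None:
        threshold = compute_d90(dataset)
    out: dict[str, MeasureSet] = {}
    for s in dataset:
        n = len(s)
        out[s.person_id] = MeasureSet(
            mean=mean_affect(s) if n >= 1 else math.nan,
            sd=sd_affect(s, ddof=ddof) if n >= 2 else math.nan,
            rel_sd=rel_sd(s, dataset.bounds, ddof=ddof) if n >= 2 else math.nan,
            rmssd=rmssd(s) if n >= 2 else math.nan,
            tkeo=tkeo(s) if n >= 3 else math.nan,
            pac=pac(s, threshold) if n >= 2 else math.nan,
            ar1=ar1(s) if n >= 3 else math.nan,
        )
    return out


def measures_frame(measures: Mapping[str, MeasureSet]) -> pd.DataFrame:
    """Tabular view: one row per person, one column per measure."""
    df = pd.DataFrame(
        [{"person_id": pid, **ms.as_dict()} for pid, ms in measures.items()],
        columns=["person_id", *MEASURE_NAMES],
    )
    return df


# ---------------------------------------------------------------------------
# Row-wise kernels: evaluate a measure along axis 1 of a (replicates, n)
# matrix in one vectorized pass.  The Monte-Carlo engines (accuracy, power)
# rely on these; tests pin them against the scalar functions above.


def _rows_mean(x: np.ndarray) -> np.ndarray:
    return x.mean(axis=1)


def _rows_sd(x: np.ndarray) -> np.ndarray:
    return x.std(axis=1, ddof=0)


def _rows_rel_sd(x: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    lo, hi = bounds
    m = x.mean(axis=1)
    s = x.std(axis=1, ddof=0)
    max_sd = np.sqrt(np.clip((m - lo) * (hi - m), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(max_sd > 0, s / np.where(max_sd > 0, max_sd, 1.0), np.nan)
    return out


def _rows_rmssd(x: np.ndarray) -> np.ndarray:
    d = np.diff(x, axis=1)
    return np.sqrt(np.mean(d * d, axis=1))


def _rows_tkeo(x: np.ndarray) -> np.ndarray:
    return np.mean(x[:, 1:-1] ** 2 - x[:, :-2] * x[:, 2:], axis=1)


def _rows_pac(x: np.ndarray, d90) -> np.ndarray:
    # d90 may be a scalar or one threshold per row
    d = np.abs(np.diff(x, axis=1))
    thr = np.asarray(d90, dtype=float)
    if thr.ndim == 1:
        thr = thr[:, None]
    return np.mean(d > thr, axis=1)


def _rows_ar1(x: np.ndarray) -> np.ndarray:
    c = x - x.mean(axis=1, keepdims=True)
    denom = np.sum(c * c, axis=1)
    num = np.sum(c[:, :-1] * c[:, 1:], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)


def measure_rows(
    x: np.ndarray,
    measure: str,
    *,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    d90: float | np.ndarray | None = None,
) -> np.ndarray:
    """Evaluate ``measure`` on each row of a (replicates, n) value matrix.

    Rows must already be in temporal order.  ``pac`` requires ``d90`` —
    either one pooled threshold or one per row.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-d (replicates, n) matrix")
    n = x.shape[1]
    if n < MIN_N[measure]:
        raise InsufficientDataError(
            f"{measure} requires n >= {MIN_N[measure]}, got {n}"
        )
    if measure == "mean":
        return _rows_mean(x)
    if measure == "sd":
        return _rows_sd(x)
    if measure == "rel_sd":
        return _rows_rel_sd(x, bounds)
    if measure == "rmssd":
        return _rows_rmssd(x)
    if measure == "tkeo":
        return _rows_tkeo(x)
    if measure == "pac":
        if d90 is None:
            raise ValueError("pac requires a d90 threshold")
        return _rows_pac(x, d90)
    if measure == "ar1":
        return _rows_ar1(x)
    raise ValueError(f"unknown measure {measure!r}")
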