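"""Estimation accuracy of affect-dynamics measures under subsampling.

The question answered here: how many reports per person does a study need
before a measure computed on that subset is close to the person's "true"
value?  Truth is defined as the measure computed on the person's complete
record (everyone kept has at least 50 reports by default).  For a given
sampling strategy and number of observations n, each person's estimation
error is the root mean square error (RMSE) of the subsample estimates
against their truth — over many independent re-draws for stochastic
strategies, or the single absolute error for the deterministic close and
distant selections.  Person-level RMSEs are averaged into one curve point
per n, with a percentile-bootstrap confidence interval over persons.

Accuracy is judged against between-person benchmarks: an average RMSE equal
to one between-person standard deviation of the true measure means the
typical within-person estimation error is as large as the population spread
of the quantity being estimated; 0.5 and 0.3 SD are the stricter yardsticks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ESMDataset, InsufficientDataError, MeasureSet, PersonSeries
from .measures import MIN_N, compute_all, compute_d90, measure_rows
from .sampling import (
    SamplingPlan,
    apply_filter,
    close_subsample,
    distant_subsample,
    eligible_persons,
)

__all__ = [
    "AccuracyCurve",
    "BenchmarkThresholds",
    "true_measures",
    "person_rmse",
    "rmse_curve",
    "bootstrap_ci",
    "benchmark_thresholds",
    "min_n_for_accuracy",
    "curves_frame",
]

#: Multipliers of the between-person SD used as accuracy benchmarks.
BENCHMARK_MULTIPLIERS = (1.0, 0.5, 0.3)


@dataclass(frozen=True)
class AccuracyCurve:
    """One point of an accuracy curve: mean RMSE at a given n under a strategy."""

    measure: str
    strategy: str
    n_obs: int
    mean_rmse: float
    ci_lower: float
    ci_upper: float
    n_persons: int
    replicates: int
    window: str | None = None
    days: str | None = None

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.mean_rmse <= self.ci_upper):
            raise ValueError(
                f"CI ({self.ci_lower}, {self.ci_upper}) does not bracket "
                f"mean RMSE {self.mean_rmse}"
            )


@dataclass(frozen=True)
class BenchmarkThresholds:
    """Between-person SD of the true measure and its benchmark multiples."""

    measure: str
    between_person_sd: float
    thresholds: tuple[float, ...]


def true_measures(
    dataset: ESMDataset, min_reports: int = 50
) -> dict[str, MeasureSet]:
    """All seven measures from each person's complete record.

    Persons below the ``min_reports`` cut are excluded (the study's
    inclusion rule; set to 1 to keep everyone).
    """
    keep = {pid: s for pid, s in dataset.persons.items() if len(s) >= min_reports}
    if not keep:
        raise InsufficientDataError(
            f"no person has >= {min_reports} reports"
        )
    return compute_all(ESMDataset(keep, dataset.bounds))


def _random_estimates(
    values: np.ndarray,
    n: int,
    replicates: int,
    rng: np.random.Generator,
    measure: str,
    *,
    bounds: tuple[float, float],
    d90: float | np.ndarray | None = None,
    return_matrix: bool = False,
):
    """Measure estimates from ``replicates`` random n-subsets of one record."""
    L = len(values)
    u = rng.random((replicates, L))
    idx = np.sort(np.argpartition(u, n - 1, axis=1)[:, :n], axis=1)
    sub = values[idx]
    if return_matrix:
        return sub
    return measure_rows(sub, measure, bounds=bounds, d90=d90)


def person_rmse(
    series: PersonSeries,
    measure: str,
    plan: SamplingPlan,
    truth: float,
    rng: np.random.Generator | None = None,
    *,
    d90: float | None = None,
    bounds: tuple[float, float] = (0.0, 100.0),
    bias_shift: float = 0.0,
) -> float:
    """RMSE of subsample estimates of one measure against the person's truth.

    Stochastic strategies re-draw ``plan.replicates`` subsets; close/distant
    yield a single deterministic estimate whose RMSE is its absolute error.
    ``bias_shift`` is added to every estimate before comparison (time-window
    fixed-effect correction).  PAC here uses a fixed ``d90``; recomputing
    d90 per subsampled dataset is a dataset-level operation handled by
    :func:`rmse_curve`.
    """
    n = plan.n_obs
    if measure == "pac" and d90 is None:
        raise ValueError("pac requires a d90 threshold")
    src = apply_filter(series, plan.window, plan.days)
    if src is None or len(src) < n:
        raise InsufficientDataError(
            f"person {series.person_id!r} infeasible for {plan.strategy} at n={n}"
        )
    if plan.strategy == "close":
        est = np.array(
            [measure_rows(close_subsample(src, n).values[None, :], measure,
                          bounds=bounds, d90=d90)[0]]
        )
    elif plan.strategy == "distant":
        est = np.array(
            [measure_rows(distant_subsample(src, n).values[None, :], measure,
                          bounds=bounds, d90=d90)[0]]
        )
    else:
        if rng is None:
            rng = np.random.default_rng(plan.seed)
        est = _random_estimates(
            src.values, n, plan.replicates, rng, measure, bounds=bounds, d90=d90
        )
    err = est + bias_shift - truth
    return float(np.sqrt(np.nanmean(err * err)))


def bootstrap_ci(
    values: Sequence[float],
    reps: int = 2000,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean of ``values``."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise InsufficientDataError("bootstrap_ci needs at least 2 values")
    if rng is None:
        rng = np.random.default_rng()
    idx = rng.integers(0, len(x), size=(reps, len(x)))
    means = x[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(means, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def rmse_curve(
    dataset: ESMDataset,
    measure: str,
    strategy: str,
    n_range: Iterable[int] = range(3, 31),
    replicates: int = 1000,
    rng: np.random.Generator | None = None,
    *,
    window: str | None = None,
    days: str | None = None,
    min_reports_truth: int = 50,
    min_reports_window: int = 30,
    debias_correction: bool = True,
    pac_threshold_mode: str = "recompute",
    bootstrap_reps: int = 2000,
    ci_level: float = 0.95,
) -> list[AccuracyCurve]:
    """Mean-over-persons RMSE of one measure for each n under one strategy.

    Truth is the full-record value per person (full-sample d90 for PAC).
    For ``time_window``/``day_filter`` the subsample is drawn from the
    filtered record, eligibility requires ``min_reports_window`` surviving
    reports, and (if ``debias_correction``) estimates are shifted so their
    population mean over full window records matches the full-record
    population mean.  ``pac_threshold_mode`` controls whether d90 is
    recomputed from each subsampled dataset (default) or held fixed at the
    full-sample value.  Persons infeasible at a given n are excluded from
    that cell only; empty cells are omitted.
    """
    if rng is None:
        rng = np.random.default_rng()
    ds = ESMDataset(
        {pid: s for pid, s in dataset.persons.items() if len(s) >= min_reports_truth},
        dataset.bounds,
    )
    if strategy in ("time_window", "day_filter"):
        ds = eligible_persons(ds, window, days, min_reports_window)
    if len(ds) == 0:
        return []
    truth_d90 = compute_d90(ds).d90 if measure == "pac" else None
    truths_all = compute_all(ds, threshold=None)
    truths = {
        pid: ms[measure]
        for pid, ms in truths_all.items()
        if not math.isnan(ms[measure])
    }
    # time-window fixed-effect shift: population mean of full-record truths
    # minus population mean of full window-restricted estimates
    bias_shift = 0.0
    if debias_correction and strategy in ("time_window", "day_filter"):
        window_full = {}
        for pid in truths:
            f = apply_filter(ds[pid], window, days)
            if f is not None and len(f) >= MIN_N[measure]:
                window_full[pid] = float(
                    measure_rows(
                        f.values[None, :], measure, bounds=ds.bounds, d90=truth_d90
                    )[0]
                )
        common = [p for p in truths if p in window_full and
                  not math.isnan(window_full[p])]
        if common:
            bias_shift = float(
                np.mean([truths[p] for p in common])
                - np.mean([window_full[p] for p in common])
            )
    deterministic = strategy in ("close", "distant")
    reps = 1 if deterministic else replicates
    curves: list[AccuracyCurve] = []
    for n in n_range:
        if n < MIN_N[measure]:
            continue
        est_rows: dict[str, np.ndarray] = {}  # person -> (reps, n) value matrix
        for pid in truths:
            src = ds[pid] if deterministic else apply_filter(ds[pid], window, days)
            if src is None or len(src) < n:
                continue
            if strategy == "close":
                try:
                    sub = close_subsample(src, n).values[None, :]
                except InsufficientDataError:
                    continue
            elif strategy == "distant":
                sub = distant_subsample(src, n).values[None, :]
            else:
                sub = _random_estimates(
                    src.values, n, reps, rng, measure,
                    bounds=ds.bounds, return_matrix=True,
                )
            est_rows[pid] = sub
        if len(est_rows) < 2:
            continue
        if measure == "pac" and pac_threshold_mode == "recompute":
            # pool |successive differences| across persons within each
            # replicate's subsampled dataset, one d90 per replicate
            pooled = np.concatenate(
                [np.abs(np.diff(m, axis=1)) for m in est_rows.values()], axis=1
            )
            d90_r = np.percentile(pooled, 90, axis=1)
            estimates = {
                pid: measure_rows(m, "pac", d90=d90_r)
                for pid, m in est_rows.items()
            }
        else:
            estimates = {
                pid: measure_rows(m, measure, bounds=ds.bounds, d90=truth_d90)
                for pid, m in est_rows.items()
            }
        person_rmses = []
        for pid, est in estimates.items():
            err = est + bias_shift - truths[pid]
            ok = ~np.isnan(err)
            if not ok.any():
                continue
            person_rmses.append(float(np.sqrt(np.mean(err[ok] ** 2))))
        if len(person_rmses) < 2:
            continue
        mean_rmse = float(np.mean(person_rmses))
        lo, hi = bootstrap_ci(person_rmses, reps=bootstrap_reps, rng=rng)
        curves.append(
            AccuracyCurve(
                measure=measure,
                strategy=strategy,
                n_obs=int(n),
                mean_rmse=mean_rmse,
                ci_lower=min(lo, mean_rmse),
                ci_upper=max(hi, mean_rmse),
                n_persons=len(person_rmses),
                replicates=reps,
                window=window,
                days=days,
            )
        )
    return curves


def benchmark_thresholds(
    truths: Mapping[str, MeasureSet],
    multipliers: tuple[float, ...] = BENCHMARK_MULTIPLIERS,
) -> list[BenchmarkThresholds]:
    """Between-person SD of each true measure, with benchmark multiples.

    Persons with an undefined value of a measure are dropped pairwise for
    that measure; measures defined for fewer than two persons are omitted.
    """
    out = []
    from .core import MEASURE_NAMES

    for m in MEASURE_NAMES:
        vals = np.array(
            [ms[m] for ms in truths.values() if not math.isnan(ms[m])]
        )
        if len(vals) < 2:
            continue
        sd = float(np.std(vals, ddof=0))
        out.append(
            BenchmarkThresholds(m, sd, tuple(k * sd for k in multipliers))
        )
    return out


def min_n_for_accuracy(
    curves: Sequence[AccuracyCurve], threshold: float
) -> int | None:
    """Smallest n whose mean RMSE is at or below ``threshold``; None if never."""
    if not curves:
        raise ValueError("no curves supplied")
    for c in sorted(curves, key=lambda c: c.n_obs):
        if c.mean_rmse <= threshold:
            return c.n_obs
    return None


def curves_frame(curves: Sequence[AccuracyCurve]) -> pd.DataFrame:
    """Accuracy curves as a tidy table for CSV export."""
    cols = [
        "measure", "strategy", "window", "days", "n_obs",
        "mean_rmse", "ci_lower", "ci_upper", "n_persons", "replicates",
    ]
    return pd.DataFrame(
        [{k: getattr(c, k) for k in cols} for c in curves], columns=cols
    )
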