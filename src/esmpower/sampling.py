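"""Sampling strategies for subsetting ESM records.

Five strategies are compared when estimating a person's affect dynamics
from fewer reports than they actually provided:

* ``random`` — n reports drawn uniformly without replacement;
* ``close`` — the n consecutive reports spanning the shortest time,
  requiring every adjacent gap within the run to be at most 24 h;
* ``distant`` — the n reports closest to an equally spaced grid laid over
  the person's first-to-last observation window;
* ``time_window`` — only reports from one of four clock-time windows
  (morning 06–12, afternoon 12–16, evening 16–20, night 20–06), then
  random subsampling within the window;
* ``day_filter`` — only weekday (Mon–Fri) or weekend (Sat–Sun) reports,
  then random subsampling.

Close and distant selection are deterministic — each person has exactly one
such subset per n.  Window/day conditions carry an eligibility rule (at
least 30 surviving reports by default) and an additive bias correction that
removes time-window fixed effects: the population-mean difference between
full-record estimates and window-restricted full estimates is added to
every estimate, leaving the between-person ordering untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core import ESMDataset, InsufficientDataError, PersonSeries, ValidationError

__all__ = [
    "STRATEGIES",
    "TIME_WINDOWS",
    "DAY_FILTERS",
    "SamplingPlan",
    "random_subsample",
    "close_subsample",
    "distant_subsample",
    "filter_time_window",
    "filter_days",
    "apply_filter",
    "eligible_persons",
    "debias",
]

STRATEGIES = ("random", "close", "distant", "time_window", "day_filter")

#: Half-open [start, end) clock-hour windows; together they partition the day.
TIME_WINDOWS = {
    "morning": (6, 12),
    "afternoon": (12, 16),
    "evening": (16, 20),
    "night": (20, 6),  # wraps midnight
}

DAY_FILTERS = ("weekday", "weekend")

_MAX_CLOSE_GAP_H = 24.0


@dataclass(frozen=True)
class SamplingPlan:
    """A sampling strategy with its parameters.

    ``replicates`` is the number of independent re-draws for the stochastic
    strategies; the deterministic close/distant strategies are forced to a
    single replicate.
    """

    strategy: str
    n_obs: int
    window: str | None = None
    days: str | None = None
    replicates: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValidationError(f"unknown strategy {self.strategy!r}")
        if self.n_obs < 3:
            raise ValidationError(f"n_obs must be >= 3, got {self.n_obs}")
        if (self.window is not None) != (self.strategy == "time_window"):
            raise ValidationError("window must be set iff strategy is time_window")
        if (self.days is not None) != (self.strategy == "day_filter"):
            raise ValidationError("days must be set iff strategy is day_filter")
        if self.window is not None and self.window not in TIME_WINDOWS:
            raise ValidationError(f"unknown time window {self.window!r}")
        if self.days is not None and self.days not in DAY_FILTERS:
            raise ValidationError(f"unknown day filter {self.days!r}")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.strategy in ("close", "distant"):
            object.__setattr__(self, "replicates", 1)

    @property
    def deterministic(self) -> bool:
        return self.strategy in ("close", "distant")


def random_subsample(
    series: PersonSeries, n: int, rng: np.random.Generator
) -> PersonSeries:
    """Draw n reports uniformly without replacement, returned in time order."""
    if n > len(series):
        raise InsufficientDataError(
            f"person {series.person_id!r}: requested {n} of {len(series)} reports"
        )
    idx = rng.choice(len(series), size=n, replace=False)
    return series.take(idx)


def close_subsample(series: PersonSeries, n: int) -> PersonSeries:
    """The n consecutive reports collected within the shortest time span.

    Candidate windows are contiguous runs of n reports whose every adjacent
    gap is at most 24 h; among qualifying windows the one with the smallest
    first-to-last span wins, earliest window on ties.
    """
    m = len(series)
    if n > m:
        raise InsufficientDataError(
            f"person {series.person_id!r}: requested {n} of {m} reports"
        )
    t = series.times.astype("int64").astype(float)  # seconds
    gaps = np.diff(t)
    max_gap = _MAX_CLOSE_GAP_H * 3600.0
    best_start = -1
    best_span = np.inf
    # windows [j, j+n-1]; valid iff no internal gap exceeds 24 h
    ok = gaps <= max_gap
    for j in range(m - n + 1):
        if n > 1 and not ok[j : j + n - 1].all():
            continue
        span = t[j + n - 1] - t[j]
        if span < best_span:  # strict: ties keep the earliest window
            best_span = span
            best_start = j
    if best_start < 0:
        raise InsufficientDataError(
            f"person {series.person_id!r}: no run of {n} consecutive reports "
            f"with all gaps <= 24 h"
        )
    return series.take(np.arange(best_start, best_start + n))


def distant_subsample(series: PersonSeries, n: int, mode: str = "optimal") -> PersonSeries:
    """The n reports closest to an equally spaced first-to-last grid.

    Grid instants g_k = t_first + k·(t_last − t_first)/(n − 1).  In
    ``optimal`` mode a dynamic program picks the order-preserving set of n
    distinct reports minimising Σ|t(chosen_k) − g_k|, preferring earlier
    reports on ties; ``greedy`` assigns each grid point its nearest unused
    report left to right.
    """
    m = len(series)
    if n < 2:
        raise InsufficientDataError("distant sampling requires n >= 2")
    if n > m:
        raise InsufficientDataError(
            f"person {series.person_id!r}: requested {n} of {m} reports"
        )
    t = series.times.astype("int64").astype(float)
    grid = np.linspace(t[0], t[-1], n)
    cost = np.abs(t[None, :] - grid[:, None])  # (n, m)
    if mode == "greedy":
        chosen: list[int] = []
        prev = -1
        for k in range(n):
            # nearest unused report after prev, but leave room for the rest
            lo, hi = prev + 1, m - (n - k) + 1
            j = lo + int(np.argmin(cost[k, lo:hi]))
            chosen.append(j)
            prev = j
        return series.take(np.array(chosen))
    if mode != "optimal":
        raise ValidationError(f"unknown distant mode {mode!r}")
    # Suffix DP: best[k][i] = min cost assigning grid points k..n-1 to
    # reports with chosen_k = i and subsequent choices strictly after i.
    best = np.full((n, m), np.inf)
    best[n - 1] = cost[n - 1]
    for k in range(n - 2, -1, -1):
        # suffix minimum of best[k+1] over j > i
        suffix = np.minimum.accumulate(best[k + 1][::-1])[::-1]
        best[k, : m - 1] = cost[k, : m - 1] + suffix[1:]
    # forward greedy reconstruction: earliest index achieving the optimum at
    # each step gives the lexicographically smallest (earliest-report) set
    chosen = []
    prev = -1
    remaining = float(np.min(best[0]))
    for k in range(n):
        for i in range(prev + 1, m - (n - 1 - k)):
            if k == n - 1:
                tail = 0.0
            else:
                tail = float(np.min(best[k + 1, i + 1 :]))
            if np.isclose(cost[k, i] + tail, remaining, rtol=0, atol=1e-6):
                chosen.append(i)
                prev = i
                remaining = tail
                break
        else:  # pragma: no cover - DP guarantees a path
            raise AssertionError("distant assignment reconstruction failed")
    return series.take(np.array(chosen))


def _window_mask(series: PersonSeries, window: str) -> np.ndarray:
    start, end = TIME_WINDOWS[window]
    # seconds since midnight, local clock
    day = series.times.astype("datetime64[D]")
    secs = (series.times - day).astype("timedelta64[s]").astype(float)
    h = secs / 3600.0
    if start < end:
        return (h >= start) & (h < end)
    return (h >= start) | (h < end)  # night wraps midnight


def filter_time_window(series: PersonSeries, window: str) -> PersonSeries | None:
    """Keep reports whose local clock time falls in the named window.

    Windows are half-open so 12:00 is afternoon, not morning; night wraps
    midnight.  Returns None when no report survives.
    """
    if window not in TIME_WINDOWS:
        raise ValidationError(f"unknown time window {window!r}")
    mask = _window_mask(series, window)
    if not mask.any():
        return None
    return series.take(np.flatnonzero(mask))


def filter_days(series: PersonSeries, days: str) -> PersonSeries | None:
    """Keep weekday (Mon–Fri) or weekend (Sat–Sun) reports; None if empty."""
    if days not in DAY_FILTERS:
        raise ValidationError(f"unknown day filter {days!r}")
    # numpy epoch 1970-01-01 was a Thursday -> weekday index (Mon=0)
    dow = (series.times.astype("datetime64[D]").astype("int64") + 3) % 7
    mask = dow >= 5 if days == "weekend" else dow < 5
    if not mask.any():
        return None
    return series.take(np.flatnonzero(mask))


def apply_filter(
    series: PersonSeries, window: str | None = None, days: str | None = None
) -> PersonSeries | None:
    """Apply a time-window or day filter (at most one may be set)."""
    if window is not None and days is not None:
        raise ValidationError("set either window or days, not both")
    if window is not None:
        return filter_time_window(series, window)
    if days is not None:
        return filter_days(series, days)
    return series


def eligible_persons(
    dataset: ESMDataset,
    window: str | None = None,
    days: str | None = None,
    min_reports: int = 30,
) -> ESMDataset:
    """Persons with at least ``min_reports`` reports surviving the filter.

    Returned series keep their *full* records; the filter is only the
    eligibility test here (condition-specific estimation re-applies it).
    """
    keep = {}
    for s in dataset:
        f = apply_filter(s, window, days)
        if f is not None and len(f) >= min_reports:
            keep[s.person_id] = s
    return ESMDataset(keep, dataset.bounds)


def debias(
    window_estimates: Mapping[str, float],
    window_pop_mean_full: float,
    full_pop_mean: float,
) -> dict[str, float]:
    """Additive bias correction for time-window fixed effects.

    Every window-restricted estimate is shifted by
    (full_pop_mean − window_pop_mean_full): the population mean of the
    measure over all records minus its population mean over window-restricted
    records, both computed on the same eligible persons.  After correction
    the corrected window-full estimates average exactly to full_pop_mean,
    and person ranks are untouched.
    """
    shift = full_pop_mean - window_pop_mean_full
    return {pid: est + shift for pid, est in window_estimates.items()}
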