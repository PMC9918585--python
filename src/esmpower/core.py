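"""Domain types and long-format ESM data I/O.

An experience-sampling (ESM) dataset is a collection of per-person affect
time series: each report is a timestamped value on a bounded slider scale
(0-100 by default).  Timestamps are timezone-naive local clock time, since
all time-of-day windowing (morning/afternoon/evening/night) is defined on
the local clock.

On disk the canonical format is a long CSV with header columns
``person_id,timestamp,affect`` and ISO-8601 timestamps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "InsufficientDataError",
    "PersonSeries",
    "ESMDataset",
    "MeasureSet",
    "PACThreshold",
    "MEASURE_NAMES",
    "read_esm_csv",
    "write_esm_csv",
    "write_table",
]

#: Canonical measure order: trait, variability (2), instability (3), inertia.
MEASURE_NAMES = ("mean", "sd", "rel_sd", "rmssd", "tkeo", "pac", "ar1")

DEFAULT_BOUNDS = (0.0, 100.0)


class ValidationError(ValueError):
    """Input violates a dataset invariant (bounds, ordering, duplicates)."""


class InsufficientDataError(ValueError):
    """A series is too short for the requested operation."""


@dataclass(frozen=True)
class PersonSeries:
    """One person's time-ordered affect record.

    Parameters
    ----------
    person_id
        Opaque identifier, unique within a dataset.
    times
        ``numpy.datetime64`` array, strictly increasing.
    values
        Affect scores aligned with ``times``.
    """

    person_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype="datetime64[s]")
        values = np.asarray(self.values, dtype=float)
        if times.shape != values.shape or times.ndim != 1:
            raise ValidationError(
                f"person {self.person_id!r}: times and values must be "
                f"aligned 1-d arrays, got {times.shape} vs {values.shape}"
            )
        if len(times) == 0:
            raise ValidationError(f"person {self.person_id!r}: empty series")
        if len(times) > 1:
            dt = np.diff(times.astype("int64"))
            if np.any(dt <= 0):
                bad = int(np.argmax(dt <= 0)) + 1
                raise ValidationError(
                    f"person {self.person_id!r}: timestamps not strictly "
                    f"increasing at position {bad} ({times[bad]})"
                )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n(self) -> int:
        return len(self.values)

    def take(self, indices: np.ndarray) -> "PersonSeries":
        """Subset by (sorted, unique) positional indices, keeping time order."""
        idx = np.sort(np.asarray(indices, dtype=int))
        return PersonSeries(self.person_id, self.times[idx], self.values[idx])


@dataclass(frozen=True)
class ESMDataset:
    """A collection of person series sharing one bounded affect scale."""

    persons: Mapping[str, PersonSeries]
    bounds: tuple[float, float] = DEFAULT_BOUNDS

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not lo < hi:
            raise ValidationError(f"bounds must satisfy lower < upper, got {self.bounds}")
        for pid, series in self.persons.items():
            if pid != series.person_id:
                raise ValidationError(
                    f"key {pid!r} does not match series person_id {series.person_id!r}"
                )
            v = series.values
            if np.any(v < lo) or np.any(v > hi):
                bad = float(v[(v < lo) | (v > hi)][0])
                raise ValidationError(
                    f"person {pid!r}: affect value {bad} outside bounds {self.bounds}"
                )

    def __len__(self) -> int:
        return len(self.persons)

    def __iter__(self) -> Iterator[PersonSeries]:
        return iter(self.persons.values())

    def __getitem__(self, person_id: str) -> PersonSeries:
        return self.persons[person_id]

    @property
    def person_ids(self) -> list[str]:
        return list(self.persons)

    @classmethod
    def from_series(
        cls, series: Iterable[PersonSeries], bounds: tuple[float, float] = DEFAULT_BOUNDS
    ) -> "ESMDataset":
        persons: dict[str, PersonSeries] = {}
        for s in series:
            if s.person_id in persons:
                raise ValidationError(f"duplicate person_id {s.person_id!r}")
            persons[s.person_id] = s
        return cls(persons, bounds)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view with columns person_id, timestamp, affect."""
        frames = [
            pd.DataFrame(
                {
                    "person_id": s.person_id,
                    "timestamp": s.times,
                    "affect": s.values,
                }
            )
            for s in self
        ]
        if not frames:
            return pd.DataFrame(columns=["person_id", "timestamp", "affect"])
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class MeasureSet:
    """The seven affect-dynamics statistics for one person.

    Undefined values (series too short, zero variance for ar1, mean at a
    scale bound for rel_sd) are NaN — an explicit missing marker, never 0.
    """

    mean: float = math.nan
    sd: float = math.nan
    rel_sd: float = math.nan
    rmssd: float = math.nan
    tkeo: float = math.nan
    pac: float = math.nan
    ar1: float = math.nan

    def __getitem__(self, name: str) -> float:
        if name not in MEASURE_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in MEASURE_NAMES}


@dataclass(frozen=True)
class PACThreshold:
    """90th-percentile threshold for the probability of acute change.

    ``d90`` is the 90th percentile of absolute successive affect changes
    pooled over every person's within-person successive pairs; ``n_diffs``
    is how many differences were pooled.
    """

    d90: float
    n_diffs: int

    def __post_init__(self) -> None:
        if self.d90 < 0:
            raise ValidationError(f"d90 must be >= 0, got {self.d90}")
        if self.n_diffs < 1:
            raise ValidationError("n_diffs must be positive")


# ---------------------------------------------------------------------------
# I/O


def read_esm_csv(
    path, bounds: tuple[float, float] = DEFAULT_BOUNDS
) -> ESMDataset:
    """Read a long-format ESM CSV into a validated :class:`ESMDataset`.

    The file must have header columns ``person_id,timestamp,affect`` with
    ISO-8601 timestamps.  Rows are sorted by (person_id, timestamp); within
    a person, duplicate timestamps are rejected (the sampling app enforces
    at least one hour between reports) as are out-of-bounds affect values.
    """
    df = pd.read_csv(path, dtype={"person_id": str})
    missing = {"person_id", "timestamp", "affect"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: unparseable timestamp ({exc})") from exc
    affect = pd.to_numeric(df["affect"], errors="coerce")
    if affect.isna().any():
        line = int(affect.index[affect.isna()][0]) + 2  # header + 1-based
        raise ValidationError(f"{path}: malformed affect value at line {line}")
    lo, hi = bounds
    out_of_bounds = (affect < lo) | (affect > hi)
    if out_of_bounds.any():
        line = int(affect.index[out_of_bounds][0]) + 2
        raise ValidationError(
            f"{path}: affect value {affect[out_of_bounds].iloc[0]} outside "
            f"bounds {bounds} at line {line}"
        )
    df = df.assign(timestamp=ts, affect=affect).sort_values(
        ["person_id", "timestamp"], kind="stable"
    )
    dup = df.duplicated(["person_id", "timestamp"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate report for person {row['person_id']!r} "
            f"at {row['timestamp']}"
        )
    series = [
        PersonSeries(
            str(pid),
            g["timestamp"].to_numpy().astype("datetime64[s]"),
            g["affect"].to_numpy(dtype=float),
        )
        for pid, g in df.groupby("person_id", sort=True)
    ]
    return ESMDataset.from_series(series, bounds)


def write_esm_csv(dataset: ESMDataset, path) -> None:
    """Write a dataset as a long CSV (inverse of :func:`read_esm_csv`)."""
    df = dataset.to_frame()
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


def write_table(rows: pd.DataFrame | Iterable[Mapping], path) -> None:
    """Write tabular results as tidy CSV; empty input yields a header-only file."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, index=False)
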