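"""Synthetic ESM data with known ground-truth affect dynamics.

Emulates the sampling regime of a signal-contingent smartphone study: a few
beeps per day (default 4) at random times inside a per-day window (default
09:00-22:00), at least one hour between consecutive prompts, integer slider
responses on a bounded 0-100 scale, and many weeks of participation per
person.

The latent affect process for person i at beep k is

    x_k = μ_i + A·cos(2π(h_k − h_peak)/24) + w·1[weekend] + s_k,

where μ_i is the person's trait level, the cosine term a diurnal cycle in
clock hour h_k with amplitude A peaking at h_peak, w a weekend shift, and
s_k a stationary AR(1) in beep order with person-specific persistence φ_i
and innovation scale σ_i (stationary SD σ_i/√(1−φ_i²)).  Persons are
heterogeneous: μ_i ~ Normal(trait_mean, trait_sd), σ_i lognormal,
φ_i ~ Normal truncated to a stationary range.  Observed values are clipped
to the scale bounds and, by default, rounded to integers as a slider would
report.  The generator returns both the dataset and a ground-truth table,
so estimator recovery can be checked exactly.

The person-level heterogeneity distributions are placeholders chosen to be
plausible for momentary happiness data; the originating study's person-level
distributions are not public.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .core import ESMDataset, PersonSeries, ValidationError

__all__ = ["SyntheticConfig", "generate_schedule", "generate_person", "generate_dataset"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    ``days_per_person`` may be an int or an inclusive (low, high) range
    sampled per person.  ``day_window`` is in clock hours; ``trait_*``
    parameterise the population of person means, ``within_sd_log_*`` the
    lognormal population of AR(1) innovation scales, ``phi_*`` the normal
    (truncated to (−0.95, 0.95)) population of lag-1 persistences.
    """

    n_persons: int = 200
    days_per_person: int | tuple[int, int] = 28
    beeps_per_day: int = 4
    day_window: tuple[float, float] = (9.0, 22.0)
    min_gap_minutes: float = 60.0
    trait_mean: float = 60.0
    trait_sd: float = 12.0
    within_sd_log_mean: float = math.log(9.0)
    within_sd_log_sd: float = 0.35
    phi_mean: float = 0.35
    phi_sd: float = 0.15
    diurnal_amplitude: float = 6.0
    diurnal_peak_hour: float = 19.0
    weekend_shift: float = 3.0
    bounds: tuple[float, float] = (0.0, 100.0)
    round_to_integer: bool = True
    start_date: str = "2024-01-01"  # a Monday
    seed: int | None = None

    def __post_init__(self) -> None:
        start, end = self.day_window
        if not 0 <= start < end <= 24:
            raise ValidationError(f"day_window must satisfy 0 <= start < end <= 24, got {self.day_window}")
        window_min = (end - start) * 60.0
        needed = (self.beeps_per_day - 1) * self.min_gap_minutes
        if self.beeps_per_day < 1:
            raise ValidationError("beeps_per_day must be >= 1")
        # strict: zero slack would force one deterministic schedule
        if needed >= window_min:
            raise ValidationError(
                f"{self.beeps_per_day} beeps with {self.min_gap_minutes} min "
                f"gaps cannot fit a {window_min:.0f} min window"
            )
        # gap between last beep of a day and first of the next
        if (24.0 - (end - start)) * 60.0 < self.min_gap_minutes:
            raise ValidationError("day window leaves no overnight gap >= min_gap")
        if self.n_persons < 0:
            raise ValidationError("n_persons must be >= 0")
        days = self.days_per_person
        lo = days if isinstance(days, int) else days[0]
        if lo < 1:
            raise ValidationError("days_per_person must be >= 1")


def generate_schedule(
    config: SyntheticConfig, n_days: int, rng: np.random.Generator
) -> np.ndarray:
    """Random beep times: per day, uniform in the window with spaced gaps.

    Uses the spacing transform — draw sorted uniforms in the window
    shortened by (beeps−1)·min_gap, then add k·min_gap to the k-th — which
    samples uniformly from the set of schedules respecting the minimum gap.
    """
    start_h, end_h = config.day_window
    b = config.beeps_per_day
    gap = config.min_gap_minutes
    slack = (end_h - start_h) * 60.0 - (b - 1) * gap
    day0 = np.datetime64(config.start_date)
    all_times = []
    for d in range(n_days):
        u = np.sort(rng.uniform(0.0, slack, size=b))
        minutes = start_h * 60.0 + u + np.arange(b) * gap
        base = (day0 + np.timedelta64(d, "D")).astype("datetime64[s]")
        all_times.append(base + (minutes * 60.0).astype("timedelta64[s]"))
    return np.concatenate(all_times)


def _draw_person_params(config: SyntheticConfig, rng: np.random.Generator):
    mu = rng.normal(config.trait_mean, config.trait_sd)
    sigma = rng.lognormal(config.within_sd_log_mean, config.within_sd_log_sd)
    phi = float(np.clip(rng.normal(config.phi_mean, config.phi_sd), -0.95, 0.95))
    return mu, sigma, phi


def generate_person(
    config: SyntheticConfig,
    person_id: str,
    rng: np.random.Generator,
) -> tuple[PersonSeries, dict]:
    """One person's series plus their ground-truth parameter record."""
    days = config.days_per_person
    n_days = days if isinstance(days, int) else int(rng.integers(days[0], days[1] + 1))
    times = generate_schedule(config, n_days, rng)
    mu, sigma, phi = _draw_person_params(config, rng)
    n = len(times)
    # stationary AR(1) in beep order via a linear recurrence filter
    innov = sigma * rng.standard_normal(n)
    innov[0] = (sigma / math.sqrt(1 - phi * phi)) * rng.standard_normal()
    s = lfilter([1.0], [1.0, -phi], innov)
    day = times.astype("datetime64[D]")
    hour = (times - day).astype("timedelta64[s]").astype(float) / 3600.0
    diurnal = config.diurnal_amplitude * np.cos(
        2 * math.pi * (hour - config.diurnal_peak_hour) / 24.0
    )
    dow = (day.astype("int64") + 3) % 7  # Mon=0
    weekend = (dow >= 5).astype(float)
    latent = mu + diurnal + config.weekend_shift * weekend + s
    lo, hi = config.bounds
    obs = np.clip(latent, lo, hi)
    if config.round_to_integer:
        obs = np.round(obs)
    truth = {
        "person_id": person_id,
        "mu": mu,
        "sigma": sigma,
        "phi": phi,
        "stationary_sd": sigma / math.sqrt(1 - phi * phi),
        "n_reports": n,
    }
    return PersonSeries(person_id, times, obs), truth


def generate_dataset(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[ESMDataset, pd.DataFrame]:
    """A dataset of independent persons with an aligned ground-truth table."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    width = max(4, len(str(max(config.n_persons, 1))))
    series, truths = [], []
    for i in range(config.n_persons):
        pid = f"p{i:0{width}d}"
        s, t = generate_person(config, pid, rng)
        series.append(s)
        truths.append(t)
    truth_df = pd.DataFrame(
        truths,
        columns=["person_id", "mu", "sigma", "phi", "stationary_sd", "n_reports"],
    )
    return ESMDataset.from_series(series, config.bounds), truth_df
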