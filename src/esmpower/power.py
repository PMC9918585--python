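"""Empirical statistical power for affect-dynamics correlation studies.

A typical design question: with N participants each providing n affect
reports, what is the power to detect a Pearson correlation of r between an
affect-dynamics measure and an outcome, at significance level α?

The engine answers it by simulation.  Outcomes are constructed against the
participants' *true* measure values (full records) at a target correlation,
by mixing the standardised truth vector with standardised Gaussian noise
orthogonalised against it — in exact mode the realised sample correlation
equals the target to numerical precision; in population mode it holds in
expectation.  Inside the power engine the target correlation must hold at
the *population* level so that each simulated study's sample correlation
fluctuates the way a real study's would: either outcomes are regenerated
per simulated dataset with population-mode mixing (the default), or one
exact-mode outcome vector per simulation is pre-generated against the full
person pool and read off at the resampled persons (``outcome_mode="pool"``,
mirroring a pre-generated outcome bank).  Building an exact-mode outcome
against the resampled persons themselves would pin every simulated sample
correlation at the target and collapse power to a step function.
Each simulated dataset then re-estimates the measure from a
fresh random n-report subsample per participant (the measurement noise a
real study would face), and tests the Pearson correlation between estimates
and outcomes with a two-tailed t-test.  Power is the proportion of
simulations with a significant *positive* correlation, so under the null
(r = 0) the expected rate is α/2, not α.

The Fisher-z closed form Φ(atanh(r)·√(N−3) − z_{1−α/2}) is provided as the
classical analytic approximation for the noiseless (full-record) case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ESMDataset, MEASURE_NAMES, MeasureSet, ValidationError
from .measures import compute_d90, measure_rows
from .accuracy import true_measures

__all__ = [
    "PowerCell",
    "DesignFrontier",
    "simulate_outcome",
    "pearson_test",
    "fisher_z_power",
    "power_cell",
    "power_grid",
    "minimal_designs",
    "effect_benchmarks",
    "grid_frame",
    "DEFAULT_PARTICIPANT_GRID",
    "DEFAULT_OBS_GRID",
    "DEFAULT_R_TARGETS",
]

#: Default design grids: 10 participant counts × 10 observation counts.
DEFAULT_PARTICIPANT_GRID = (10, 20, 40, 80, 160, 320, 640, 1280, 2560, 5120)
DEFAULT_OBS_GRID = (5, 10, 15, 20, 25, 30, 35, 40, 45, 50)
#: Weak / medium / strong target correlations.
DEFAULT_R_TARGETS = (0.10, 0.30, 0.50)


@dataclass(frozen=True)
class PowerCell:
    """Estimated power for one (measure, N participants, n obs, r, α) design."""

    measure: str
    n_participants: int
    n_obs: int | None
    r_target: float
    alpha: float
    power: float
    mc_se: float
    n_sims: int


@dataclass(frozen=True)
class DesignFrontier:
    """Minimal observations per participant achieving a power threshold.

    ``points`` maps each participant count to the smallest grid n_obs whose
    estimated power meets the threshold (after isotonic cleanup of
    Monte-Carlo inversions); participant counts that never reach it are
    absent.
    """

    measure: str
    r_target: float
    alpha: float
    power_threshold: float
    points: tuple[tuple[int, int], ...]


def simulate_outcome(
    y: np.ndarray,
    r_target: float,
    rng: np.random.Generator,
    mode: str = "exact",
) -> np.ndarray:
    """An outcome vector correlated with ``y`` at ``r_target``.

    Standard-normal noise is orthogonalised against the standardised ``y``
    and the two are mixed as r·ỹ + sqrt(1−r²)·ε̃.  In ``exact`` mode both
    components are standardised so the sample Pearson correlation equals
    ``r_target`` exactly; in ``population`` mode the raw noise is added
    unstandardised and the correlation holds in expectation only.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ValidationError("need at least 3 values to build an outcome")
    if abs(r_target) >= 1:
        raise ValidationError(f"|r_target| must be < 1, got {r_target}")
    sd = y.std()
    if sd == 0:
        raise ValidationError("cannot correlate an outcome with a constant vector")
    yt = (y - y.mean()) / sd
    eps = rng.standard_normal(len(y))
    if mode == "population":
        return r_target * yt + math.sqrt(1 - r_target**2) * eps
    if mode != "exact":
        raise ValidationError(f"unknown outcome mode {mode!r}")
    eps = eps - eps.mean()
    eps = eps - (eps @ yt) / (yt @ yt) * yt  # orthogonal to yt
    norm = eps.std()
    if norm == 0:  # pragma: no cover - measure-zero event
        raise ValidationError("degenerate noise vector")
    return r_target * yt + math.sqrt(1 - r_target**2) * (eps / norm)


def pearson_test(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float, bool]:
    """Two-tailed t-test on the Pearson correlation.

    Returns ``(r, t, p, significant_positive)`` with
    t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom;
    ``significant_positive`` requires both p < α and r > 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n or n < 3:
        raise ValidationError("pearson_test needs two equal-length vectors, n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("pearson_test inputs must be non-constant")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, math.copysign(math.inf, r), 0.0, r > 0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, t, p, (p < alpha) and (r > 0)


def fisher_z_power(r: float, n: int, alpha: float = 0.05) -> float:
    """Closed-form power approximation for detecting a positive Pearson r.

    Under Fisher's z transform, atanh(r̂) is approximately normal with mean
    atanh(r) and SE 1/sqrt(n−3); power for the upper rejection region is
    Φ(atanh(r)·sqrt(n−3) − z_{1−α/2}).
    """
    z = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(math.atanh(r) * math.sqrt(n - 3) - z))


def _truth_vector(
    truths: Mapping[str, MeasureSet], measure: str
) -> tuple[list[str], np.ndarray]:
    pids, vals = [], []
    for pid, ms in truths.items():
        v = ms[measure]
        if not math.isnan(v):
            pids.append(pid)
            vals.append(v)
    return pids, np.asarray(vals, dtype=float)


def power_cell(
    dataset: ESMDataset,
    measure: str,
    n_participants: int,
    n_obs: int | None,
    r_target: float,
    alpha: float = 0.05,
    n_sims: int = 2500,
    rng: np.random.Generator | None = None,
    *,
    truths: Mapping[str, MeasureSet] | None = None,
    min_reports_truth: int = 50,
    replace: bool = True,
    outcome_mode: str = "population",
    count_rule: str = "positive",
    pac_threshold_mode: str = "recompute",
) -> PowerCell:
    """Simulated power for one design cell.

    Per simulation: draw ``n_participants`` persons (with replacement by
    default), build an outcome correlated at ``r_target`` with those
    persons' true measure values, re-estimate the measure from a fresh
    random ``n_obs``-report subsample per person (``n_obs=None`` uses the
    noiseless true values), and test the estimate-outcome correlation.
    Power is the fraction of significant positive results
    (``count_rule="two_sided"`` counts either sign).

    ``outcome_mode="population"`` (default) regenerates a population-mode
    outcome against each simulated dataset; ``"pool"`` pre-generates
    ``n_sims`` exact-mode outcome vectors against the full person set and
    indexes them at the resampled persons.  Both leave the target
    correlation to hold in the population and fluctuate in each sample,
    which is what a power calculation measures.
    """
    if rng is None:
        rng = np.random.default_rng()
    if truths is None:
        truths = true_measures(dataset, min_reports_truth)
    pids, tv = _truth_vector(truths, measure)
    P = len(pids)
    if P < 3:
        raise ValidationError(f"need >= 3 persons with defined {measure}, got {P}")
    if not replace and n_participants > P:
        raise ValidationError(
            f"cannot draw {n_participants} of {P} persons without replacement"
        )
    noiseless = n_obs is None
    if not noiseless:
        lengths = [len(dataset[p]) for p in pids]
        feasible = [i for i, L in enumerate(lengths) if L >= n_obs]
        if len(feasible) < 3:
            raise ValidationError(
                f"fewer than 3 persons have >= {n_obs} reports for measure {measure}"
            )
        pids = [pids[i] for i in feasible]
        tv = tv[feasible]
        P = len(pids)
        lengths = [lengths[i] for i in feasible]
        equal_len = len(set(lengths)) == 1
        if equal_len:
            V = np.stack([dataset[p].values for p in pids])
        else:
            V_list = [dataset[p].values for p in pids]
        full_d90 = compute_d90(dataset).d90 if measure == "pac" else None
    pool = None
    if outcome_mode == "pool":
        # pre-generate one outcome vector per simulation against the full
        # fixed person set; each simulation then reads off its resampled rows
        pool = np.stack(
            [simulate_outcome(tv, r_target, rng, "exact") for _ in range(n_sims)]
        )
    n_sig = 0
    chunk = max(1, int(2_000_000 // max(1, n_participants * (1 if noiseless else max(lengths)))))
    sims_done = 0
    while sims_done < n_sims:
        S = min(chunk, n_sims - sims_done)
        if replace:
            sel = rng.integers(0, P, size=(S, n_participants))
        else:
            sel = np.stack(
                [rng.choice(P, size=n_participants, replace=False) for _ in range(S)]
            )
        for s in range(S):
            y = tv[sel[s]]
            tries = 0
            while y.std() == 0:  # resample degenerate draws (all-equal truths)
                sel[s] = (rng.integers(0, P, size=n_participants)
                          if replace else rng.choice(P, n_participants, replace=False))
                y = tv[sel[s]]
                tries += 1
                if tries > 100:
                    raise ValidationError(
                        f"true {measure} values are constant across persons"
                    )
            if pool is not None:
                outcome = pool[sims_done + s][sel[s]]
                if outcome.std() == 0:
                    outcome = simulate_outcome(y, r_target, rng, "exact")
            else:
                outcome = simulate_outcome(y, r_target, rng, outcome_mode)
            if noiseless:
                est = y
            else:
                if equal_len:
                    rows = V[sel[s]]
                    u = rng.random(rows.shape)
                    idx = np.sort(
                        np.argpartition(u, n_obs - 1, axis=1)[:, :n_obs], axis=1
                    )
                    sub = np.take_along_axis(rows, idx, axis=1)
                else:
                    sub = np.stack(
                        [
                            np.asarray(V_list[j])[
                                np.sort(rng.choice(lengths[j], n_obs, replace=False))
                            ]
                            for j in sel[s]
                        ]
                    )
                if measure == "pac":
                    if pac_threshold_mode == "recompute":
                        d = np.percentile(np.abs(np.diff(sub, axis=1)), 90)
                    else:
                        d = full_d90
                    est = measure_rows(sub, "pac", d90=d)
                else:
                    est = measure_rows(sub, measure, bounds=dataset.bounds)
            ok = ~np.isnan(est)
            if ok.sum() < 3 or est[ok].std() == 0:
                continue  # degenerate simulation counts as non-significant
            _, _, p, sig_pos = pearson_test(est[ok], outcome[ok], alpha)
            if count_rule == "two_sided":
                n_sig += p < alpha
            else:
                n_sig += sig_pos
        sims_done += S
    power = n_sig / n_sims
    return PowerCell(
        measure=measure,
        n_participants=n_participants,
        n_obs=n_obs,
        r_target=r_target,
        alpha=alpha,
        power=power,
        mc_se=math.sqrt(power * (1 - power) / n_sims),
        n_sims=n_sims,
    )


def power_grid(
    dataset: ESMDataset,
    measures: Sequence[str] = MEASURE_NAMES,
    participant_grid: Sequence[int] = DEFAULT_PARTICIPANT_GRID,
    obs_grid: Sequence[int] = DEFAULT_OBS_GRID,
    r_targets: Sequence[float] = DEFAULT_R_TARGETS,
    alpha: float = 0.05,
    n_sims: int = 2500,
    rng: np.random.Generator | None = None,
    *,
    min_reports_truth: int = 50,
    on_error: str = "skip",
    **cell_kwargs,
) -> list[PowerCell]:
    """Power over the Cartesian product of designs, measures and effect sizes.

    Each cell gets an independent random stream spawned from ``rng`` so the
    grid is reproducible regardless of iteration order.  Infeasible cells
    are skipped (``on_error="raise"`` propagates instead).
    """
    if rng is None:
        rng = np.random.default_rng()
    truths = true_measures(dataset, min_reports_truth)
    cells = []
    for m in measures:
        for r in r_targets:
            for npart in participant_grid:
                for nobs in obs_grid:
                    cell_rng = rng.spawn(1)[0]
                    try:
                        cells.append(
                            power_cell(
                                dataset, m, npart, nobs, r, alpha, n_sims,
                                cell_rng, truths=truths,
                                min_reports_truth=min_reports_truth,
                                **cell_kwargs,
                            )
                        )
                    except ValidationError:
                        if on_error == "raise":
                            raise
        # else: skip infeasible cell, continue the grid
    return cells


def minimal_designs(
    cells: Sequence[PowerCell], power_threshold: float = 0.80
) -> DesignFrontier:
    """Minimal n_obs per participant count achieving the power threshold.

    All cells must share one (measure, r_target, alpha).  For each
    participant count the smallest grid n_obs with power ≥ threshold is
    taken; isotonic cleanup then enforces that the frontier never rises with
    more participants by carrying the largest requirement seen at any larger
    participant count (conservative: Monte-Carlo dips are never promoted to
    smaller designs).
    """
    if not cells:
        raise ValidationError("no cells supplied")
    keys = {(c.measure, c.r_target, c.alpha) for c in cells}
    if len(keys) != 1:
        raise ValidationError(f"cells mix designs: {sorted(keys)}")
    measure, r_target, alpha = keys.pop()
    participants = sorted({c.n_participants for c in cells})
    raw: dict[int, int | None] = {}
    for npart in participants:
        sub = sorted(
            (c for c in cells if c.n_participants == npart),
            key=lambda c: (c.n_obs is None, c.n_obs),
        )
        raw[npart] = next(
            (c.n_obs for c in sub if c.power >= power_threshold), None
        )
    points = []
    running: int | None = None  # max requirement among larger participant counts
    for npart in reversed(participants):
        if raw[npart] is None:
            continue
        running = raw[npart] if running is None else max(running, raw[npart])
        points.append((npart, running))
    points.reverse()
    return DesignFrontier(measure, r_target, alpha, power_threshold, tuple(points))


def effect_benchmarks(
    truths: Mapping[str, MeasureSet] | pd.DataFrame,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Pairwise-complete Pearson r between each measure and each covariate.

    ``covariates`` is indexed by person_id with one column per covariate.
    Pairs with fewer than 3 complete observations are NaN.  The resulting
    table is the plausible-effect-size benchmark a study planner reads
    before choosing a target r.
    """
    if isinstance(truths, pd.DataFrame):
        mdf = truths
    else:
        mdf = pd.DataFrame(
            {pid: ms.as_dict() for pid, ms in truths.items()}
        ).T
    mdf = mdf.loc[mdf.index.intersection(covariates.index)]
    cov = covariates.loc[mdf.index]
    out = pd.DataFrame(index=mdf.columns, columns=cov.columns, dtype=float)
    for m in mdf.columns:
        for c in cov.columns:
            pair = pd.concat([mdf[m], cov[c]], axis=1).dropna()
            if len(pair) < 3 or pair.iloc[:, 0].std() == 0 or pair.iloc[:, 1].std() == 0:
                out.loc[m, c] = np.nan
            else:
                out.loc[m, c] = float(pair.corr().iloc[0, 1])
    return out


def grid_frame(cells: Sequence[PowerCell]) -> pd.DataFrame:
    """Power cells as a tidy table for CSV export."""
    cols = ["measure", "n_participants", "n_obs", "r_target", "alpha",
            "power", "mc_se", "n_sims"]
    return pd.DataFrame([{k: getattr(c, k) for k in cols} for c in cells],
                        columns=cols)
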