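"""Empirical standard errors by simulation: a generic Monte Carlo engine for
rate-based demographic estimators, Poisson and binomial parametric bootstraps,
and a delete-one jackknife for micro-data.

All engines share the same summary: the standard error of a quantity is the
sample standard deviation of its replicate values, and confidence intervals
are percentile intervals of the replicate distribution (linear interpolation
between order statistics).  Exposures are treated as fixed constants
throughout; only deaths (or rates) are random.

Replicate draw order is fixed — population 1 first, then population 2, each
as one (reps, groups) matrix in age order — so a seed fully determines the
replicate stream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decompose import arriaga_from_rates
from .lifetable import q_from_m
from .schedules import CauseSchedule, MortalitySchedule

__all__ = [
    "SimulationConfig",
    "UncertaintyResult",
    "mc_engine",
    "mc_schedules",
    "poisson_bootstrap",
    "binomial_bootstrap",
    "jackknife_microdata",
    "summarize_replicates",
    "make_arriaga_estimator",
    "make_cause_estimator",
    "cause_rate_variances",
    "rate_variances",
    "schedule_from_microdata",
]

FAILURE_BUDGET = 0.01  # fraction of replicates allowed to fail before aborting


@dataclass(frozen=True)
class SimulationConfig:
    """Replication settings shared by all simulation engines.

    ``seed`` has no default on purpose: published standard errors should be
    reproducible, so the caller must choose one.
    """

    seed: int
    reps: int = 1000
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required for reproducible simulation")
        if self.reps < 2:
            raise ValueError("at least two replicates are required")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass(frozen=True)
class UncertaintyResult:
    """Standard errors and percentile confidence intervals per quantity.

    ``labels`` names each quantity (for the decomposition: one per age group
    plus ``'total'``).  ``replicates`` optionally stores the full replicate
    matrix (reps, quantities) for audit; failed replicates are NaN rows.
    """

    labels: tuple[str, ...]
    se: np.ndarray
    method: str
    reps: int
    seed: int | None
    ci_level: float | None
    estimate: np.ndarray | None = None
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    n_failed: int = 0
    n_truncated: int = 0
    replicates: np.ndarray | None = field(default=None, repr=False)

    @property
    def total_se(self) -> float:
        return float(self.se[self.labels.index("total")])

    def to_frame(self) -> pd.DataFrame:
        data = {"quantity": list(self.labels), "se": self.se}
        if self.estimate is not None:
            data["estimate"] = self.estimate
        if self.ci_lower is not None:
            data["ci_lower"] = self.ci_lower
            data["ci_upper"] = self.ci_upper
        return pd.DataFrame(data)


def summarize_replicates(
    replicates: np.ndarray,
    ci_level: float = 0.95,
    labels: tuple[str, ...] | None = None,
    method: str = "simulation",
    seed: int | None = None,
    estimate: np.ndarray | None = None,
    n_truncated: int = 0,
    keep_replicates: bool = False,
) -> UncertaintyResult:
    """Standard errors and percentile CIs from a (reps, quantities) matrix.

    SE is the sample standard deviation (denominator reps - 1) over successful
    replicates; CI bounds are empirical quantiles with linear interpolation
    between order statistics.  Rows containing non-finite values count as
    failed replicates and are excluded.
    """
    replicates = np.atleast_2d(np.asarray(replicates, dtype=float))
    ok = np.all(np.isfinite(replicates), axis=1)
    n_failed = int((~ok).sum())
    good = replicates[ok]
    if len(good) < 2:
        raise RuntimeError("fewer than two successful replicates; nothing to summarize")
    se = good.std(axis=0, ddof=1)
    alpha = 1.0 - ci_level
    lo = np.quantile(good, alpha / 2, axis=0)
    hi = np.quantile(good, 1.0 - alpha / 2, axis=0)
    if labels is None:
        labels = tuple(f"q{i}" for i in range(replicates.shape[1]))
    return UncertaintyResult(
        labels=labels,
        se=se,
        estimate=estimate,
        ci_lower=lo,
        ci_upper=hi,
        method=method,
        reps=replicates.shape[0],
        seed=seed,
        ci_level=ci_level,
        n_failed=n_failed,
        n_truncated=n_truncated,
        replicates=replicates if keep_replicates else None,
    )


def _check_failures(replicates: np.ndarray, method: str) -> None:
    bad = ~np.all(np.isfinite(np.atleast_2d(replicates)), axis=1)
    frac = bad.mean()
    if frac > FAILURE_BUDGET:
        raise RuntimeError(
            f"{method}: {bad.sum()} of {len(bad)} replicates failed "
            f"({100 * frac:.1f}% > {100 * FAILURE_BUDGET:.0f}% budget); "
            "inputs are too sparse for stable resampling"
        )


def _evaluate(estimator, rate_draws: list[np.ndarray]) -> np.ndarray:
    """Run the estimator over a stack of replicate rate vectors.

    Estimators advertising ``vectorized = True`` receive the full
    (reps, n_rates) matrices at once; otherwise they are called per replicate
    and exceptions mark the replicate as failed.
    """
    reps = rate_draws[0].shape[0]
    if getattr(estimator, "vectorized", False):
        out = np.asarray(estimator(*rate_draws), dtype=float)
        return np.atleast_2d(out)
    rows = []
    for r in range(reps):
        try:
            val = np.atleast_1d(np.asarray(estimator(*[d[r] for d in rate_draws]), dtype=float))
        except Exception:
            val = None
        rows.append(val)
    try:
        width = next(len(v) for v in rows if v is not None)
    except StopIteration:
        raise RuntimeError("every replicate failed; the estimator raised on all draws") from None
    return np.vstack([v if v is not None else np.full(width, np.nan) for v in rows])


def rate_variances(schedule: MortalitySchedule) -> np.ndarray:
    """Sampling variance of each observed rate: survey SE^2 when supplied,
    otherwise the Poisson-implied m / N (= D / N^2)."""
    if schedule.rate_se is not None:
        return schedule.rate_se**2
    if schedule.exposure is None:
        raise ValueError("need exposure (or rate_se) to derive rate variances")
    return schedule.rates / schedule.exposure


def mc_engine(
    estimator,
    rates: list[np.ndarray],
    variances: list[np.ndarray],
    config: SimulationConfig,
    labels: tuple[str, ...] | None = None,
    keep_replicates: bool = False,
) -> UncertaintyResult:
    """Generic Monte Carlo standard errors for any rate-based estimator.

    Each input rate is drawn independently from a normal distribution centred
    at the observed rate with the supplied variance; the estimator is
    evaluated on every draw and the replicate distribution is summarized.
    Negative rate draws are truncated to zero and counted in the result
    (they are rare whenever each group has roughly five or more expected
    events, the regime in which the normal approximation is trustworthy).
    """
    rng = np.random.default_rng(config.seed)
    draws = []
    n_trunc = 0
    for r, v in zip(rates, variances):
        r = np.asarray(r, dtype=float)
        d = rng.normal(loc=r, scale=np.sqrt(np.asarray(v, dtype=float)),
                       size=(config.reps, len(r)))
        n_trunc += int((d < 0).sum())
        draws.append(np.maximum(d, 0.0))
    replicates = _evaluate(estimator, draws)
    _check_failures(replicates, "mc")
    est = np.atleast_1d(np.asarray(estimator(*[np.asarray(r, dtype=float) for r in rates]),
                                   dtype=float)).ravel()
    return summarize_replicates(
        replicates, config.ci_level,
        labels=labels or getattr(estimator, "labels", None),
        method="monte-carlo", seed=config.seed, estimate=est,
        n_truncated=n_trunc, keep_replicates=keep_replicates,
    )


def mc_schedules(
    sched1: MortalitySchedule,
    sched2: MortalitySchedule,
    config: SimulationConfig,
    estimator=None,
    keep_replicates: bool = False,
) -> UncertaintyResult:
    """Monte Carlo SEs for a two-schedule estimator (default: Arriaga).

    Rate variances are survey SE^2 when present, else m / N.
    """
    if estimator is None:
        estimator = make_arriaga_estimator(sched1, sched2)
    return mc_engine(
        estimator,
        [sched1.rates, sched2.rates],
        [rate_variances(sched1), rate_variances(sched2)],
        config,
        keep_replicates=keep_replicates,
    )


def _bootstrap(sched1, sched2, estimator, config, draw_deaths, method, keep_replicates):
    if estimator is None:
        estimator = make_arriaga_estimator(sched1, sched2)
    for s in (sched1, sched2):
        if not s.has_counts:
            raise ValueError(f"{method} needs death counts and exposures")
    rng = np.random.default_rng(config.seed)
    draws = []
    for s in (sched1, sched2):
        D = draw_deaths(rng, s, config.reps)
        draws.append(D / s.exposure[None, :])
    replicates = _evaluate(estimator, draws)
    _check_failures(replicates, method)
    est = np.atleast_1d(np.asarray(estimator(sched1.rates, sched2.rates), dtype=float)).ravel()
    return summarize_replicates(
        replicates, config.ci_level,
        labels=getattr(estimator, "labels", None),
        method=method, seed=config.seed, estimate=est,
        keep_replicates=keep_replicates,
    )


def poisson_bootstrap(
    sched1: MortalitySchedule,
    sched2: MortalitySchedule,
    config: SimulationConfig,
    estimator=None,
    keep_replicates: bool = False,
) -> UncertaintyResult:
    """Parametric bootstrap drawing deaths ~ Poisson(observed deaths) in every
    age group (open group included); rates are re-derived per replicate with
    exposures fixed."""

    def draw(rng, s, reps):
        return rng.poisson(lam=s.deaths, size=(reps, len(s.deaths))).astype(float)

    return _bootstrap(sched1, sched2, estimator, config, draw,
                      "poisson-bootstrap", keep_replicates)


def binomial_bootstrap(
    sched1: MortalitySchedule,
    sched2: MortalitySchedule,
    config: SimulationConfig,
    estimator=None,
    keep_replicates: bool = False,
) -> UncertaintyResult:
    """Parametric bootstrap drawing closed-group deaths ~ Binomial with
    success probability nqx and trials round(nDx / nqx) (floored at 1).

    The open group keeps the Poisson draw: its death probability is 1, so a
    binomial there would have zero variance even though the group typically
    carries a large share of all deaths.
    """

    def draw(rng, s, reps):
        C = s.grid.n_closed
        q = q_from_m(s.rates[:C], s.nax[:C], s.grid.widths[:C])
        with np.errstate(divide="ignore", invalid="ignore"):
            trials = np.where(q > 0, np.round(s.deaths[:C] / np.where(q > 0, q, 1.0)), 0)
        trials = np.maximum(trials, 1).astype(np.int64)
        closed = rng.binomial(n=trials[None, :], p=q[None, :], size=(reps, C)).astype(float)
        closed[:, q == 0] = 0.0  # no deaths observed -> no variance
        open_grp = rng.poisson(lam=s.deaths[-1], size=(reps, 1)).astype(float)
        return np.concatenate([closed, open_grp], axis=1)

    return _bootstrap(sched1, sched2, estimator, config, draw,
                      "binomial-bootstrap", keep_replicates)


def jackknife_microdata(
    records: pd.DataFrame,
    estimator,
    mode: str = "delete-one",
) -> UncertaintyResult:
    """Delete-one jackknife over micro-data rows.

    The estimator is any function of the records DataFrame returning a scalar
    or vector.  Each of the N replicates omits one row; the variance is
    (N - 1)/N times the summed squared deviations of the replicate estimates
    from the full-sample estimate.  Only standard errors are reported (no
    percentile CIs — jackknife replicates do not form a sampling
    distribution).  Intended for modest N; for large vital-statistics samples
    prefer the parametric engines.
    """
    if mode != "delete-one":
        raise ValueError("only the delete-one jackknife is implemented")
    N = len(records)
    if N < 2:
        raise ValueError("jackknife needs at least two records")
    records = records.reset_index(drop=True)
    full = np.atleast_1d(np.asarray(estimator(records), dtype=float))
    reps = np.empty((N, len(full)))
    for j in range(N):
        sub = records.drop(index=j)
        try:
            reps[j] = np.asarray(estimator(sub), dtype=float)
        except Exception:
            reps[j] = np.nan
    ok = np.all(np.isfinite(reps), axis=1)
    n_failed = int((~ok).sum())
    if n_failed:
        warnings.warn(
            f"{n_failed} jackknife replicates failed (e.g. emptied an age group) "
            "and were excluded",
            stacklevel=2,
        )
    good = reps[ok]
    Ng = len(good)
    if Ng < 2:
        raise RuntimeError("fewer than two successful jackknife replicates")
    var = (Ng - 1) / Ng * np.sum((good - full) ** 2, axis=0)
    labels = getattr(estimator, "labels", None) or tuple(f"q{i}" for i in range(len(full)))
    return UncertaintyResult(
        labels=tuple(labels),
        se=np.sqrt(var),
        estimate=full,
        ci_lower=None,
        ci_upper=None,
        method="jackknife (delete-one)",
        reps=N,
        seed=None,
        ci_level=None,
        n_failed=n_failed,
    )


def schedule_from_microdata(
    records: pd.DataFrame,
    grid,
    age_col: str = "age_start",
    death_col: str = "death",
    exposure_col: str | None = "exposure",
    nax: np.ndarray | None = None,
    name: str = "",
) -> MortalitySchedule:
    """Aggregate person-level rows into a mortality schedule.

    Each row carries the start age of its group, a 0/1 death flag and,
    optionally, person-years of exposure (defaults to the group width for
    survivors are not distinguished — one year per row if absent).
    """
    starts = np.asarray(grid.starts)
    idx = pd.Categorical(records[age_col], categories=starts)
    deaths = records.groupby(idx, observed=False)[death_col].sum().to_numpy(dtype=float)
    if exposure_col is not None and exposure_col in records:
        expo = records.groupby(idx, observed=False)[exposure_col].sum().to_numpy(dtype=float)
    else:
        expo = records.groupby(idx, observed=False)[death_col].count().to_numpy(dtype=float)
    if np.any(expo <= 0):
        raise ValueError("every age group needs positive exposure in the micro-data")
    return MortalitySchedule.from_counts(grid, deaths, expo, nax=nax, name=name)


def make_arriaga_estimator(sched1: MortalitySchedule, sched2: MortalitySchedule):
    """Vectorised estimator mapping two rate vectors to the per-age Arriaga
    contributions plus their total (nax and the grid come from the observed
    schedules and are held fixed across replicates)."""
    if sched1.grid != sched2.grid:
        raise ValueError("schedules must share the same age grid")
    grid = sched1.grid
    a1, a2, widths = sched1.nax, sched2.nax, grid.widths

    def estimator(m1, m2):
        contrib = arriaga_from_rates(m1, a1, m2, a2, widths)
        return np.concatenate([contrib, contrib.sum(axis=-1, keepdims=True)], axis=-1)

    estimator.vectorized = True
    estimator.labels = tuple(
        f"age_{s:g}" for s in grid.starts
    ) + ("total",)
    return estimator


def make_cause_estimator(causes1: CauseSchedule, causes2: CauseSchedule):
    """Vectorised estimator on flattened per-(age, cause) rate vectors.

    Input rates are row-major flattened (age major, cause minor) for each
    population; output is the flattened age-by-cause contribution matrix plus
    the total.  All-cause rates are recovered as the cause sums, so replicate
    draws at the (age, cause) level propagate into both the age decomposition
    and its split.
    """
    g1, g2 = causes1.schedule.grid, causes2.schedule.grid
    if g1 != g2:
        raise ValueError("cause schedules must share the same age grid")
    if causes1.labels != causes2.labels:
        raise ValueError("cause labels must match")
    G, K = causes1.cause_deaths.shape
    a1, a2, widths = causes1.schedule.nax, causes2.schedule.nax, g1.widths

    def estimator(mc1, mc2):
        mc1 = np.asarray(mc1, dtype=float).reshape(mc1.shape[:-1] + (G, K))
        mc2 = np.asarray(mc2, dtype=float).reshape(mc2.shape[:-1] + (G, K))
        m1 = mc1.sum(axis=-1)
        m2 = mc2.sum(axis=-1)
        dx = arriaga_from_rates(m1, a1, m2, a2, widths)
        dm_all = m2 - m1
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = (mc2 - mc1) / dm_all[..., None]
        dxi = dx[..., None] * ratios
        flat = dxi.reshape(dxi.shape[:-2] + (G * K,))
        return np.concatenate([flat, dx.sum(axis=-1, keepdims=True)], axis=-1)

    estimator.vectorized = True
    estimator.labels = tuple(
        f"age_{s:g}:{lab}" for s in g1.starts for lab in causes1.labels
    ) + ("total",)
    return estimator


def cause_rate_variances(causes: CauseSchedule) -> np.ndarray:
    """Poisson-implied variance of each flattened (age, cause) rate: m_xi / N_x."""
    return (causes.cause_rates / causes.schedule.exposure[:, None]).ravel()
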