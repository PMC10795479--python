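"""Analytic (delta-method) standard errors for the Arriaga decomposition.

The decomposition is a smooth function of the closed-group survival
probabilities p_i of each population and of the two open-group death counts
D_w (exposures held fixed).  Linearising around the observed values gives

    var(Dx) ~= sum_theta (dDx/dtheta)^2 * var(theta)

with binomial variance (1-p_i)^2 * p_i / D_i for each probability and
Poisson variance D_w for the open-group counts (survey-supplied squared
standard errors may replace either).  Parameters are sampled independently
across age groups and populations; the total's standard error uses the fact
that parameters are shared across age rows, so its derivative w.r.t. each
parameter is the column sum of the per-age Jacobian.

The closed-form Jacobian below is validated against central finite
differences of the implemented decomposition in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .lifetable import LifeTable, build_lifetable, dq_dm, lifetable_arrays
from .schedules import MortalitySchedule

__all__ = [
    "DecompositionJacobian",
    "ParameterVariances",
    "jacobian",
    "count_variances",
    "survey_variances",
    "delta_se",
    "decomposition_from_params",
]


@dataclass(frozen=True)
class DecompositionJacobian:
    """Partial derivatives of each age contribution Dx.

    ``d_p1``/``d_p2`` have shape (groups, closed groups): derivative of row x
    w.r.t. the survival probability of group i in population 1/2.  ``d_D1``/
    ``d_D2`` have shape (groups,): derivatives w.r.t. the open-group death
    counts.  Sparsity: d_p1 is lower-triangular in (x, i) for closed rows,
    d_p2 upper-triangular, d_D1 vanishes except in the open row, and the open
    row of d_p2 vanishes entirely.
    """

    d_p1: np.ndarray
    d_p2: np.ndarray
    d_D1: np.ndarray
    d_D2: np.ndarray


@dataclass(frozen=True)
class ParameterVariances:
    """Sampling variances of the decomposition's parameters.

    ``var_p1``/``var_p2``: per closed group; ``var_D1``/``var_D2``: open-group
    death counts.  ``source`` records whether they are count-implied
    (binomial/Poisson) or survey-supplied squared standard errors.
    """

    var_p1: np.ndarray
    var_p2: np.ndarray
    var_D1: float
    var_D2: float
    source: str = "count-based"

    def __post_init__(self) -> None:
        for v in (self.var_p1, self.var_p2):
            if np.any(np.asarray(v) < 0):
                raise ValueError("variances must be non-negative")
        if self.var_D1 < 0 or self.var_D2 < 0:
            raise ValueError("variances must be non-negative")


def jacobian(lt1: LifeTable, lt2: LifeTable,
             deaths_open1: float, deaths_open2: float) -> DecompositionJacobian:
    """Closed-form Jacobian of the decomposition at the observed life tables.

    ``deaths_open*`` are the open-group death counts of the two populations,
    needed because the open-group rate enters as D/N with N fixed.
    """
    if lt1.grid != lt2.grid:
        raise ValueError("life tables must share the same age grid")
    grid = lt1.grid
    if not grid.open_ended:
        raise ValueError("an open-ended final group is required")
    G, C = grid.n_groups, grid.n_closed
    n = grid.widths

    l1, L1, e1, p1, a1 = lt1.l, lt1.L, lt1.e, lt1.p, lt1.a
    l2, L2, e2, p2, a2 = lt2.l, lt2.L, lt2.e, lt2.p, lt2.a
    l1n, e2n = l1[1:], e2[1:]          # values at x+n for closed rows x
    D1w, D2w = float(deaths_open1), float(deaths_open2)

    d_p1 = np.zeros((G, C))
    d_p2 = np.zeros((G, C))
    d_D1 = np.zeros(G)
    d_D2 = np.zeros(G)

    x = np.arange(C)
    # closed rows: shared factors
    direct = L2[:C] / l2[:C] - L1[:C] / l1[:C]
    chain = p2[:C] * l1[:C] - l1n[:C]          # multiplies e2(x+n) in the indirect term

    # d/dp1[i], i < x: both l1(x) and l1(x+n) scale with p1(i)
    with np.errstate(divide="ignore", invalid="ignore"):
        below = (l1[:C] * direct + e2n[:C] * (p2[:C] * l1[:C] - l1n[:C]))[:, None] / p1[None, :C]
    mask_below = x[:, None] > x[None, :]
    d_p1[:C][mask_below] = np.broadcast_to(below, (C, C))[mask_below]
    # diagonal i == x
    d_p1[x, x] = -l1[:C] * ((n[:C] - a1[:C]) + e2n[:C])
    # open row: l1(w) scales with every p1(i)
    d_p1[G - 1, :] = l1[-1] / p1[:C] * (e2[-1] - e1[-1])

    # d/dp2[i]: diagonal i == x
    d_p2[x, x] = l1[:C] * ((n[:C] - a2[:C]) + e2n[:C])
    # i > x (closed i): e2(x+n) responds via de(x+n)/dp_i = l_i/l_(x+n) * ((n_i - a_i) + e_(i+n))
    de_factor = (n[:C] - a2[:C]) + e2[1 : C + 1]   # ((n_i - a_i2) + e2(i+n)) per closed i
    with np.errstate(divide="ignore", invalid="ignore"):
        above = (l2[None, :C] / l2[1 : C + 1, None]) * de_factor[None, :] * chain[:, None]
    mask_above = x[:, None] < x[None, :]
    d_p2[:C][mask_above] = above[mask_above]

    # open-group death counts
    with np.errstate(divide="ignore", invalid="ignore"):
        d_D2[:C] = -(l2[-1] / l2[1 : C + 1]) * (e2[-1] / D2w) * chain
    d_D1[G - 1] = l1[-1] * e1[-1] / D1w
    d_D2[G - 1] = -l1[-1] * e2[-1] / D2w
    return DecompositionJacobian(d_p1=d_p1, d_p2=d_p2, d_D1=d_D1, d_D2=d_D2)


def count_variances(sched1: MortalitySchedule, sched2: MortalitySchedule) -> ParameterVariances:
    """Count-implied parameter variances: binomial for closed-group survival
    probabilities, Poisson (variance = count) for open-group deaths.

    Groups with zero deaths contribute zero variance, with a warning.
    """
    out = []
    for s in (sched1, sched2):
        if not s.has_counts:
            raise ValueError("count-based variances need deaths and exposure")
        lt = build_lifetable(s)
        C = s.grid.n_closed
        D = s.deaths[:C]
        if np.any(D == 0):
            warnings.warn("zero-death groups contribute zero variance", stacklevel=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            var_p = np.where(D > 0, (1.0 - lt.p[:C]) ** 2 * lt.p[:C] / D, 0.0)
        out.append((var_p, float(s.deaths[-1])))
    (vp1, vD1), (vp2, vD2) = out
    return ParameterVariances(var_p1=vp1, var_p2=vp2, var_D1=vD1, var_D2=vD2,
                              source="count-based")


def survey_variances(
    sched1: MortalitySchedule,
    sched2: MortalitySchedule,
    se_scale: str = "rate",
) -> ParameterVariances:
    """Survey-supplied parameter variances from per-group standard errors.

    With ``se_scale='rate'`` the schedules' ``rate_se`` are standard errors of
    the central rates m and are converted to the probability scale through the
    exact derivative dq/dm = n / (1 + (n - a) m)^2; with ``'probability'``
    they are used as standard errors of np directly.  The open group's SE is
    converted to a death-count SE via D = m * N (exposure fixed).
    """
    if se_scale not in ("rate", "probability"):
        raise ValueError("se_scale must be 'rate' or 'probability'")
    out = []
    for s in (sched1, sched2):
        if s.rate_se is None:
            raise ValueError(
                "survey mode needs rate_se on every group; supply standard errors "
                "from the survey estimation software"
            )
        C = s.grid.n_closed
        if se_scale == "rate":
            se_p = dq_dm(s.rates[:C], s.nax[:C], s.grid.widths[:C]) * s.rate_se[:C]
        else:
            se_p = s.rate_se[:C]
        if s.exposure is None:
            raise ValueError("survey mode needs exposure for the open group (D = m * N)")
        se_D = float(s.exposure[-1] * s.rate_se[-1]) if se_scale == "rate" else float(s.rate_se[-1])
        out.append((se_p**2, se_D**2))
    (vp1, vD1), (vp2, vD2) = out
    return ParameterVariances(var_p1=vp1, var_p2=vp2, var_D1=vD1, var_D2=vD2,
                              source="survey-supplied")


def delta_se(jac: DecompositionJacobian, variances: ParameterVariances):
    """Per-age and total standard errors from the Jacobian and variances.

    Returns an :class:`~arriaga.resampling.UncertaintyResult` (without
    replicates) with per-age entries followed by the total.  The total's
    derivative w.r.t. each parameter is the column sum of the per-age
    Jacobian, capturing the covariance across age rows induced by shared
    parameters.
    """
    from .resampling import UncertaintyResult  # local import to avoid a cycle

    def quad(dp1, dp2, dD1, dD2):
        return (
            np.sum(dp1**2 * variances.var_p1, axis=-1)
            + np.sum(dp2**2 * variances.var_p2, axis=-1)
            + dD1**2 * variances.var_D1
            + dD2**2 * variances.var_D2
        )

    var_age = quad(jac.d_p1, jac.d_p2, jac.d_D1, jac.d_D2)
    var_total = float(
        quad(jac.d_p1.sum(axis=0), jac.d_p2.sum(axis=0),
             jac.d_D1.sum(), jac.d_D2.sum())
    )
    se = np.append(np.sqrt(var_age), np.sqrt(var_total))
    labels = [f"age_{i}" for i in range(len(var_age))] + ["total"]
    return UncertaintyResult(
        labels=tuple(labels),
        se=se,
        estimate=None,
        ci_lower=None,
        ci_upper=None,
        method=f"delta ({variances.source})",
        reps=0,
        seed=None,
        ci_level=None,
    )


def decomposition_from_params(
    p1: np.ndarray,
    p2: np.ndarray,
    D1w: float,
    D2w: float,
    a1: np.ndarray,
    a2: np.ndarray,
    widths: np.ndarray,
    N1w: float,
    N2w: float,
) -> np.ndarray:
    """Decomposition as an explicit function of its delta-method parameters.

    Survival probabilities and open-group death counts in, per-age
    contributions out (nax and exposures fixed).  Exists so tests can
    difference it numerically against the closed-form Jacobian.
    """
    widths = np.asarray(widths, dtype=float)
    C = len(p1)

    def cols(p, a, Dw, Nw):
        q = np.append(1.0 - np.asarray(p, dtype=float), 1.0)
        pfull = 1.0 - q
        l = np.concatenate([[1.0], np.cumprod(pfull[:-1])])
        l_next = l * pfull
        mw = Dw / Nw
        with np.errstate(invalid="ignore"):
            L = np.where(np.isinf(widths), l / mw, widths * l_next + a * (l - l_next))
        T = np.cumsum(L[::-1])[::-1]
        return l, L, T / l

    l1, L1, e1 = cols(p1, a1, D1w, N1w)
    l2, L2, e2 = cols(p2, a2, D2w, N2w)
    direct = l1[:C] * (L2[:C] / l2[:C] - L1[:C] / l1[:C])
    indirect = e2[1:] * ((l2[1:] / l2[:C]) * l1[:C] - l1[1:])
    open_grp = l1[-1] * (e2[-1] - e1[-1])
    return np.append(direct + indirect, open_grp)
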