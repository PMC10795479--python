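"""Abridged period life tables with radix 1.

Columns follow the standard construction: the interval death probability is

    nqx = n * nmx / (1 + (n - nax) * nmx)

survivorship l accumulates as a product of np = 1 - nq, person-years are
nLx = n * l(x+n) + nax * (l(x) - l(x+n)) for closed groups and l/m for the
open-ended group (where q = 1 and e = 1/m), and ex = Tx / lx.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schedules import AgeGrid, MortalitySchedule

__all__ = ["LifeTable", "q_from_m", "dq_dm", "build_lifetable", "lifetable_arrays",
           "e0_gradient", "e0_variance_delta"]


def q_from_m(m, a, n):
    """Interval death probability from the central rate.

    Accepts scalars or arrays; values are clamped at 1 (a warning is issued
    for scalar use via :func:`build_lifetable`).  For the open-ended group
    pass ``n = inf`` — the probability is 1 by construction.
    """
    m = np.asarray(m, dtype=float)
    a = np.asarray(a, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore"):
        q = np.where(np.isinf(n), 1.0, n * m / (1.0 + (n - a) * m))
    return np.minimum(q, 1.0)


def dq_dm(m, a, n):
    """Exact derivative of :func:`q_from_m` with respect to the rate."""
    m = np.asarray(m, dtype=float)
    a = np.asarray(a, dtype=float)
    n = np.asarray(n, dtype=float)
    return np.where(np.isinf(n), 0.0, n / (1.0 + (n - a) * m) ** 2)


def lifetable_arrays(m: np.ndarray, a: np.ndarray, n: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised life-table columns for rate arrays of shape ``(..., G)``.

    The leading axes broadcast, which lets resampling engines build thousands
    of replicate life tables in one call.  Degenerate inputs (zero open-group
    rate, closed-group q reaching 1) yield non-finite entries rather than
    raising; strict validation lives in :func:`build_lifetable`.
    """
    m = np.asarray(m, dtype=float)
    q = q_from_m(m, a, n)
    p = 1.0 - q
    # l: radix 1, cumulative product of survival through preceding groups
    l = np.cumprod(p[..., :-1], axis=-1)
    l = np.concatenate([np.ones(l.shape[:-1] + (1,)), l], axis=-1)
    l_next = l * p
    with np.errstate(divide="ignore", invalid="ignore"):
        L = np.where(np.isinf(n), l / m, n * l_next + a * (l - l_next))
        T = np.cumsum(L[..., ::-1], axis=-1)[..., ::-1]
        e = T / l
    return {"q": q, "p": p, "l": l, "L": L, "T": T, "e": e}


@dataclass(frozen=True)
class LifeTable:
    """Derived life-table columns for one population (radix 1)."""

    grid: AgeGrid
    m: np.ndarray
    a: np.ndarray
    q: np.ndarray
    p: np.ndarray
    l: np.ndarray
    L: np.ndarray
    T: np.ndarray
    e: np.ndarray

    @property
    def e0(self) -> float:
        return float(self.e[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.grid.starts,
                "n": self.grid.widths,
                "m": self.m,
                "a": self.a,
                "q": self.q,
                "l": self.l,
                "L": self.L,
                "T": self.T,
                "e": self.e,
            }
        )


def build_lifetable(schedule: MortalitySchedule) -> LifeTable:
    """Construct the abridged life table for a mortality schedule.

    Requires an open-ended final group with a positive rate (otherwise the
    open-group expectancy 1/m is undefined).
    """
    grid = schedule.grid
    if not grid.open_ended:
        raise ValueError("life-table construction requires an open-ended final group")
    if schedule.rates[-1] <= 0:
        raise ValueError("open-group death rate must be positive (e = 1/m undefined)")
    cols = lifetable_arrays(schedule.rates, schedule.nax, grid.widths)
    closed = slice(0, grid.n_closed)
    raw_q = grid.widths[closed] * schedule.rates[closed] / (
        1.0 + (grid.widths[closed] - schedule.nax[closed]) * schedule.rates[closed]
    )
    if np.any(raw_q > 1.0):
        warnings.warn("death probability clamped at 1 for extreme rates", stacklevel=2)
    return LifeTable(grid=grid, m=schedule.rates, a=schedule.nax, **cols)


def e0_gradient(lt: LifeTable, deaths_open: float) -> tuple[np.ndarray, float]:
    """Gradient of e0 with respect to the closed-group survival probabilities
    and the open-group death count (exposure held fixed).

    de0/dp_i = l_i * ((n_i - a_i) + e_{i+n});  de0/dD_omega = -l_w * e_w / D_w.
    """
    C = lt.grid.n_closed
    n = lt.grid.widths[:C]
    grad_p = lt.l[:C] * ((n - lt.a[:C]) + lt.e[1 : C + 1])
    grad_D = -float(lt.l[-1] * lt.e[-1] / deaths_open)
    return grad_p, grad_D


def e0_variance_delta(schedule: MortalitySchedule) -> float:
    """Delta-method variance of a single life expectancy at birth.

    Uses binomial variance (1-p)^2 * p / D for each closed-group survival
    probability and Poisson variance (= the count) for open-group deaths.
    Groups with zero deaths contribute zero variance (with a warning).  This
    is an independent single-population quantity used to cross-check the
    decomposition total's standard error.
    """
    if not schedule.has_counts:
        raise ValueError("delta variance of e0 needs death counts")
    lt = build_lifetable(schedule)
    C = schedule.grid.n_closed
    D = schedule.deaths
    if np.any(D[:C] == 0):
        warnings.warn("zero-death groups contribute zero variance to e0", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_p = np.where(D[:C] > 0, (1.0 - lt.p[:C]) ** 2 * lt.p[:C] / D[:C], 0.0)
    grad_p, grad_D = e0_gradient(lt, float(D[-1]))
    return float(np.sum(grad_p**2 * var_p) + grad_D**2 * float(D[-1]))
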