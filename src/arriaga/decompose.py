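"""Arriaga's decomposition of a life-expectancy difference.

The change e0(2) - e0(1) between two populations is attributed additively to
age groups.  For a closed group the contribution combines a direct effect
(extra person-years lived within the interval) and an indirect/interaction
effect (survivors added to later ages):

    Dx = l1(x) * (L2(x)/l2(x) - L1(x)/l1(x))
         + e2(x+n) * (p2(x) * l1(x) - l1(x+n))        [radix 1]

and the open-ended group contributes l1(w) * (e2(w) - e1(w)).  The
contributions sum exactly to the difference in life expectancy at birth.

A cause-of-death split distributes each age contribution across causes in
proportion to the cause-specific rate changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lifetable import LifeTable, lifetable_arrays
from .schedules import AgeGrid, CauseSchedule

__all__ = [
    "AgeDecomposition",
    "CauseDecomposition",
    "arriaga_decompose",
    "arriaga_from_rates",
    "cause_decompose",
]


@dataclass(frozen=True)
class AgeDecomposition:
    """Per-age contributions to the change in e0 from population 1 to 2."""

    grid: AgeGrid
    contributions: np.ndarray
    direction: tuple[str, str] = ("pop1", "pop2")

    @property
    def total(self) -> float:
        return float(self.contributions.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.grid.starts, "n": self.grid.widths, "contribution": self.contributions}
        )


@dataclass(frozen=True)
class CauseDecomposition:
    """Age-by-cause contribution matrix; rows sum to the age contributions."""

    grid: AgeGrid
    contributions: np.ndarray  # (age groups, causes)
    labels: tuple[str, ...]
    direction: tuple[str, str] = ("pop1", "pop2")

    @property
    def by_age(self) -> np.ndarray:
        return self.contributions.sum(axis=1)

    @property
    def total(self) -> float:
        return float(self.contributions.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.contributions, columns=list(self.labels))
        df.insert(0, "age", self.grid.starts)
        df.insert(1, "n", self.grid.widths)
        return df


def _contributions(l1, L1, e1, l2, L2, e2) -> np.ndarray:
    """Vectorised Arriaga contributions from life-table columns (..., G)."""
    l1n = l1[..., 1:]  # l1 at x+n for closed groups
    e2n = e2[..., 1:]  # e2 at x+n for closed groups
    p2 = l2[..., 1:] / l2[..., :-1]  # closed-group survival probabilities, pop 2
    direct = l1[..., :-1] * (L2[..., :-1] / l2[..., :-1] - L1[..., :-1] / l1[..., :-1])
    indirect = e2n * (p2 * l1[..., :-1] - l1n)
    open_grp = l1[..., -1:] * (e2[..., -1:] - e1[..., -1:])
    return np.concatenate([direct + indirect, open_grp], axis=-1)


def arriaga_from_rates(m1, a1, m2, a2, widths) -> np.ndarray:
    """Decomposition contributions straight from rate arrays of shape (..., G).

    The workhorse for resampling engines: leading axes broadcast, so one call
    evaluates the decomposition for a whole stack of replicate schedules.
    """
    lt1 = lifetable_arrays(m1, a1, widths)
    lt2 = lifetable_arrays(m2, a2, widths)
    return _contributions(lt1["l"], lt1["L"], lt1["e"],
                          lt2["l"], lt2["L"], lt2["e"])


def arriaga_decompose(lt1: LifeTable, lt2: LifeTable) -> AgeDecomposition:
    """Decompose e0(lt2) - e0(lt1) into age-group contributions.

    Population 1 is the baseline; reversing the arguments negates the total.
    """
    if lt1.grid != lt2.grid:
        raise ValueError("life tables must share the same age grid")
    contrib = _contributions(lt1.l, lt1.L, lt1.e, lt2.l, lt2.L, lt2.e)
    return AgeDecomposition(grid=lt1.grid, contributions=contrib)


def cause_split_ratios(dm_cause: np.ndarray, dm_all: np.ndarray, dx: np.ndarray,
                       atol: float = 1e-15) -> np.ndarray:
    """Share of each age contribution assigned to each cause.

    ratio[x, i] = (m2_xi - m1_xi) / (m2_x - m1_x).  Where the all-cause rate
    change vanishes the ratio is 0/0: if the age contribution is itself ~0 the
    whole row is set to zero; otherwise the split is genuinely undefined and
    an error is raised rather than returning unstable ratios.
    """
    dm_all = np.asarray(dm_all, dtype=float)
    tiny = np.abs(dm_all) < atol
    if np.any(tiny & (np.abs(dx) > 1e-10)):
        bad = int(np.argmax(tiny & (np.abs(dx) > 1e-10)))
        raise ZeroDivisionError(
            f"all-cause rate change ~0 but age contribution is not (group index {bad}); "
            "cause split undefined"
        )
    denom = np.where(tiny, 1.0, dm_all)
    ratios = dm_cause / denom[:, None]
    ratios[tiny, :] = 0.0
    return ratios


def cause_decompose(
    age_result: AgeDecomposition,
    causes1: CauseSchedule,
    causes2: CauseSchedule,
) -> CauseDecomposition:
    """Split each age contribution across causes of death.

    Dxi = Dx * (m2_xi - m1_xi) / (m2_x - m1_x); the shares sum to 1 by
    construction so rows sum back to the age contributions.
    """
    if causes1.schedule.grid != age_result.grid or causes2.schedule.grid != age_result.grid:
        raise ValueError("cause schedules must share the decomposition's age grid")
    if causes1.labels != causes2.labels:
        raise ValueError("cause labels must match between populations")
    dm_cause = causes2.cause_rates - causes1.cause_rates
    dm_all = causes2.schedule.rates - causes1.schedule.rates
    ratios = cause_split_ratios(dm_cause, dm_all, age_result.contributions)
    contrib = age_result.contributions[:, None] * ratios
    return CauseDecomposition(
        grid=age_result.grid,
        contributions=contrib,
        labels=causes1.labels,
        direction=age_result.direction,
    )
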