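"""Domain types for abridged mortality schedules.

An abridged mortality schedule is the raw material of period life-table
analysis: an age grid (0, 1-4, 5-9, ..., 85+), death counts and person-years
of exposure (or central death rates directly), and the separation factors
``nax`` giving the average person-years lived within an interval by those who
die in it.  The final group is open-ended (no upper bound), where the
probability of dying is 1 and deaths are modelled as Poisson.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AgeGrid",
    "MortalitySchedule",
    "CauseSchedule",
    "default_nax",
]

_REL_TOL = 1e-12


@dataclass(frozen=True)
class AgeGrid:
    """Ordered age groups ``[start, start+n)`` with an optional open final group.

    Parameters
    ----------
    starts
        Exact starting ages in years, strictly increasing.
    widths
        Interval widths in years; ``np.inf`` for the open-ended group, which
        may only be the last one.
    """

    starts: np.ndarray
    widths: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        widths = np.asarray(self.widths, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "widths", widths)
        if starts.ndim != 1 or widths.shape != starts.shape:
            raise ValueError("starts and widths must be 1-D arrays of equal length")
        if len(starts) < 2:
            raise ValueError("an age grid needs at least two groups")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("age-group starts must be strictly increasing")
        if np.any(widths[:-1] <= 0) or np.any(np.isinf(widths[:-1])):
            raise ValueError("only the last age group may be open-ended")
        if widths[-1] <= 0:
            raise ValueError("final width must be positive or infinite")
        closed = widths[:-1]
        if not np.allclose(starts[:-1] + closed, starts[1:], rtol=0, atol=1e-9):
            raise ValueError("age groups must be contiguous: starts[k+1] = starts[k] + widths[k]")

    @property
    def open_ended(self) -> bool:
        return bool(np.isinf(self.widths[-1]))

    @property
    def n_groups(self) -> int:
        return len(self.starts)

    @property
    def n_closed(self) -> int:
        return self.n_groups - 1 if self.open_ended else self.n_groups

    @classmethod
    def abridged(cls, open_age: float = 85.0) -> "AgeGrid":
        """Standard abridged grid 0, 1-4, 5-9, ..., ``open_age``+."""
        starts = [0.0, 1.0] + list(np.arange(5.0, open_age + 1e-9, 5.0))
        widths = [1.0, 4.0] + [5.0] * (len(starts) - 3) + [np.inf]
        return cls(np.array(starts), np.array(widths))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AgeGrid):
            return NotImplemented
        return bool(
            np.array_equal(self.starts, other.starts)
            and np.array_equal(self.widths, other.widths)
        )


def default_nax(grid: AgeGrid, m: np.ndarray) -> np.ndarray:
    """Fallback separation factors when a schedule supplies none.

    Mid-interval (n/2) everywhere except the first two groups of a grid
    starting at birth, where infant deaths cluster early in the interval:
    a0 = 0.07 + 1.7 * m0 (clamped to (0, 1)) and a(1-4) = 1.5.  These are
    conventional values for synthetic or exploratory data; observed nax
    should be supplied whenever available.  The open group carries NaN
    (its person-years come from l/m, no separation factor involved).
    """
    a = np.asarray(grid.widths, dtype=float) / 2.0
    if grid.starts[0] == 0.0 and grid.widths[0] == 1.0:
        a[0] = min(max(0.07 + 1.7 * float(m[0]), 1e-6), 1.0 - 1e-9)
        if grid.n_groups > 1 and grid.widths[1] == 4.0:
            a[1] = 1.5
    if grid.open_ended:
        a[-1] = np.nan
    return a


@dataclass(frozen=True)
class MortalitySchedule:
    """One population's mortality inputs on an age grid.

    Either supply ``deaths`` and ``exposure`` (rates are derived) or ``rates``
    directly (optionally with per-group standard errors, the survey case).
    ``nax`` applies to closed groups only; the open group's entry is ignored.
    """

    grid: AgeGrid
    rates: np.ndarray
    nax: np.ndarray
    deaths: np.ndarray | None = None
    exposure: np.ndarray | None = None
    rate_se: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        G = self.grid.n_groups
        rates = np.asarray(self.rates, dtype=float)
        nax = np.asarray(self.nax, dtype=float)
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "nax", nax)
        for attr in ("deaths", "exposure", "rate_se"):
            v = getattr(self, attr)
            if v is not None:
                object.__setattr__(self, attr, np.asarray(v, dtype=float))
        if rates.shape != (G,) or nax.shape != (G,):
            raise ValueError("rates and nax must have one entry per age group")
        if np.any(~np.isfinite(rates)) or np.any(rates < 0):
            raise ValueError("rates must be finite and non-negative")
        if self.exposure is not None and np.any(self.exposure <= 0):
            bad = int(np.argmax(self.exposure <= 0))
            raise ValueError(f"exposure must be positive (group starting at age {self.grid.starts[bad]:g})")
        if self.deaths is not None:
            if np.any(self.deaths < 0):
                bad = int(np.argmax(self.deaths < 0))
                raise ValueError(f"negative death count (group starting at age {self.grid.starts[bad]:g})")
            if self.exposure is None:
                raise ValueError("deaths without exposure: supply exposure or rates only")
            implied = self.deaths / self.exposure
            scale = np.maximum(np.abs(rates), 1e-300)
            if np.any(np.abs(implied - rates) > _REL_TOL * np.maximum(scale, 1.0)):
                raise ValueError("rates inconsistent with deaths/exposure")
            if np.any(self.deaths == 0):
                warnings.warn(
                    "schedule has age groups with zero deaths; no variance engine "
                    "assigns positive variance there",
                    stacklevel=2,
                )
        closed = slice(0, self.grid.n_closed)
        n_closed = self.grid.widths[closed]
        a_closed = nax[closed]
        if np.any(~np.isfinite(a_closed)) or np.any(a_closed <= 0) or np.any(a_closed > n_closed):
            raise ValueError("nax must satisfy 0 < nax <= n for closed groups")
        if self.rate_se is not None:
            if self.rate_se.shape != (G,):
                raise ValueError("rate_se must have one entry per age group")
            if np.any(self.rate_se < 0):
                raise ValueError("rate_se must be non-negative")

    @classmethod
    def from_counts(
        cls,
        grid: AgeGrid,
        deaths: np.ndarray,
        exposure: np.ndarray,
        nax: np.ndarray | None = None,
        name: str = "",
    ) -> "MortalitySchedule":
        deaths = np.asarray(deaths, dtype=float)
        exposure = np.asarray(exposure, dtype=float)
        if np.any(exposure <= 0):
            bad = int(np.argmax(exposure <= 0))
            raise ValueError(f"exposure must be positive (group starting at age {grid.starts[bad]:g})")
        rates = deaths / exposure
        if nax is None:
            nax = default_nax(grid, rates)
        return cls(grid=grid, rates=rates, nax=np.asarray(nax, dtype=float),
                   deaths=deaths, exposure=exposure, name=name)

    @classmethod
    def from_rates(
        cls,
        grid: AgeGrid,
        rates: np.ndarray,
        nax: np.ndarray | None = None,
        rate_se: np.ndarray | None = None,
        exposure: np.ndarray | None = None,
        name: str = "",
    ) -> "MortalitySchedule":
        rates = np.asarray(rates, dtype=float)
        if nax is None:
            nax = default_nax(grid, rates)
        deaths = rates * exposure if exposure is not None else None
        return cls(grid=grid, rates=rates, nax=np.asarray(nax, dtype=float),
                   deaths=deaths, exposure=np.asarray(exposure, dtype=float) if exposure is not None else None,
                   rate_se=rate_se, name=name)

    def with_exposure(self, exposure: np.ndarray) -> "MortalitySchedule":
        """Attach (or replace) exposures, recomputing deaths = rate * exposure."""
        exposure = np.asarray(exposure, dtype=float)
        return replace(self, exposure=exposure, deaths=self.rates * exposure)

    @property
    def has_counts(self) -> bool:
        return self.deaths is not None and self.exposure is not None


@dataclass(frozen=True)
class CauseSchedule:
    """A mortality schedule with its deaths split by cause.

    ``cause_deaths`` has shape (age groups, causes) and must sum across
    causes to the schedule's all-cause deaths.
    """

    schedule: MortalitySchedule
    cause_deaths: np.ndarray
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        cd = np.asarray(self.cause_deaths, dtype=float)
        object.__setattr__(self, "cause_deaths", cd)
        G = self.schedule.grid.n_groups
        if cd.ndim != 2 or cd.shape[0] != G:
            raise ValueError("cause_deaths must be (age groups, causes)")
        if not self.labels:
            object.__setattr__(self, "labels", tuple(f"cause_{i}" for i in range(cd.shape[1])))
        elif len(self.labels) != cd.shape[1]:
            raise ValueError("one label per cause required")
        if np.any(cd < 0):
            raise ValueError("cause deaths must be non-negative")
        if self.schedule.deaths is None:
            raise ValueError("cause splits need a schedule with death counts")
        totals = cd.sum(axis=1)
        if np.any(np.abs(totals - self.schedule.deaths) > 1e-9 * np.maximum(1.0, self.schedule.deaths)):
            raise ValueError("cause deaths must sum to all-cause deaths in every age group")

    @property
    def n_causes(self) -> int:
        return self.cause_deaths.shape[1]

    @property
    def cause_rates(self) -> np.ndarray:
        """Per-(age, cause) death rates nDxi / nNx."""
        return self.cause_deaths / self.schedule.exposure[:, None]
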