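"""Synthetic mortality schedules from a smooth parametric hazard.

The generator emulates the inputs every engine in this package consumes: a
Gompertz–Makeham force of mortality

    mu(x) = c + b * exp(theta * x) + h * exp(-k * x)

(the last term is an optional infant-mortality bump), integrated to exact
group-average central rates, with death counts drawn Poisson or binomial
around their expectations.  Defaults are tuned to a contemporary low-mortality
female population (e0 around 84) at exposures giving hundreds of deaths per
age group, the regime of the vital-statistics worked example.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lifetable import q_from_m
from .schedules import AgeGrid, MortalitySchedule, default_nax

__all__ = ["HazardParams", "synth_schedule", "group_rates_from_hazard", "synth_microdata"]

_OPEN_CAP = 130.0  # integration cap (years) standing in for infinity
_STEPS_PER_YEAR = 32


@dataclass(frozen=True)
class HazardParams:
    """Gompertz–Makeham parameters plus an infant bump (per-year hazard)."""

    makeham: float = 2.0e-4       # age-independent background hazard c
    gompertz_level: float = 3.0e-5  # senescent hazard b at age 0
    gompertz_slope: float = 0.095   # exponential rate of ageing theta
    infant_level: float = 0.025     # bump height h at exact age 0
    infant_decay: float = 4.0       # per-year decay k of the bump

    def hazard(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        mu = (
            self.makeham
            + self.gompertz_level * np.exp(self.gompertz_slope * x)
            + self.infant_level * np.exp(-self.infant_decay * x)
        )
        return mu

    def validate(self) -> None:
        x = np.linspace(0.0, _OPEN_CAP, 1024)
        if np.any(self.hazard(x) < 0):
            raise ValueError("hazard parameters produce a negative force of mortality")


def group_rates_from_hazard(params: HazardParams, grid: AgeGrid) -> np.ndarray:
    """Exact (quadrature) stationary-population central death rates per group.

    m = integral of mu * S over the interval / integral of S, with survival
    S(x) = exp(-integral of mu), evaluated on a fine midpoint grid; the open
    group integrates to an age cap far beyond any surviving mass.
    """
    params.validate()
    h = 1.0 / _STEPS_PER_YEAR
    xs = np.arange(0.0, _OPEN_CAP, h) + h / 2.0
    mu = params.hazard(xs)
    # survival at midpoints via cumulative hazard (midpoint rule)
    H = np.concatenate([[0.0], np.cumsum(mu * h)])
    S_mid = np.exp(-(H[:-1] + mu * h / 2.0))
    bounds = np.append(grid.starts, _OPEN_CAP if grid.open_ended else grid.starts[-1] + grid.widths[-1])
    rates = np.empty(grid.n_groups)
    for k in range(grid.n_groups):
        sel = (xs >= bounds[k]) & (xs < bounds[k + 1])
        deaths = np.sum(mu[sel] * S_mid[sel])
        expo = np.sum(S_mid[sel])
        rates[k] = deaths / expo
    return rates


def synth_schedule(
    grid: AgeGrid,
    exposure: np.ndarray,
    params: HazardParams | None = None,
    noise: str = "poisson",
    seed: int | None = None,
    nax: np.ndarray | None = None,
    name: str = "synthetic",
) -> MortalitySchedule:
    """Draw a synthetic mortality schedule around the hazard's true rates.

    ``noise='none'`` returns the exact expectations (deaths = N * m);
    ``'poisson'`` draws deaths ~ Poisson(N * m); ``'binomial'`` draws
    deaths ~ Binomial(round(N * m / q), q) per closed group with a Poisson
    open group.  A fixed seed reproduces the schedule bit for bit.
    """
    params = params or HazardParams()
    exposure = np.asarray(exposure, dtype=float)
    if np.any(exposure <= 0):
        raise ValueError("exposures must be positive")
    true_m = group_rates_from_hazard(params, grid)
    lam = exposure * true_m
    if noise == "none":
        deaths = lam
    else:
        if seed is None:
            raise ValueError("a seed is required for noisy draws")
        rng = np.random.default_rng(seed)
        if noise == "poisson":
            deaths = rng.poisson(lam).astype(float)
        elif noise == "binomial":
            a = nax if nax is not None else default_nax(grid, true_m)
            C = grid.n_closed
            q = q_from_m(true_m[:C], np.asarray(a)[:C], grid.widths[:C])
            trials = np.maximum(np.round(lam[:C] / q), 1).astype(np.int64)
            closed = rng.binomial(trials, q).astype(float)
            deaths = np.append(closed, rng.poisson(lam[-1]))
        else:
            raise ValueError("noise must be 'none', 'poisson', or 'binomial'")
    rates = deaths / exposure
    a = nax if nax is not None else default_nax(grid, np.where(rates > 0, rates, true_m))
    return MortalitySchedule(
        grid=grid, rates=rates, nax=np.asarray(a, dtype=float),
        deaths=deaths, exposure=exposure, name=name,
    )


def synth_microdata(
    grid: AgeGrid,
    n_records: int,
    death_prob: np.ndarray,
    seed: int,
    person_years: np.ndarray | None = None,
) -> pd.DataFrame:
    """Person-level rows for the delete-one jackknife: each record carries an
    age-group start, a Bernoulli death flag, and its person-years of exposure
    (group width by default, halved for decedents).

    ``death_prob`` gives the per-record death probability per age group —
    deliberately a free dial, since jackknife fixtures need far higher
    per-record risk than real populations to keep N modest.
    """
    rng = np.random.default_rng(seed)
    G = grid.n_groups
    death_prob = np.broadcast_to(np.asarray(death_prob, dtype=float), (G,))
    groups = rng.integers(0, G, size=n_records)
    deaths = rng.random(n_records) < death_prob[groups]
    widths = np.where(np.isinf(grid.widths), 5.0, grid.widths)
    if person_years is None:
        person_years = np.where(deaths, widths[groups] / 2.0, widths[groups])
    return pd.DataFrame(
        {
            "age_start": grid.starts[groups],
            "death": deaths.astype(int),
            "exposure": person_years,
        }
    )
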