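"""Bundled example data: mortality of women in the urban Pacific region of
the United States, 1990 and 2019 (a published 50% vital-statistics sample).

Only central death rates and separation factors are published for this
example; the underlying death and population counts are not.  Variance
engines need counts, so the loaders can attach a SYNTHETIC exposure profile
(person-years per age group) at a scale plausible for that population, from
which deaths are reconstructed as rate * exposure.  This fixes the absolute
scale of standard errors but leaves every cross-method comparison meaningful,
since all engines see the same counts.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .io import read_schedule
from .schedules import MortalitySchedule

__all__ = ["urban_pacific_women", "SYNTHETIC_EXPOSURE"]

# Synthetic person-years by age group (0, 1-4, 5-9, ..., 80-84, 85+) for a
# 50% sample of urban Pacific-region U.S. women; chosen once as a plausible
# population profile, not fitted to anything.
SYNTHETIC_EXPOSURE = np.array(
    [
        110_000, 450_000, 550_000, 520_000, 530_000, 600_000, 650_000,
        640_000, 600_000, 550_000, 480_000, 420_000, 370_000, 330_000,
        290_000, 250_000, 200_000, 140_000, 90_000,
    ],
    dtype=float,
)


def urban_pacific_women(year: int, with_exposure: bool = False) -> MortalitySchedule:
    """Load the 1990 or 2019 published schedule (rates and nax).

    With ``with_exposure=True`` the synthetic exposure profile is attached so
    that count-based variance engines can run; deaths are then rate * N and
    generally non-integer.
    """
    if year not in (1990, 2019):
        raise ValueError("bundled example covers the years 1990 and 2019")
    ref = resources.files("arriaga.data") / f"urban_pacific_women_{year}.csv"
    with resources.as_file(ref) as path:
        sched = read_schedule(path, name=f"urban_pacific_women_{year}")
    if with_exposure:
        sched = sched.with_exposure(SYNTHETIC_EXPOSURE)
    return sched
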