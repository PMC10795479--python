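import numpy as np
import pytest

import arriaga as ar

# Printed worked-example columns (urban Pacific U.S. women), used as frozen
# expected values: age, n, then m, a, q, l, L for 1990 and 2019, and the
# per-age decomposition contribution.
TABLE1 = np.array([
    # age n   m90       a90       q90       l90       L90       m19       a19       q19       l19       L19       contrib
    [0,  1, 0.007655, 0.074435, 0.007601, 1.000000, 0.992964, 0.003609, 0.063104, 0.003596, 1.000000, 0.996631, 0.34],
    [1,  4, 0.000433, 1.510379, 0.001730, 0.992399, 3.965320, 0.000175, 1.516522, 0.000698, 0.996404, 3.983887, 0.08],
    [5,  5, 0.000185, 2.500000, 0.000926, 0.990682, 4.951116, 0.000118, 2.500000, 0.000588, 0.995708, 4.977077, 0.03],
    [10, 5, 0.000224, 2.698390, 0.001119, 0.989765, 4.946274, 0.000109, 2.673004, 0.000546, 0.995123, 4.974350, 0.04],
    [15, 5, 0.000399, 2.625958, 0.001994, 0.988657, 4.938605, 0.000208, 2.717355, 0.001042, 0.994580, 4.970533, 0.06],
    [20, 5, 0.000467, 2.560885, 0.002330, 0.986685, 4.927819, 0.000327, 2.599822, 0.001635, 0.993543, 4.963819, 0.04],
    [25, 5, 0.000538, 2.609242, 0.002686, 0.984386, 4.915609, 0.000366, 2.632594, 0.001829, 0.991919, 4.955300, 0.05],
    [30, 5, 0.000752, 2.645253, 0.003754, 0.981742, 4.900032, 0.000562, 2.652385, 0.002807, 0.990105, 4.944000, 0.05],
    [35, 5, 0.001069, 2.651170, 0.005331, 0.978056, 4.878036, 0.000781, 2.646976, 0.003897, 0.987326, 4.927576, 0.07],
    [40, 5, 0.001541, 2.706326, 0.007677, 0.972843, 4.847083, 0.001120, 2.649646, 0.005585, 0.983479, 4.904482, 0.09],
    [45, 5, 0.002628, 2.706583, 0.013063, 0.965374, 4.797949, 0.001600, 2.669022, 0.007968, 0.977985, 4.871762, 0.19],
    [50, 5, 0.004234, 2.670296, 0.020964, 0.952764, 4.717286, 0.002449, 2.688760, 0.012179, 0.970193, 4.823654, 0.29],
    [55, 5, 0.006295, 2.681929, 0.031022, 0.932790, 4.596873, 0.003895, 2.677877, 0.019302, 0.958377, 4.748930, 0.33],
    [60, 5, 0.010252, 2.655346, 0.050056, 0.903853, 4.413187, 0.005957, 2.648850, 0.029376, 0.939879, 4.634479, 0.48],
    [65, 5, 0.015119, 2.644060, 0.072993, 0.858610, 4.145398, 0.008548, 2.662720, 0.041901, 0.912269, 4.472003, 0.58],
    [70, 5, 0.023492, 2.640862, 0.111291, 0.795938, 3.770714, 0.013564, 2.673357, 0.065747, 0.874044, 4.236520, 0.65],
    [75, 5, 0.037778, 2.614471, 0.173272, 0.707357, 3.244402, 0.022154, 2.685871, 0.105370, 0.816579, 3.883780, 0.69],
    [80, 5, 0.061530, 2.500000, 0.266634, 0.584792, 2.534146, 0.040466, 2.500000, 0.183743, 0.730536, 3.317103, 0.56],
    [85, np.inf, 0.151531, np.nan, 1.000000, 0.428867, 2.830227, 0.110591, np.nan, 1.000000, 0.596305, 5.391965, 1.05],
])

E0_1990, E0_2019, TOTAL_CHANGE = 79.31, 84.98, 5.66


@pytest.fixture(scope="session")
def pacific_pair():
    """The bundled 1990/2019 example with its synthetic exposure profile."""
    return (ar.urban_pacific_women(1990, with_exposure=True),
            ar.urban_pacific_women(2019, with_exposure=True))


@pytest.fixture(scope="session")
def pacific_lifetables(pacific_pair):
    s1, s2 = pacific_pair
    return ar.build_lifetable(s1), ar.build_lifetable(s2)


def random_schedule_pair(seed: int, exposure_scale: float = 200_000.0):
    """A reproducible pair of noisy synthetic schedules on the standard grid."""
    grid = ar.AgeGrid.abridged(85.0)
    expo = np.full(grid.n_groups, exposure_scale)
    hp1 = ar.HazardParams()
    hp2 = ar.HazardParams(makeham=3.5e-4, gompertz_level=5.0e-5,
                          gompertz_slope=0.092, infant_level=0.045)
    s1 = ar.synth_schedule(grid, expo, hp1, noise="poisson", seed=seed)
    s2 = ar.synth_schedule(grid, expo, hp2, noise="poisson", seed=seed + 1_000_000)
    return s1, s2
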