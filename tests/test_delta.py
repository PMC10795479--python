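"""Delta-method Jacobian and standard errors, validated against central
finite differences of the implemented decomposition and against simulation."""

import numpy as np
import pytest

import arriaga as ar
from arriaga.delta import decomposition_from_params, jacobian
from arriaga.lifetable import lifetable_arrays

from conftest import random_schedule_pair


def fd_jacobian(s1, s2, h_p=1e-6, h_D=1.0):
    """Central finite differences of the decomposition w.r.t. each survival
    probability and the open-group death counts (the independent oracle)."""
    lt1, lt2 = ar.build_lifetable(s1), ar.build_lifetable(s2)
    C = s1.grid.n_closed
    G = s1.grid.n_groups
    p1, p2 = lt1.p[:C].copy(), lt2.p[:C].copy()
    D1, D2 = float(s1.deaths[-1]), float(s2.deaths[-1])
    kw = dict(a1=s1.nax, a2=s2.nax, widths=s1.grid.widths,
              N1w=float(s1.exposure[-1]), N2w=float(s2.exposure[-1]))

    def f(pa, pb, Da, Db):
        return decomposition_from_params(pa, pb, Da, Db, **kw)

    d_p1 = np.empty((G, C))
    d_p2 = np.empty((G, C))
    for i in range(C):
        e = np.zeros(C); e[i] = h_p
        d_p1[:, i] = (f(p1 + e, p2, D1, D2) - f(p1 - e, p2, D1, D2)) / (2 * h_p)
        d_p2[:, i] = (f(p1, p2 + e, D1, D2) - f(p1, p2 - e, D1, D2)) / (2 * h_p)
    d_D1 = (f(p1, p2, D1 + h_D, D2) - f(p1, p2, D1 - h_D, D2)) / (2 * h_D)
    d_D2 = (f(p1, p2, D1, D2 + h_D) - f(p1, p2, D1, D2 - h_D)) / (2 * h_D)
    return d_p1, d_p2, d_D1, d_D2


def assert_jacobian_close(jac, fd, rel=1e-5):
    for analytic, numeric in zip((jac.d_p1, jac.d_p2, jac.d_D1, jac.d_D2), fd):
        # relative tolerance with an absolute floor tied to the block's scale,
        # so FD roundoff at the exact zeros doesn't masquerade as error
        floor = 1e-7 * max(np.abs(numeric).max(), 1e-12)
        np.testing.assert_allclose(analytic, numeric, rtol=rel, atol=floor)


class TestJacobian:
    def test_params_function_reproduces_decomposition(self, pacific_pair, pacific_lifetables):
        s1, s2 = pacific_pair
        lt1, lt2 = pacific_lifetables
        C = s1.grid.n_closed
        base = decomposition_from_params(
            lt1.p[:C], lt2.p[:C], s1.deaths[-1], s2.deaths[-1],
            s1.nax, s2.nax, s1.grid.widths, s1.exposure[-1], s2.exposure[-1])
        np.testing.assert_allclose(
            base, ar.arriaga_decompose(lt1, lt2).contributions, atol=1e-13)

    def test_diagonal_entry_closed_form(self, pacific_pair, pacific_lifetables):
        # d(Dx)/d(px1) at x = i is -l1(x) * ((n - a1(x)) + e2(x+n))
        s1, s2 = pacific_pair
        lt1, lt2 = pacific_lifetables
        jac = jacobian(lt1, lt2, s1.deaths[-1], s2.deaths[-1])
        x = 10
        expected = -lt1.l[x] * ((5.0 - s1.nax[x]) + lt2.e[x + 1])
        assert jac.d_p1[x, x] == pytest.approx(expected, rel=1e-12)

    def test_diagonals_negate_for_identical_populations(self, pacific_pair, pacific_lifetables):
        s1, _ = pacific_pair
        lt1, _ = pacific_lifetables
        jac = jacobian(lt1, lt1, s1.deaths[-1], s1.deaths[-1])
        diag1 = np.diag(jac.d_p1[:18])
        diag2 = np.diag(jac.d_p2[:18])
        np.testing.assert_allclose(diag1, -diag2, rtol=1e-12)

    def test_sparsity_pattern_is_exact(self, pacific_pair, pacific_lifetables):
        s1, s2 = pacific_pair
        lt1, lt2 = pacific_lifetables
        jac = jacobian(lt1, lt2, s1.deaths[-1], s2.deaths[-1])
        C = 18
        x, i = np.mgrid[0:C, 0:C]
        assert np.all(jac.d_p1[:C][x < i] == 0.0)
        assert np.all(jac.d_p2[:C][x > i] == 0.0)
        assert np.all(jac.d_p2[C] == 0.0)   # open row, pop 2 probabilities
        assert np.all(jac.d_D1[:C] == 0.0)  # pop-1 open deaths touch only the open row

    def test_matches_finite_differences_on_example(self, pacific_pair, pacific_lifetables):
        s1, s2 = pacific_pair
        lt1, lt2 = pacific_lifetables
        jac = jacobian(lt1, lt2, s1.deaths[-1], s2.deaths[-1])
        assert_jacobian_close(jac, fd_jacobian(s1, s2))

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_finite_differences_on_random_pairs(self, seed):
        s1, s2 = random_schedule_pair(900 + seed, exposure_scale=150_000.0)
        lt1, lt2 = ar.build_lifetable(s1), ar.build_lifetable(s2)
        jac = jacobian(lt1, lt2, s1.deaths[-1], s2.deaths[-1])
        assert_jacobian_close(jac, fd_jacobian(s1, s2))


class TestCountVariances:
    def test_binomial_form(self, pacific_pair, pacific_lifetables):
        s1, s2 = pacific_pair
        lt1, _ = pacific_lifetables
        v = ar.count_variances(s1, s2)
        expected = (1 - lt1.p[:18]) ** 2 * lt1.p[:18] / s1.deaths[:18]
        np.testing.assert_allclose(v.var_p1, expected, rtol=1e-12)
        assert v.var_D1 == s1.deaths[-1]
        assert v.source == "count-based"

    def test_certain_survival_has_zero_variance(self):
        grid = ar.AgeGrid.abridged(85.0)
        deaths = np.full(19, 100.0)
        deaths[6] = 0.0  # p = 1 in that group
        with pytest.warns(UserWarning):
            s = ar.MortalitySchedule.from_counts(grid, deaths, np.full(19, 1e5))
        with pytest.warns(UserWarning, match="zero"):
            v = ar.count_variances(s, s)
        assert v.var_p1[6] == 0.0

    def test_doubling_counts_halves_variance(self, pacific_pair):
        s1, s2 = pacific_pair
        big = ar.MortalitySchedule.from_counts(s1.grid, s1.deaths * 2, s1.exposure * 2,
                                               nax=s1.nax)
        v1 = ar.count_variances(s1, s2)
        v2 = ar.count_variances(big, s2)
        np.testing.assert_allclose(v2.var_p1, v1.var_p1 / 2, rtol=1e-12)

    def test_matches_empirical_binomial_simulation(self):
        # simulation oracle for var(p-hat) at worked-example scale
        s1, _ = random_schedule_pair(5)
        lt = ar.build_lifetable(s1)
        v = ar.count_variances(s1, s1)
        rng = np.random.default_rng(99)
        C, x = 18, 13
        trials = int(round(s1.deaths[x] / lt.q[x]))
        draws = rng.binomial(trials, lt.q[x], size=5000) / trials
        assert draws.var(ddof=1) == pytest.approx(v.var_p1[x], rel=0.10)


class TestSurveyVariances:
    def test_probability_scale_consistency_with_counts(self, pacific_pair):
        # survey SEs numerically equal to the binomial-implied ones must
        # reproduce count_variances exactly
        import dataclasses
        s1, s2 = pacific_pair
        cv = ar.count_variances(s1, s2)
        se1 = np.append(np.sqrt(cv.var_p1), np.sqrt(cv.var_D1))
        se2 = np.append(np.sqrt(cv.var_p2), np.sqrt(cv.var_D2))
        t1 = dataclasses.replace(s1, rate_se=se1)
        t2 = dataclasses.replace(s2, rate_se=se2)
        sv = ar.survey_variances(t1, t2, se_scale="probability")
        np.testing.assert_allclose(sv.var_p1, cv.var_p1, rtol=1e-12)
        assert sv.var_D1 == pytest.approx(cv.var_D1, rel=1e-12)

    def test_zero_ses_give_zero_variances(self, pacific_pair):
        import dataclasses
        s1, s2 = pacific_pair
        t1 = dataclasses.replace(s1, rate_se=np.zeros(19))
        t2 = dataclasses.replace(s2, rate_se=np.zeros(19))
        sv = ar.survey_variances(t1, t2)
        assert np.all(sv.var_p1 == 0) and sv.var_D2 == 0

    def test_rate_to_probability_propagation_matches_fd(self, pacific_pair):
        import dataclasses
        s1, s2 = pacific_pair
        se_m = 0.03 * s1.rates
        t1 = dataclasses.replace(s1, rate_se=se_m)
        sv = ar.survey_variances(t1, t1)
        n, a, m = s1.grid.widths[:18], s1.nax[:18], s1.rates[:18]
        h = 1e-6
        slope = (ar.q_from_m(m + h, a, n) - ar.q_from_m(m - h, a, n)) / (2 * h)
        np.testing.assert_allclose(np.sqrt(sv.var_p1), slope * se_m[:18], rtol=1e-5)

    def test_missing_se_is_an_error(self, pacific_pair):
        with pytest.raises(ValueError, match="rate_se"):
            ar.survey_variances(*pacific_pair)


class TestDeltaSe:
    def test_zero_variances_give_zero_ses(self, pacific_pair, pacific_lifetables):
        s1, s2 = pacific_pair
        lt1, lt2 = pacific_lifetables
        jac = jacobian(lt1, lt2, s1.deaths[-1], s2.deaths[-1])
        v = ar.ParameterVariances(var_p1=np.zeros(18), var_p2=np.zeros(18),
                                  var_D1=0.0, var_D2=0.0)
        res = ar.delta_se(jac, v)
        assert np.all(res.se == 0.0)

    def test_total_se_equals_two_population_e0_composition(self, pacific_pair, pacific_lifetables):
        # independent oracle: Sum(Dx) == e0(2) - e0(1), and the populations are
        # independent, so var(total) must equal var(e0_1) + var(e0_2)
        s1, s2 = pacific_pair
        lt1, lt2 = pacific_lifetables
        res = ar.delta_se(jacobian(lt1, lt2, s1.deaths[-1], s2.deaths[-1]),
                          ar.count_variances(s1, s2))
        oracle = np.sqrt(ar.e0_variance_delta(s1) + ar.e0_variance_delta(s2))
        assert res.total_se == pytest.approx(oracle, rel=1e-8)

    def test_total_se_oracle_on_random_pairs(self):
        for seed in (31, 32, 33):
            s1, s2 = random_schedule_pair(seed)
            lt1, lt2 = ar.build_lifetable(s1), ar.build_lifetable(s2)
            res = ar.delta_se(jacobian(lt1, lt2, s1.deaths[-1], s2.deaths[-1]),
                              ar.count_variances(s1, s2))
            oracle = np.sqrt(ar.e0_variance_delta(s1) + ar.e0_variance_delta(s2))
            assert res.total_se == pytest.approx(oracle, rel=1e-8)

    def test_per_age_ses_match_parametric_simulation(self):
        # parameter-recovery oracle: empirical SD of the contributions over
        # Poisson-resampled schedule pairs vs the analytic SEs
        s1, s2 = random_schedule_pair(8)
        lt1, lt2 = ar.build_lifetable(s1), ar.build_lifetable(s2)
        res = ar.delta_se(jacobian(lt1, lt2, s1.deaths[-1], s2.deaths[-1]),
                          ar.count_variances(s1, s2))
        rng = np.random.default_rng(2024)
        reps = 4000
        m1 = rng.poisson(s1.deaths, size=(reps, 19)) / s1.exposure
        m2 = rng.poisson(s2.deaths, size=(reps, 19)) / s2.exposure
        sims = ar.arriaga_from_rates(m1, s1.nax, m2, s2.nax, s1.grid.widths)
        sd = sims.std(axis=0, ddof=1)
        big = s1.deaths >= 5
        np.testing.assert_allclose(sd[big], res.se[:-1][big], rtol=0.15)
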