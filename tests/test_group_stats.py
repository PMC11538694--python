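"""Statistics layer vs independent oracles: Friedman rank formula,
Mann-Whitney enumeration, Holm-Sidak step-down, regression and the
logistic growth fit."""

import numpy as np
import pytest
from scipy import stats as sps

from _oracles import friedman_bruteforce, holm_sidak_bruteforce, mannwhitney_exact_p
from dyadscan.group_stats import (
    exposure_regression,
    friedman,
    holm_sidak,
    logistic_growth_fit,
    mann_whitney,
)


class TestFriedman:
    def test_identical_columns_null(self):
        res = friedman(np.tile([[1.0, 1.0, 1.0]], (4, 1)))
        assert res.statistic == 0.0 and res.p == 1.0

    def test_strictly_increasing_rows_worked_example(self):
        # ranks are 1,2,3 in every row: 12/(3*3*4) * ((3-6)^2+(6-6)^2+(9-6)^2) = 6
        table = np.array([[1, 2, 3], [4, 5, 6], [0.1, 0.5, 0.9]])
        res = friedman(table)
        assert res.statistic == pytest.approx(6.0)

    def test_matches_bruteforce_and_scipy_on_random_tables(self, rng):
        for _ in range(200):
            n = rng.integers(3, 7)
            k = rng.integers(3, 6)
            table = rng.standard_normal((n, k))
            ours = friedman(table)
            assert ours.statistic == pytest.approx(friedman_bruteforce(table), abs=1e-9)
            ref = sps.friedmanchisquare(*table.T)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_incomplete_blocks_rejected(self):
        table = np.array([[1.0, 2.0], [np.nan, 1.0]])
        with pytest.raises(ValueError, match="incomplete"):
            friedman(table)


class TestMannWhitney:
    def test_fully_separated_small_sample(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert mann_whitney(x, x).p == pytest.approx(1.0)

    def test_large_shift_significant(self, rng):
        x = rng.standard_normal(50)
        res = mann_whitney(x + 10, rng.standard_normal(50))
        assert res.p < 1e-6

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(200):
            nx, ny = rng.integers(2, 6), rng.integers(2, 6)
            x = rng.standard_normal(nx)
            y = rng.standard_normal(ny)
            res = mann_whitney(x, y)
            assert res.p == pytest.approx(mannwhitney_exact_p(x, y), abs=1e-9)

    def test_asymptotic_close_to_exact_at_threshold(self, rng):
        # n just above the exact-method cutoff: approximation within 0.02
        x = rng.standard_normal(9)
        y = rng.standard_normal(9) + 1.0
        approx = mann_whitney(x, y).p
        exact = mannwhitney_exact_p(x, y)
        assert abs(approx - exact) < 0.02


class TestHolmSidak:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_sidak([0.03]), [0.03])

    def test_two_p_worked_example(self):
        adj = holm_sidak([0.01, 0.04])
        assert adj[0] == pytest.approx(1 - 0.99**2)
        assert adj[1] == pytest.approx(0.04)

    def test_all_ones(self):
        np.testing.assert_allclose(holm_sidak([1.0, 1.0, 1.0]), 1.0)

    def test_matches_direct_formula_and_is_monotone(self, rng):
        for _ in range(200):
            m = rng.integers(2, 10)
            p = rng.uniform(0, 1, m)
            adj = holm_sidak(p)
            np.testing.assert_allclose(adj, holm_sidak_bruteforce(p), atol=1e-12)
            assert (adj >= p - 1e-12).all()
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-12).all()


class TestExposureRegression:
    def test_exact_line(self):
        days = np.repeat([1, 2, 3, 4, 5], 3)
        fit = exposure_regression(0.1 * days, days)
        assert fit.beta == pytest.approx(0.1)
        assert fit.sem == pytest.approx(0.0, abs=1e-12)

    def test_shuffled_labels_centered_on_zero(self, rng):
        days = np.repeat(np.arange(1, 6), 4)
        y = 0.1 * days + 0.05 * rng.standard_normal(days.size)
        betas = [exposure_regression(y, rng.permutation(days)).beta for _ in range(300)]
        assert abs(np.mean(betas)) < 0.01

    def test_constant_exposure_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            exposure_regression([1.0, 2.0, 3.0], [2, 2, 2])


class TestLogisticGrowth:
    def test_parameter_recovery(self):
        recovered = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = np.arange(1, 11, dtype=float)
            y = 0.4 / (1 + np.exp(-1.2 * (t - 4))) + 0.01 * rng.standard_normal(t.size)
            fit = logistic_growth_fit(t, y)
            assert fit.converged
            recovered.append((fit.L, fit.k, fit.t0))
        L, k, t0 = np.median(recovered, axis=0)
        assert abs(L - 0.4) / 0.4 < 0.1
        assert abs(k - 1.2) / 1.2 < 0.1
        assert abs(t0 - 4.0) / 4.0 < 0.1

    def test_plateau_day_location(self):
        t = np.arange(1, 11, dtype=float)
        y = 0.4 / (1 + np.exp(-1.1 * (t - 4)))
        fit = logistic_growth_fit(t, y)
        # closed form: t0 + ln(19)/k
        assert fit.plateau_day == pytest.approx(4 + np.log(19) / 1.1, rel=0.02)

    def test_constant_data_flagged_degenerate(self):
        fit = logistic_growth_fit(np.arange(1, 8), np.full(7, 0.3))
        assert not fit.converged and fit.plateau_day is None

    def test_too_few_days_rejected(self):
        with pytest.raises(ValueError, match="5 distinct days"):
            logistic_growth_fit([1, 2, 3, 4], [0.1, 0.2, 0.3, 0.4])
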