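"""Profile-difference tests, reliability, correlations, sparse-cell screen."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from profilex.lpa import HIGH_LABEL, LOW_LABEL
from profilex.study_counts import (
    CANDIDATE_SET,
    CATEGORICAL_COUNTS,
    CONTINUOUS_VARS,
    N_COLLECTED,
    N_HIGH,
    N_TOTAL,
    PRINTED_CHI2_2X2,
    PRINTED_CHI2_MOTHER,
)
from profilex.univariate import (
    TestResult as UnivTestResult,
    UnivariateError,
    chi_square,
    cronbach_alpha,
    fisher_exact,
    mann_whitney,
    profile_crosstabs,
    screen_sparse,
    spearman_matrix,
    univariate_report,
)


class TestChiSquare:
    @pytest.mark.parametrize("var,expected", sorted(PRINTED_CHI2_2X2.items()))
    def test_reproduces_published_2x2(self, var, expected):
        res = chi_square(CATEGORICAL_COUNTS[var])
        assert res.method == "chi_square_yates"
        assert round(res.statistic, 2) == expected

    def test_reproduces_published_mother_education(self):
        res = chi_square(CATEGORICAL_COUNTS["mother_education"])
        assert res.method == "chi_square"
        assert res.df == 2
        assert round(res.statistic, 2) == PRINTED_CHI2_MOTHER

    def test_gender_association_negligible(self):
        # gender prints as 0.00: the Yates-corrected statistic is below 0.005
        res = chi_square(CATEGORICAL_COUNTS["gender"])
        assert 0.0 <= res.statistic < 0.005
        assert res.p_value > 0.9

    def test_no_association_2x2(self):
        res = chi_square([[50, 50], [50, 50]])
        assert res.statistic == pytest.approx(0.0)

    def test_zero_expected_count_refused(self):
        with pytest.raises(UnivariateError, match="fisher"):
            chi_square([[0, 0], [5, 5]])

    def test_bad_shape_refused(self):
        with pytest.raises(UnivariateError):
            chi_square([[1, 2, 3]])

    def test_negative_counts_refused(self):
        with pytest.raises(UnivariateError):
            chi_square([[1, -2], [3, 4]])


class TestFisherExact:
    def test_hand_value_2x2(self):
        # [[5,0],[0,5]]: only the two perfectly discordant tables are as
        # extreme; each has probability 1/C(10,5) = 1/252
        res = fisher_exact([[5, 0], [0, 5]])
        assert res.p_value == pytest.approx(2 / 252)

    def test_matches_scipy_2x2(self):
        t = [[8, 2], [1, 5]]
        assert fisher_exact(t).p_value == pytest.approx(stats.fisher_exact(t)[1])

    def test_independent_table_p_one(self):
        res = fisher_exact([[10, 10], [10, 10]])
        assert res.p_value == pytest.approx(1.0)

    def test_hand_value_tea_tasting(self):
        res = fisher_exact([[1, 9], [11, 3]])
        assert res.p_value == pytest.approx(0.002759456, abs=1e-8)

    def test_rxc_exact_small_total(self):
        # diagonal 3x3: maximal association, tiny exact p
        res = fisher_exact([[6, 0, 0], [0, 6, 0], [0, 0, 6]])
        assert res.p_value < 1e-4
        assert "monte_carlo" not in res.notes

    def test_rxc_enumeration_matches_scipy_2x2(self):
        from profilex.univariate import _fisher_enumerate

        t = np.array([[8, 2], [1, 5]])
        assert _fisher_enumerate(t) == pytest.approx(stats.fisher_exact(t)[1], rel=1e-10)

    def test_zero_margin_p_one(self):
        assert fisher_exact([[3, 0], [4, 0]]).p_value == pytest.approx(1.0)
        assert fisher_exact([[3, 0, 2], [4, 0, 1]]).p_value == pytest.approx(1.0)

    def test_rxc_monte_carlo_matches_exact(self):
        """The MC path agrees with the exact path on a table it can both do."""
        t = np.array([[12, 4, 8], [5, 10, 6]])
        exact = fisher_exact(t).p_value
        from profilex.univariate import _fisher_montecarlo

        mc = _fisher_montecarlo(t, seed=0)
        assert abs(mc - exact) < 0.01

    def test_large_total_flags_monte_carlo(self):
        t = np.array([[120, 40, 80], [50, 100, 60]])
        res = fisher_exact(t, seed=0)
        assert res.notes.get("monte_carlo")
        assert 0.0 < res.p_value <= 1.0


class TestMannWhitney:
    def test_hand_value_no_ties(self):
        # x=[1,2,3], y=[4,5,6]: U2=9, var=5.25, Z=4.5/sqrt(5.25)
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(4.5 / np.sqrt(5.25))
        assert res.notes["U"] == 9.0
        assert not res.notes["tie_correction"]

    def test_sign_convention(self):
        # Z > 0 when the second sample ranks higher
        hi = mann_whitney([1, 2, 3, 4], [10, 11, 12])
        lo = mann_whitney([10, 11, 12], [1, 2, 3, 4])
        assert hi.statistic > 0 > lo.statistic
        assert hi.p_value == pytest.approx(lo.p_value)

    def test_matches_scipy_asymptotic(self, rng):
        x = rng.integers(0, 8, 40).astype(float)  # heavy ties
        y = rng.integers(2, 10, 30).astype(float)
        res = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=False)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        assert res.notes["tie_correction"]

    def test_null_calibration(self, rng):
        """Type-I error of the two-sided 5% test within its 99% binomial band."""
        reps, rejects = 200, 0
        for _ in range(reps):
            x = rng.standard_normal(30)
            y = rng.standard_normal(30)
            rejects += mann_whitney(x, y).p_value < 0.05
        rate = rejects / reps
        half = 2.576 * np.sqrt(0.05 * 0.95 / reps)
        assert 0.05 - half <= rate <= 0.05 + half

    def test_empty_sample_refused(self):
        with pytest.raises(UnivariateError):
            mann_whitney([], [1.0])

    def test_all_tied_refused(self):
        with pytest.raises(UnivariateError):
            mann_whitney([1, 1, 1], [1, 1, 1])


class TestCronbachAlpha:
    def test_identical_items_alpha_one(self):
        m = np.column_stack([np.arange(10.0)] * 3)
        assert cronbach_alpha(m) == pytest.approx(1.0)

    def test_hand_value(self):
        # item variances 1 and 4; total [3,6,9] has variance 9 -> 2*(1-5/9)
        m = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        assert cronbach_alpha(m) == pytest.approx(8 / 9)

    def test_independent_items_near_zero(self, rng):
        m = rng.standard_normal((5000, 4))
        assert abs(cronbach_alpha(m)) < 0.1

    def test_degenerate_refused(self):
        with pytest.raises(UnivariateError):
            cronbach_alpha(np.ones((5, 3)))
        with pytest.raises(UnivariateError):
            cronbach_alpha(np.ones((5, 1)))


class TestSpearman:
    def test_perfect_monotone(self, small_cohort):
        mat = spearman_matrix(small_cohort)
        assert np.allclose(np.diag(mat), 1.0)
        assert mat.shape == (6, 6)
        assert (mat.abs() <= 1.0 + 1e-12).all().all()

    def test_equals_pearson_on_midranks(self, rng):
        cohort = pd.DataFrame(
            {
                name: rng.integers(lo, hi + 1, 100)
                for name, (lo, hi) in (
                    ("fas", (0, 13)),
                    ("gses", (10, 40)),
                    ("psss", (12, 84)),
                    ("aps", (8, 40)),
                    ("gps", (11, 55)),
                    ("uwes", (17, 119)),
                )
            }
        )
        mat = spearman_matrix(cohort)
        r_fas = stats.rankdata(cohort["fas"])
        r_gses = stats.rankdata(cohort["gses"])
        assert mat.loc["fas", "gses"] == pytest.approx(np.corrcoef(r_fas, r_gses)[0, 1])

    def test_constant_column_refused(self, small_cohort):
        bad = small_cohort.copy()
        bad["fas"] = 5
        with pytest.raises(UnivariateError, match="fas"):
            spearman_matrix(bad)


class TestScreenSparse:
    def test_recovers_published_candidate_set(self):
        kept, excluded = screen_sparse(CATEGORICAL_COUNTS, CONTINUOUS_VARS)
        assert len(kept) == 9
        assert set(kept) == set(CANDIDATE_SET)
        assert "volunteer" in excluded  # 3 high-profile volunteers < 10
        assert "ethnic" in excluded

    def test_threshold_boundary(self):
        counts = {"a": [[10, 10], [10, 10]], "b": [[9, 10], [10, 10]]}
        kept, excluded = screen_sparse(counts)
        assert kept == ["a"] and excluded == ["b"]

    def test_custom_threshold(self):
        counts = {"a": [[5, 5], [5, 5]]}
        assert screen_sparse(counts, threshold=5) == (["a"], [])
        assert screen_sparse(counts, threshold=6) == ([], ["a"])

    def test_continuous_always_kept(self):
        kept, _ = screen_sparse({}, ["x", "y"])
        assert kept == ["x", "y"]


class TestReport:
    @pytest.fixture
    def labeled(self, small_cohort):
        lab = small_cohort.copy()
        lab["profile"] = np.where(lab["true_class"] == 1, HIGH_LABEL, LOW_LABEL)
        return lab

    def test_crosstab_row_order(self, labeled):
        tabs = profile_crosstabs(labeled, ["gender_male"])
        t = tabs["gender_male"]
        assert t.sum() == len(labeled)
        assert t[0].sum() == (labeled["profile"] == LOW_LABEL).sum()

    def test_report_structure(self, labeled):
        rep = univariate_report(labeled, ["gender_male", "scholarship"], ["gses", "psss"], seed=0)
        assert set(rep.columns) == {"variable", "level", "low", "high", "statistic", "p", "method"}
        assert set(rep.loc[rep["method"] != "", "method"]) <= {
            "chi_square_yates",
            "chi_square",
            "fisher_exact",
            "mann_whitney",
        }
        gses_row = rep[rep["variable"] == "gses"].iloc[0]
        assert gses_row["method"] == "mann_whitney"
        assert "(" in gses_row["low"]  # median(P25,P75) format

    def test_fisher_fallback_on_sparse_expected(self, labeled):
        lab = labeled.copy()
        rare = np.zeros(len(lab), dtype=int)
        rare[:3] = 1  # expected count in the high profile well below 5
        lab["rare_flag"] = rare
        rep = univariate_report(lab, ["rare_flag"], [], seed=0)
        assert rep.iloc[0]["method"] == "fisher_exact"

    def test_published_shares(self):
        assert round(100 * N_HIGH / N_TOTAL, 1) == 8.1
        assert round(100 * N_TOTAL / N_COLLECTED) == 94

    def test_result_dataclass_defaults(self):
        r = UnivTestResult(method="chi_square", statistic=1.0, p_value=0.5)
        assert r.df is None and r.notes == {}
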