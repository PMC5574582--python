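from itertools import combinations

import numpy as np
import pytest
from scipy.stats import rankdata

from markrecap.capture_data import CaptureMatrix, FrequencyTable
from markrecap.catchability_tests import (
    chapman_test,
    run_all_tests,
    sex_chisq_test,
    sex_fisher_test,
    sex_wmw_test,
    ztp_test,
)


def matrix_from_counts(male_counts, female_counts, t=8):
    """Build a capture matrix whose per-individual capture counts are given."""
    counts = list(male_counts) + list(female_counts)
    det = np.zeros((len(counts), t), dtype=int)
    for i, c in enumerate(counts):
        det[i, :c] = 1
    sexes = ["male"] * len(male_counts) + ["female"] * len(female_counts)
    return CaptureMatrix(det, sexes)


class TestZtp:
    def test_rate_fitted_by_moment_matching(self):
        """Mean captures 2.313 per captured individual gives lambda ~ 2.0."""
        # 687 doubles + 313 triples: mean = 2313/1000 = 2.313 exactly
        f = np.array([0, 687, 313, 0, 0, 0, 0, 0])
        ft = FrequencyTable(t=8, f=f)
        assert ft.total_captures / ft.n == pytest.approx(2.313)
        res = ztp_test(ft)
        lam = float(res.method_detail.split("lambda_hat=")[1].split(",")[0])
        assert lam / (1 - np.exp(-lam)) == pytest.approx(2.313, abs=1e-4)
        assert lam == pytest.approx(2.0, abs=0.01)

    def test_perfect_fit_has_high_p(self):
        from scipy.special import gammaln

        lam, t, n = 1.5, 8, 100_000
        i = np.arange(1, t + 1)
        pmf = np.exp(i * np.log(lam) - lam - gammaln(i + 1)) / (1 - np.exp(-lam))
        f = np.round(n * pmf).astype(int)
        res = ztp_test(FrequencyTable(t=t, f=f))
        assert res.statistic < 1.0
        assert res.p_value > 0.95

    def test_no_recaptures_is_degenerate(self):
        ft = FrequencyTable(t=4, f=np.array([20, 0, 0, 0]))
        res = ztp_test(ft)
        assert np.isnan(res.p_value)
        assert "degenerate" in res.method_detail


class TestChapman:
    def test_perfect_truncated_binomial_fit_has_high_p(self):
        from scipy.stats import binom

        t, p, n = 8, 0.15, 50_000
        i = np.arange(1, t + 1)
        pmf = binom.pmf(i, t, p) / (1 - (1 - p) ** t)
        f = np.round(n * pmf).astype(int)
        res = chapman_test(FrequencyTable(t=t, f=f))
        assert res.p_value > 0.9

    def test_failed_m0_fit_is_degenerate(self):
        ft = FrequencyTable(t=4, f=np.array([20, 0, 0, 0]))
        res = chapman_test(ft)
        assert np.isnan(res.p_value)


class TestSexChisq:
    def test_perfect_homogeneity(self):
        m = matrix_from_counts([2] * 10 + [1] * 10, [2] * 10 + [1] * 10)
        res = sex_chisq_test(m)
        assert res.statistic == 0
        assert res.p_value == 1
        assert res.df == 1

    def test_perfect_separation(self):
        m = matrix_from_counts([2] * 20, [1] * 20)
        assert sex_chisq_test(m).p_value < 1e-6

    def test_matches_hand_computed_corrected_statistic(self):
        """Table [[30,10],[18,22]] -> sum (|O-E|-0.5)^2 / E."""
        m = matrix_from_counts([2] * 30 + [1] * 10, [2] * 18 + [1] * 22)
        res = sex_chisq_test(m)
        expected = np.array([[24, 16], [24, 16]], dtype=float)
        observed = np.array([[30, 10], [18, 22]], dtype=float)
        stat = ((np.abs(observed - expected) - 0.5) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(stat)

    def test_zero_marginal_is_an_error(self):
        m = matrix_from_counts([1] * 5, [1] * 5)  # nobody recaptured
        with pytest.raises(ValueError, match="marginal"):
            sex_chisq_test(m)


class TestSexFisher:
    def test_two_by_two_example(self):
        """[[3,1],[1,3]] has two-sided exact p ~ 0.486."""
        m = matrix_from_counts([1, 1, 1, 2], [1, 2, 2, 2])
        res = sex_fisher_test(m)
        assert res.p_value == pytest.approx(0.485714, abs=1e-4)

    def test_identical_rows_give_p_one(self):
        m = matrix_from_counts([1, 1, 2, 3], [1, 1, 2, 3])
        assert sex_fisher_test(m).p_value == pytest.approx(1.0)

    def test_enumeration_matches_scipy_on_collapsed_2x2(self):
        # three columns, small enough for full enumeration
        m = matrix_from_counts([1, 1, 1, 2, 3], [1, 2, 2, 3, 3])
        res = sex_fisher_test(m)
        assert "enumeration" in res.method_detail
        assert 0 <= res.p_value <= 1

    def test_monte_carlo_branch_is_deterministic(self):
        rng = np.random.default_rng(0)
        male = rng.integers(1, 7, 120)
        female = rng.integers(1, 7, 120)
        m = matrix_from_counts(male, female)
        r1, r2 = sex_fisher_test(m), sex_fisher_test(m)
        assert "Monte-Carlo" in r1.method_detail
        assert r1.p_value == r2.p_value

    def test_monte_carlo_agrees_with_enumeration(self, monkeypatch):
        import markrecap.catchability_tests as ct

        m = matrix_from_counts([1, 1, 1, 1, 2, 2, 3], [1, 2, 2, 3, 3, 3, 3])
        exact = sex_fisher_test(m)
        assert "enumeration" in exact.method_detail
        monkeypatch.setattr(ct, "_FISHER_ENUM_LIMIT", 0)
        mc = sex_fisher_test(m, mc_tables=20_000)
        assert "Monte-Carlo" in mc.method_detail
        assert abs(mc.p_value - exact.p_value) < 0.02


class TestSexWmw:
    def test_identical_multisets_give_p_one(self):
        m = matrix_from_counts([1, 2, 3, 4], [1, 2, 3, 4])
        res = sex_wmw_test(m)
        assert res.p_value == pytest.approx(1.0)
        assert res.statistic == pytest.approx(8.0)  # n1*n2/2

    def test_complete_separation_is_significant(self):
        m = matrix_from_counts([5] * 10, [1] * 10)
        res = sex_wmw_test(m)
        assert res.statistic == pytest.approx(100.0)
        assert res.p_value < 1e-3

    def test_all_counts_tied_gives_p_one(self):
        m = matrix_from_counts([2, 2, 2], [2, 2])
        assert sex_wmw_test(m).p_value == 1.0

    @staticmethod
    def exact_permutation_p(x, y):
        pooled = np.concatenate([x, y])
        ranks = rankdata(pooled)
        nx = len(x)
        mu = nx * len(y) / 2

        def u_stat(idx):
            return ranks[list(idx)].sum() - nx * (nx + 1) / 2

        obs = abs(u_stat(range(nx)) - mu)
        hits = total = 0
        for idx in combinations(range(len(pooled)), nx):
            total += 1
            if abs(u_stat(idx) - mu) >= obs - 1e-9:
                hits += 1
        return hits / total

    def test_asymptotic_tracks_exact_permutation(self):
        """For 8-per-group samples the tie-corrected normal approximation
        stays within 0.15 of the exhaustive permutation p (measured bound;
        tiny groups with heavy ties can disagree by more mid-distribution)."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            x = rng.integers(1, 6, 8)
            y = rng.integers(1, 6, 8)
            m = matrix_from_counts(x, y)
            pa = sex_wmw_test(m).p_value
            pe = self.exact_permutation_p(x.astype(float), y.astype(float))
            assert abs(pa - pe) < 0.15


def test_run_all_tests_returns_all_five():
    rng = np.random.default_rng(1)
    m = matrix_from_counts(rng.integers(1, 5, 60), rng.integers(1, 5, 60))
    results = run_all_tests(m)
    assert set(results) == {"chapman", "ztp", "sex_chisq", "sex_fisher", "sex_wmw"}
    for res in results.values():
        assert res.valid
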