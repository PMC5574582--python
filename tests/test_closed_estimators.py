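import numpy as np
import pytest

from markrecap.capture_data import CaptureMatrix, FrequencyTable, build_frequency_table
from markrecap.closed_estimators import (
    ClosedModel,
    chao_moment_estimate,
    estimate_with_grouping,
    fit_closed,
    m0_mle_bruteforce,
)
from markrecap.closed_simulator import ClosedSimConfig, simulate_closed
from markrecap.experiments import replicate_rng

EXAMPLE = FrequencyTable(t=8, f=np.array([50, 25, 10, 5, 2, 1, 0, 0]))


class TestChaoMoment:
    def test_classic_formula(self):
        assert chao_moment_estimate(EXAMPLE) == pytest.approx(93 + 50**2 / 50)  # 143

    def test_no_singletons_returns_n(self):
        ft = FrequencyTable(t=4, f=np.array([0, 5, 3, 1]))
        assert chao_moment_estimate(ft) == ft.n

    def test_bias_corrected_branch_without_doubletons(self):
        ft = FrequencyTable(t=3, f=np.array([3, 0, 0]))
        assert chao_moment_estimate(ft) == pytest.approx(6.0)


class TestFitClosedChao:
    def test_matches_two_cell_closed_form(self):
        """The log-linear Chao fit has closed form n + (t-1)/t * f1^2/(2 f2).

        With one free parameter per cell i >= 3 those cells are saturated and
        the intercept is determined by the singleton and doubleton cells alone
        (solving the two score equations by hand gives the formula).
        """
        fit = fit_closed(EXAMPLE, ClosedModel.MH_CHAO)
        t, f1, f2 = 8, 50, 25
        closed_form = EXAMPLE.n + (t - 1) / t * f1**2 / (2 * f2)
        assert not fit.failed
        assert fit.N_hat == pytest.approx(closed_form, abs=1e-6)

    def test_relation_to_moment_estimator(self):
        """Log-linear Chao and the classical moment estimator differ exactly
        by the factor (t-1)/t on the unobserved-count term."""
        fit = fit_closed(EXAMPLE, ClosedModel.MH_CHAO)
        moment = chao_moment_estimate(EXAMPLE)
        assert (fit.N_hat - EXAMPLE.n) == pytest.approx(
            (8 - 1) / 8 * (moment - EXAMPLE.n), rel=1e-9
        )

    def test_two_cell_table_reduction(self):
        """With no cells above i = 2 the fit is the pure two-cell solution."""
        ft = FrequencyTable(t=6, f=np.array([40, 16, 0, 0, 0, 0]))
        fit = fit_closed(ft, ClosedModel.MH_CHAO)
        assert fit.N_hat == pytest.approx(56 + (5 / 6) * 40**2 / 32, abs=1e-6)

    def test_requires_three_periods(self):
        ft = FrequencyTable(t=2, f=np.array([5, 3]))
        fit = fit_closed(ft, ClosedModel.MH_CHAO)
        assert fit.failed and "3 sampling periods" in fit.failure_reason

    def test_eta_admissibility_is_flagged(self):
        fit = fit_closed(EXAMPLE, ClosedModel.MH_CHAO)
        assert "chao_eta_negative" in fit.diagnostics


class TestFitClosedM0:
    def test_saturated_table_gives_n(self):
        ft = FrequencyTable(t=4, f=np.array([0, 0, 0, 12]))
        fit = fit_closed(ft, ClosedModel.M0)
        assert not fit.failed
        assert fit.N_hat == 12
        assert fit.diagnostics.get("saturated")

    def test_no_recaptures_fails_loudly(self):
        ft = FrequencyTable(t=8, f=np.array([30, 0, 0, 0, 0, 0, 0, 0]))
        fit = fit_closed(ft, ClosedModel.M0)
        assert fit.failed and "no recaptures" in fit.failure_reason

    def test_agreement_with_bruteforce_oracle(self):
        """The GLM (conditional) MLE tracks the integer-search unconditional
        MLE; the two likelihoods differ by the binomial coefficient term, so
        agreement is within ~2 animals at these sample sizes."""
        cfg = ClosedSimConfig(captures_per_period=40, bias=1.0)
        for rep in range(30):
            sim = simulate_closed(cfg, replicate_rng(0, 1.0, rep))
            ft = build_frequency_table(sim.matrix)
            glm = fit_closed(ft, ClosedModel.M0)
            bf = m0_mle_bruteforce(ft)
            assert not glm.failed and not bf.at_cap
            assert abs(glm.N_hat - bf.N_hat) < 2.0

    def test_fit_outputs_are_complete(self):
        fit = fit_closed(EXAMPLE, ClosedModel.M0)
        assert fit.N_hat >= EXAMPLE.n
        assert fit.se > 0
        assert np.isfinite(fit.bic)
        assert fit.df == 8 - 2
        assert len(fit.pearson_residuals) == 8
        assert set(fit.coefficients) == {"intercept", "captures"}


class TestBruteForceM0:
    def test_no_recapture_table_hits_search_cap(self):
        ft = FrequencyTable(t=2, f=np.array([2, 0]))
        assert m0_mle_bruteforce(ft).at_cap

    def test_saturated_table_returns_n(self):
        ft = FrequencyTable(t=3, f=np.array([0, 0, 9]))
        res = m0_mle_bruteforce(ft)
        assert res.N_hat == 9 and not res.at_cap


@pytest.mark.parametrize(
    "model", [ClosedModel.M0, ClosedModel.MH_CHAO, ClosedModel.MH_DARROCH,
              ClosedModel.MH_POISSON]
)
def test_abundance_never_below_observed(model):
    rng = np.random.default_rng(11)
    for _ in range(10):
        counts = np.clip(rng.poisson(1.3, 120), 0, 8)
        counts = counts[counts > 0]
        if counts.size < 10 or (counts == 1).all():
            continue
        ft = FrequencyTable(t=8, f=np.bincount(counts, minlength=9)[1:])
        fit = fit_closed(ft, model)
        if not fit.failed:
            assert fit.N_hat >= ft.n


def test_poisson_variant_requires_a_above_one():
    with pytest.raises(ValueError, match="poisson_a"):
        fit_closed(EXAMPLE, ClosedModel.MH_POISSON, poisson_a=1.0)


class TestGrouping:
    def _sim(self, bias=2.0):
        cfg = ClosedSimConfig(captures_per_period=40, bias=bias)
        return simulate_closed(cfg, replicate_rng(0, bias, 0))

    def test_combined_equals_whole_table_fit(self):
        sim = self._sim()
        comb = estimate_with_grouping(sim.matrix, "combined")
        direct = fit_closed(build_frequency_table(sim.matrix), ClosedModel.MH_CHAO)
        assert comb.population_estimate == pytest.approx(direct.N_hat)

    def test_bias_known_absent_switches_to_m0(self):
        sim = self._sim(bias=1.0)
        comb = estimate_with_grouping(sim.matrix, "combined", bias_known_absent=True)
        direct = fit_closed(build_frequency_table(sim.matrix), ClosedModel.M0)
        assert comb.population_estimate == pytest.approx(direct.N_hat)

    def test_separated_reports_sum_and_ratio(self):
        sim = self._sim()
        sep = estimate_with_grouping(sim.matrix, "separated")
        assert not sep.failed
        assert sep.population_estimate == pytest.approx(
            sep.male.N_hat + sep.female.N_hat
        )
        assert sep.sex_ratio_estimate == pytest.approx(
            sep.male.N_hat / sep.female.N_hat
        )

    def test_missing_sex_marks_failure(self):
        m = CaptureMatrix(np.array([[1, 0], [1, 1]]), ["male", "male"])
        sep = estimate_with_grouping(m, "separated")
        assert sep.failed
        assert "insufficient captures: female" in sep.failure_reasons["female"]

    def test_unknown_mode_rejected(self):
        sim = self._sim()
        with pytest.raises(ValueError, match="mode"):
            estimate_with_grouping(sim.matrix, "pooled")
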