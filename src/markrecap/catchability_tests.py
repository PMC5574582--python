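"""Tests of equal catchability for mark-recapture data.

Five tests are implemented, operating on captured individuals only (the sex
of never-captured animals is unknown in real data):

* :func:`ztp_test` — goodness-of-fit of the frequency-of-capture distribution
  to a zero-truncated Poisson (equal catchability implies Poisson-like
  capture counts); sensitive mainly to trap response, not subgroup effects.
* :func:`chapman_test` — goodness-of-fit to the zero-truncated binomial
  implied by the M0 model's fitted capture probability.
* :func:`sex_chisq_test` — 2x2 chi-square (with continuity correction) of
  recaptured vs never-recaptured counts by sex.
* :func:`sex_fisher_test` — exact/Monte-Carlo conditional test of the full
  sex x number-of-captures contingency table.
* :func:`sex_wmw_test` — Wilcoxon-Mann-Whitney rank test (normal
  approximation with tie correction) on per-individual capture counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

from .capture_data import CaptureMatrix, FrequencyTable
from .closed_estimators import ClosedModel, fit_closed

__all__ = [
    "TestResult",
    "ztp_test",
    "chapman_test",
    "sex_chisq_test",
    "sex_fisher_test",
    "sex_wmw_test",
    "run_all_tests",
]

_FISHER_MC_TABLES = 1999
_FISHER_MC_SEED = 20_170_829
_FISHER_ENUM_LIMIT = 200_000


@dataclass
class TestResult:
    """Outcome of one equal-catchability test."""

    test_name: str
    statistic: float
    p_value: float
    df: int | None = None
    method_detail: str = ""

    @property
    def valid(self) -> bool:
        return np.isfinite(self.p_value)


def _pool_and_chisq(observed: np.ndarray, expected: np.ndarray, name: str, detail: str
                    ) -> TestResult:
    """Pool tail cells until every expected count >= 1, then chi-square GOF.

    Degrees of freedom are (retained cells - 2): one constraint for the total
    and one for the estimated distribution parameter.
    """
    obs = observed.astype(float).copy()
    exp = expected.astype(float).copy()
    # pool from the top (highest capture counts) downwards
    while len(exp) > 1 and exp[-1] < 1.0:
        exp[-2] += exp[-1]
        obs[-2] += obs[-1]
        exp = exp[:-1]
        obs = obs[:-1]
    pooled = len(observed) - len(obs)
    df = len(obs) - 2
    if df < 1:
        return TestResult(
            test_name=name,
            statistic=float("nan"),
            p_value=float("nan"),
            df=None,
            method_detail=detail + "; degenerate: fewer than 3 cells after pooling",
        )
    stat = float(((obs - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(stat, df))
    return TestResult(
        test_name=name,
        statistic=stat,
        p_value=p,
        df=df,
        method_detail=detail + f"; pooled {pooled} tail cells" if pooled else detail,
    )


def ztp_test(freq: FrequencyTable) -> TestResult:
    """Zero-truncated Poisson goodness-of-fit test of equal catchability.

    The rate is fitted by moment matching — ``lambda / (1 - exp(-lambda))``
    equals the mean number of captures per captured individual — and the
    observed capture-frequency distribution is compared with the implied
    zero-truncated Poisson by a chi-square test with tail pooling.
    """
    n, t = freq.n, freq.t
    mean = freq.total_captures / n
    if mean <= 1.0 + 1e-12:
        return TestResult(
            test_name="ztp",
            statistic=float("nan"),
            p_value=float("nan"),
            method_detail="degenerate: no recaptures (lambda at the zero boundary)",
        )
    lam = float(
        optimize.brentq(lambda l: l / (1.0 - np.exp(-l)) - mean, 1e-10, 60.0)
    )
    i = np.arange(1, t + 1)
    pmf = np.exp(i * np.log(lam) - lam - gammaln(i + 1)) / (1.0 - np.exp(-lam))
    # fold the model's tail beyond t captures into the top cell
    pmf[-1] += max(1.0 - pmf.sum(), 0.0)
    return _pool_and_chisq(
        freq.f, n * pmf, "ztp", f"zero-truncated Poisson, lambda_hat={lam:.4g}"
    )


def chapman_test(freq: FrequencyTable) -> TestResult:
    """Goodness-of-fit to the zero-truncated binomial under equal catchability.

    The capture probability is ``p_hat = total_captures / (N_hat * t)`` with
    ``N_hat`` from the M0 model fit, and the observed capture frequencies are
    compared with ``n * P(X = i | X > 0)`` for ``X ~ Binomial(t, p_hat)``.
    """
    n, t = freq.n, freq.t
    m0 = fit_closed(freq, ClosedModel.M0)
    if m0.failed:
        return TestResult(
            test_name="chapman",
            statistic=float("nan"),
            p_value=float("nan"),
            method_detail=f"degenerate: M0 fit failed ({m0.failure_reason})",
        )
    p_hat = min(freq.total_captures / (m0.N_hat * t), 1.0 - 1e-12)
    i = np.arange(1, t + 1)
    pmf = stats.binom.pmf(i, t, p_hat) / (1.0 - (1.0 - p_hat) ** t)
    return _pool_and_chisq(
        freq.f,
        n * pmf,
        "chapman",
        f"zero-truncated binomial, p_hat={p_hat:.4g}, N_hat={m0.N_hat:.4g}",
    )


def _recapture_table(matrix: CaptureMatrix) -> np.ndarray:
    counts = matrix.capture_counts()
    marked = counts >= 1
    male = matrix.is_male()
    recap = counts >= 2  # recaptured at least once after first capture
    return np.array(
        [
            [int((male & marked & recap).sum()), int((male & marked & ~recap).sum())],
            [int((~male & marked & recap).sum()), int((~male & marked & ~recap).sum())],
        ]
    )


def sex_chisq_test(matrix: CaptureMatrix) -> TestResult:
    """Chi-square test of recaptured vs never-recaptured counts by sex."""
    table = _recapture_table(matrix)
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("sex chi-square test requires all table marginals > 0")
    res = stats.chi2_contingency(table, correction=True)
    return TestResult(
        test_name="sex_chisq",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=1,
        method_detail="2x2 recaptured/not by sex, continuity corrected",
    )


def _table_logprob(counts: np.ndarray, colsums: np.ndarray, m: int, n: int) -> float:
    """log P(table | margins) for a 2xK table with first-row entries ``counts``."""
    return float(
        (gammaln(colsums + 1) - gammaln(counts + 1) - gammaln(colsums - counts + 1)).sum()
        - (gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1))
    )


def _fisher_exact_enum(colsums: np.ndarray, m: int, obs_lp: float) -> float:
    """Exact two-sided conditional p by enumeration of all margin-fixed tables."""
    n = int(colsums.sum())
    K = len(colsums)
    p = 0.0
    stack = [(0, m, 0.0)]
    while stack:
        k, rem, lp = stack.pop()
        if k == K - 1:
            if 0 <= rem <= colsums[k]:
                lp_full = lp + (
                    gammaln(colsums[k] + 1)
                    - gammaln(rem + 1)
                    - gammaln(colsums[k] - rem + 1)
                )
                lp_full -= gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
                if lp_full <= obs_lp + 1e-9:
                    p += np.exp(lp_full)
            continue
        hi = min(int(colsums[k]), rem)
        lo = max(0, rem - int(colsums[k + 1:].sum()))
        for a in range(lo, hi + 1):
            stack.append(
                (
                    k + 1,
                    rem - a,
                    lp
                    + gammaln(colsums[k] + 1)
                    - gammaln(a + 1)
                    - gammaln(colsums[k] - a + 1),
                )
            )
    return min(p, 1.0)


def _n_tables_bound(colsums: np.ndarray, m: int) -> float:
    return float(np.prod([min(c, m) + 1 for c in colsums]))


def sex_fisher_test(
    matrix: CaptureMatrix,
    mc_tables: int = _FISHER_MC_TABLES,
    seed: int = _FISHER_MC_SEED,
) -> TestResult:
    """Exact conditional test of the sex x number-of-captures table.

    The 2xK table cross-classifies captured individuals by sex and by how many
    times they were captured.  The two-sided p-value sums the conditional
    (multivariate hypergeometric) probabilities of all margin-fixed tables no
    more probable than the observed one — computed exactly for 2x2 tables and
    by full enumeration when the table network is small, otherwise by
    Monte-Carlo sampling with a fixed seed.
    """
    counts = matrix.capture_counts()
    male = matrix.is_male()
    captured = counts >= 1
    if not (captured & male).any() or not (captured & ~male).any():
        raise ValueError("Fisher test requires captured individuals of both sexes")
    kmax = int(counts.max())
    male_f = np.bincount(counts[captured & male], minlength=kmax + 1)[1:]
    female_f = np.bincount(counts[captured & ~male], minlength=kmax + 1)[1:]
    keep = (male_f + female_f) > 0
    male_f, female_f = male_f[keep], female_f[keep]
    table = np.vstack([male_f, female_f])

    if table.shape[1] == 1:
        return TestResult("sex_fisher", 0.0, 1.0, method_detail="single column; p = 1")
    if table.shape[1] == 2:
        stat, p = stats.fisher_exact(table, alternative="two-sided")
        return TestResult(
            "sex_fisher", float(stat), float(p), method_detail="2x2 exact (hypergeometric)"
        )

    colsums = table.sum(axis=0)
    m = int(male_f.sum())
    n = int(colsums.sum())
    obs_lp = _table_logprob(male_f.astype(float), colsums.astype(float), m, n)
    if _n_tables_bound(colsums, m) <= _FISHER_ENUM_LIMIT:
        p = _fisher_exact_enum(colsums, m, obs_lp)
        return TestResult(
            "sex_fisher",
            float(-obs_lp),
            float(p),
            method_detail=f"2x{table.shape[1]} exact by enumeration",
        )
    rng = np.random.default_rng(seed)
    draws = stats.multivariate_hypergeom.rvs(colsums, m, size=mc_tables, random_state=rng)
    lps = (
        gammaln(colsums + 1.0)
        - gammaln(draws + 1.0)
        - gammaln(colsums - draws + 1.0)
    ).sum(axis=1) - (gammaln(n + 1.0) - gammaln(m + 1.0) - gammaln(n - m + 1.0))
    p = (1.0 + float((lps <= obs_lp + 1e-9).sum())) / (mc_tables + 1.0)
    return TestResult(
        "sex_fisher",
        float(-obs_lp),
        float(p),
        method_detail=f"2x{table.shape[1]} Monte-Carlo ({mc_tables} tables, seed {seed})",
    )


def sex_wmw_test(matrix: CaptureMatrix) -> TestResult:
    """Wilcoxon-Mann-Whitney test on per-individual capture counts by sex.

    Two-sided normal approximation with the tie-correction term in the
    variance (capture counts are heavily tied), no continuity correction.
    """
    counts = matrix.capture_counts()
    male = matrix.is_male()
    x = counts[(counts >= 1) & male]
    y = counts[(counts >= 1) & ~male]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("WMW test requires captured individuals of both sexes")
    if np.ptp(np.concatenate([x, y])) == 0:
        # all capture counts identical: statistic at its null mean
        return TestResult(
            "sex_wmw",
            float(len(x) * len(y) / 2),
            1.0,
            method_detail="all counts tied; statistic at null mean",
        )
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return TestResult(
        "sex_wmw",
        float(res.statistic),
        float(res.pvalue),
        method_detail="asymptotic, tie-corrected variance, no continuity correction",
    )


def run_all_tests(matrix: CaptureMatrix, freq: FrequencyTable | None = None) -> dict:
    """Run all five equal-catchability tests; failures become NaN results."""
    from .capture_data import build_frequency_table

    if freq is None:
        freq = build_frequency_table(matrix)
    results = {}
    results["chapman"] = chapman_test(freq)
    results["ztp"] = ztp_test(freq)
    for name, func in (
        ("sex_chisq", sex_chisq_test),
        ("sex_fisher", sex_fisher_test),
        ("sex_wmw", sex_wmw_test),
    ):
        try:
            results[name] = func(matrix)
        except ValueError as exc:
            results[name] = TestResult(
                name, float("nan"), float("nan"), method_detail=f"failed: {exc}"
            )
    return results
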