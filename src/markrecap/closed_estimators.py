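"""Closed-population abundance estimation from capture-frequency data.

All models are Poisson log-linear regressions of the capture-frequency cells
``f_1..f_t`` on the capture count ``i``, with offset ``log C(t, i)`` so that
the homogeneous model (M0) reproduces the classical equal-catchability
binomial likelihood.  The intercept estimates the log of the unobserved count
``f_0``, so the abundance estimate is ``N_hat = n + exp(beta_0)``.

Heterogeneity (Mh) variants add columns to the linear predictor:

* ``MhChao``  — one free parameter per capture-count cell ``i >= 3``
  (the log-linear lower-bound model; with all such cells saturated the
  estimate has the closed form ``n + (t-1)/t * f1^2 / (2 f2)``),
* ``MhDarroch`` — column ``i^2 / 2`` (normal mixing on the logit scale),
* ``MhPoisson`` — column ``a^i - 1`` (default ``a = 2``).

The standard error of ``N_hat`` is by the delta method on the intercept with
the multinomial correction, ``var(N_hat) = f0 + f0^2 var(beta_0)``.

Two independent oracles are provided for testing: the classical Chao moment
estimator and a brute-force integer-search M0 maximum-likelihood estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import statsmodels.api as sm
from scipy.special import gammaln

from .capture_data import CaptureMatrix, FrequencyTable, build_frequency_table

__all__ = [
    "ClosedModel",
    "ClosedFit",
    "GroupEstimates",
    "fit_closed",
    "chao_moment_estimate",
    "m0_mle_bruteforce",
    "BruteForceM0",
    "estimate_with_grouping",
]


class ClosedModel(str, Enum):
    M0 = "M0"
    MH_CHAO = "MhChao"
    MH_DARROCH = "MhDarroch"
    MH_POISSON = "MhPoisson"


@dataclass
class ClosedFit:
    """Result of fitting one closed-population model.

    ``N_hat >= n`` always holds for successful fits; ``failed`` fits carry a
    ``failure_reason`` and NaN estimates — never a silent wrong number.
    """

    model: ClosedModel
    N_hat: float = float("nan")
    se: float = float("nan")
    coefficients: dict = field(default_factory=dict)
    deviance: float = float("nan")
    df: int = 0
    bic: float = float("nan")
    pearson_residuals: np.ndarray | None = None
    converged: bool = False
    failed: bool = True
    failure_reason: str | None = None
    diagnostics: dict = field(default_factory=dict)


def _binom_log_coef(t: int, i: np.ndarray) -> np.ndarray:
    return gammaln(t + 1) - gammaln(i + 1) - gammaln(t - i + 1)


def fit_closed(
    freq: FrequencyTable, model: ClosedModel | str, poisson_a: float = 2.0
) -> ClosedFit:
    """Fit a closed-population log-linear model to a frequency table."""
    model = ClosedModel(model)
    t, f, n = freq.t, freq.f, freq.n
    fit = ClosedFit(model=model)

    if model is ClosedModel.MH_POISSON and poisson_a <= 1:
        raise ValueError("poisson_a must be > 1 for the MhPoisson model")
    if model is ClosedModel.MH_CHAO and t < 3:
        fit.failure_reason = "MhChao requires at least 3 sampling periods"
        return fit
    if n < 1:
        fit.failure_reason = "no observed individuals"
        return fit
    if freq.total_captures == n:
        # every observed individual was captured exactly once
        fit.failure_reason = "no recaptures: abundance is not identifiable"
        return fit
    nonzero = np.flatnonzero(f)
    if len(nonzero) == 1:
        if model is ClosedModel.M0 and nonzero[0] == t - 1:
            # saturation: every individual captured in every period -> p_hat = 1
            fit.N_hat, fit.se = float(n), 0.0
            fit.converged, fit.failed = True, False
            fit.coefficients = {"intercept": float("-inf"), "captures": float("inf")}
            fit.diagnostics["saturated"] = True
            return fit
        fit.failure_reason = "degenerate frequency table: single capture-count class"
        return fit

    i = np.arange(1, t + 1, dtype=float)
    offset = _binom_log_coef(t, i)
    keep = np.ones(t, dtype=bool)
    columns = [np.ones(t), i]
    names = ["intercept", "captures"]
    if model is ClosedModel.MH_CHAO:
        # cells i >= 3 each get a free parameter; empty ones are saturated at
        # zero and are dropped (they do not inform the unobserved-count cell)
        keep = (i <= 2) | (f > 0)
        for j in np.flatnonzero((i >= 3) & keep):
            columns.append((np.arange(t) == j).astype(float))
            names.append(f"eta{int(i[j])}")
    elif model is ClosedModel.MH_DARROCH:
        columns.append(i**2 / 2.0)
        names.append("darroch")
    elif model is ClosedModel.MH_POISSON:
        columns.append(poisson_a**i - 1.0)
        names.append(f"poisson_a{poisson_a:g}")
    X = np.column_stack(columns)[keep]
    y = f[keep].astype(float)
    off = offset[keep]

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit(
                maxiter=200, tol=1e-10
            )
            params = np.asarray(res.params)
            if not np.isfinite(params).all():
                fit.failure_reason = "model fit diverged (non-finite coefficients)"
                return fit
            b0 = params[0]
            if b0 > 30:
                fit.failure_reason = "model fit diverged (unobserved count overflow)"
                return fit
            var_b0 = float(np.asarray(res.cov_params())[0, 0])
            deviance = float(res.deviance)
            bic = float(res.bic_llf)
            resid = np.asarray(res.resid_pearson)
            converged = bool(getattr(res, "converged", True))
    except Exception as exc:  # noqa: BLE001 - any fit failure is a failed fit
        fit.failure_reason = f"model fit failed: {exc}"
        return fit

    f0 = float(np.exp(b0))
    var_n = f0 + f0**2 * max(var_b0, 0.0)
    fit.N_hat = n + f0
    fit.se = float(np.sqrt(var_n))
    fit.coefficients = dict(zip(names, (float(p) for p in params)))
    fit.deviance = deviance
    fit.df = int(keep.sum() - X.shape[1])
    fit.bic = bic
    fit.pearson_residuals = resid
    fit.converged = converged
    fit.failed = not fit.converged
    if fit.failed:
        fit.failure_reason = "IRLS did not converge"
    if model is ClosedModel.MH_CHAO:
        etas = [v for k, v in fit.coefficients.items() if k.startswith("eta")]
        # negative eta violates the lower-bound constraint; reported, not refit
        fit.diagnostics["chao_eta_negative"] = bool(any(v < 0 for v in etas))
    return fit


def chao_moment_estimate(freq: FrequencyTable) -> float:
    """Classical Chao lower-bound moment estimator of abundance.

    ``n + f1^2 / (2 f2)`` when doubletons exist, and the bias-corrected
    ``n + f1 (f1 - 1) / (2 (f2 + 1))`` when ``f2 = 0``.
    """
    f1 = int(freq.f[0])
    f2 = int(freq.f[1]) if freq.t >= 2 else 0
    if f2 > 0:
        return freq.n + f1**2 / (2 * f2)
    return freq.n + f1 * (f1 - 1) / (2 * (f2 + 1))


@dataclass(frozen=True)
class BruteForceM0:
    N_hat: float
    at_cap: bool  # True if the likelihood was still rising at the search cap


def m0_mle_bruteforce(freq: FrequencyTable, cap_factor: int = 100) -> BruteForceM0:
    """Integer-search maximum-likelihood M0 abundance estimate (test oracle).

    Maximises the M0 likelihood over integer ``N`` in ``[n, cap_factor * n]``
    with the common capture probability profiled out as
    ``p_hat(N) = total_captures / (N t)``.
    """
    n, t, M = freq.n, freq.t, freq.total_captures
    if n < 1:
        raise ValueError("no observed individuals")
    Ns = np.arange(n, cap_factor * n + 1, dtype=float)
    p = M / (Ns * t)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            gammaln(Ns + 1)
            - gammaln(Ns - n + 1)
            + M * np.log(p)
            + np.where(p < 1, (Ns * t - M) * np.log1p(-p), 0.0)
        )
    k = int(np.nanargmax(ll))
    return BruteForceM0(N_hat=float(Ns[k]), at_cap=k == len(Ns) - 1)


@dataclass
class GroupEstimates:
    """Abundance (and sex ratio) estimated with the sexes pooled or separated."""

    mode: str  # "combined" or "separated"
    combined: ClosedFit | None = None
    male: ClosedFit | None = None
    female: ClosedFit | None = None
    population_estimate: float = float("nan")
    sex_ratio_estimate: float = float("nan")
    failed: bool = False
    failure_reasons: dict = field(default_factory=dict)


def estimate_with_grouping(
    matrix: CaptureMatrix, mode: str, bias_known_absent: bool = False
) -> GroupEstimates:
    """Estimate abundance with males and females pooled or separated.

    Pooled ("combined") data are fitted with the heterogeneity model MhChao —
    sex-biased catchability makes the pooled population heterogeneous — unless
    ``bias_known_absent`` is set, in which case M0 is used.  Separated mode
    fits M0 within each sex (separation removes the heterogeneity) and
    reports ``N_m + N_f`` and the estimated sex ratio ``N_m / N_f``.
    """
    if mode not in ("combined", "separated"):
        raise ValueError("mode must be 'combined' or 'separated'")
    out = GroupEstimates(mode=mode)
    if mode == "combined":
        model = ClosedModel.M0 if bias_known_absent else ClosedModel.MH_CHAO
        fit = fit_closed(build_frequency_table(matrix), model)
        out.combined = fit
        out.failed = fit.failed
        if fit.failed:
            out.failure_reasons["combined"] = fit.failure_reason
        else:
            out.population_estimate = fit.N_hat
        return out

    male = matrix.is_male()
    fits = {}
    for label, rows in (("male", np.flatnonzero(male)), ("female", np.flatnonzero(~male))):
        if len(rows) == 0:
            out.failure_reasons[label] = f"insufficient captures: {label}"
            fits[label] = None
            continue
        fit = fit_closed(build_frequency_table(matrix, rows=rows), ClosedModel.M0)
        fits[label] = fit
        if fit.failed:
            out.failure_reasons[label] = f"{label}: {fit.failure_reason}"
    out.male, out.female = fits["male"], fits["female"]
    ok = all(f is not None and not f.failed for f in fits.values())
    out.failed = not ok
    if ok:
        out.population_estimate = out.male.N_hat + out.female.N_hat
        out.sex_ratio_estimate = out.male.N_hat / out.female.N_hat
    return out
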