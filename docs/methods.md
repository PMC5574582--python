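# Methods

## Simulation model

### Closed populations

A population of `N` individuals (default 300) with a fixed sex composition
(default 1:1) is sampled over `t` periods (default 8). In each period a
predetermined number of *distinct* individuals is captured — a fixed count
(defaults used in the studies: 40 or 20) or a count drawn uniformly from an
inclusive range, drawn independently per period. Captures within a period
are taken by sequential weighted sampling without replacement: at each draw
a remaining male is selected with probability proportional to `bias` and a
remaining female proportional to 1. The implementation uses the
exponential-race construction (draw `Exp(w_i)` arrival times, keep the `n`
earliest), which is distributionally identical to the sequential scheme;
the single-draw marginal is exactly `b N_m / (b N_m + N_f)`.

Assumptions encoded: no births, deaths, or movement; no time variation in
catchability; no behavioural response to capture (an individual's weight
never changes); within a sex all individuals are exchangeable. The only
heterogeneity is the male:female weight ratio `bias`.

Two consequences of the fixed per-period sample size are worth keeping in
mind when reading results:

* **Within-period depletion.** Because sampling is without replacement,
  catching many males early in a period depletes the remaining male pool.
  At `bias` 4 with 40 captures from 300 the naive independent-draw
  expectation is 32 males + 8 females per period, but the exact expectation
  of the sequential scheme is ~31.5 males; simulated means land there, not
  at 32.
* **A rising bias starves one sex of data.** The total captured per period
  is fixed, so at high bias very few females are captured; per-sex estimates
  become noisy, right-skewed, and at the extreme non-identifiable (no female
  recaptures at all).

### Open populations (robust design)

Twelve sampling periods in four primary blocks of three secondaries.
Within a primary the population is closed; after periods 3, 6, and 9 fixed
numbers of individuals of each sex emigrate to, and immigrate from, a
neighbouring pool initialised with the same size and sex composition as the
study population. Emigration happens before immigration; selections are
uniform within sex; emigrants join the neighbour pool and can return later
(the pools partition a fixed universe of individuals, so conservation is
structural). The presence matrix marks an individual available for a period
iff it is resident when that period is sampled; captures are drawn from
residents only.

The truth record reports, per replicate, the per-period abundance and the
number of individuals of each sex present in *all* twelve periods — the
"present throughout" population that the robust-design estimator targets.

### What the generator does not emulate

Real capture effort varies over time (the simulator fixes captures per
period, not effort); real heterogeneity is usually continuous within sex,
not a clean two-group mixture; there are no births/deaths; migration counts
are deterministic per interval rather than stochastic rates. Passing tests
therefore demonstrate the estimators' behaviour under a sharp two-group
heterogeneity with fixed sample sizes — the idealised regime in which the
pooled-vs-separated comparison is cleanest — not performance on field data.

## Estimators

### Closed-population log-linear models

All closed models are Poisson regressions of the capture-frequency counts
`f_1..f_t` on the number of captures `i`, with offset `log C(t, i)`:

    log E[f_i] = log C(t, i) + b0 + b1 * i + (model terms)

so the unobserved cell (`i = 0`, offset 0) is estimated by `exp(b0)` and
`N_hat = n + exp(b0)`. Model terms:

* **M0** — none. The two score equations reduce to
  `n = N (1 - (1-p)^t)` with `p = total_captures / (N t)`; this is the
  *conditional* maximum-likelihood estimate. The package also ships a
  brute-force integer search over the *unconditional* likelihood (including
  the `C(N, n)` term) as an independent oracle; the two differ by roughly
  one to two animals at `N = 300` with these capture rates (the conditional
  estimate is slightly larger), and by more in sparse tables.
* **MhChao** — one free parameter per cell `i >= 3` (empty cells are
  saturated at zero and dropped). Those cells are then fitted exactly and
  the abundance is determined by the singleton/doubleton cells alone, with
  closed form `N_hat = n + (t-1)/t * f1^2 / (2 f2)`. Note the `(t-1)/t`
  factor: the classical Chao moment estimator `n + f1^2/(2 f2)` (also
  provided, with the `f2 = 0` bias-corrected branch, as `chao_moment_estimate`)
  is the same construction without it. Negative fitted cell parameters
  violate the lower-bound interpretation and are flagged in
  `diagnostics["chao_eta_negative"]`, not silently refitted.
* **MhDarroch** — extra column `i^2 / 2`.
* **MhPoisson** — extra column `a^i - 1`, default `a = 2` (exposed).

Standard error by the delta method on the unobserved-count scale with the
multinomial correction, `var(N_hat) = f0 + f0^2 var(b0)`. Deviance, BIC
(from the Poisson log-likelihood over frequency cells), and Pearson
residuals are reported for fit assessment. Exact parity with any particular
software package's variance formulas is not claimed.

Degenerate inputs fail loudly rather than returning a number: no recaptures
at all (abundance non-identifiable; the likelihood increases without bound),
a single occupied capture-count class (except the all-captured-every-period
case, where M0 returns `N_hat = n` with `p_hat = 1`), divergence of the
unobserved count (`b0 > 30`), or IRLS non-convergence.

### Pooled vs separated estimation

Pooled ("combined") data are heterogeneous whenever `bias != 1`, so the
pooled fit uses MhChao; when the absence of bias is known (the `bias = 1`
study arm) M0 is used instead. Separated mode fits M0 within each sex —
separation removes the only heterogeneity the generator creates — and
reports `N_m + N_f` and the sex ratio `N_m / N_f`. A sex with no observed
individuals, or a failed per-sex fit, marks the whole separated estimate
failed with a per-group reason.

### Robust design

Pollock's ad hoc composite: fit the designated closed model (MhChao pooled,
M0 per sex) to each primary period's own frequency table, giving
`N_hat_j` and per-primary detection probabilities `p*_j = n_j / N_hat_j`;
then estimate staying probabilities from the collapsed per-primary detection
histories: among individuals seen in primaries `<= j`, the fraction seen
again after `j`, divided by `1 - prod_{k>j}(1 - p*_k)`. The target quantity
is `N_throughout = N_hat_1 * phi_1 * phi_2 * phi_3`.

Numerical choices: staying-probability estimates slightly above 1 are
routine sampling noise (the ratio of two near-equal proportions) and are
retained — truncating them at 1 would bias `N_throughout` down by several
percent even with zero migration — but flagged in diagnostics; estimates
above 1.5 or non-positive detectability fail the fit. Known limitations:
the three-period within-primary fits are sparse at the default capture
rates, so per-primary abundances are right-skewed (replicate medians are
better centred than means), and the staying-probability correction assumes
individuals seen by interval `j` would remain available for all later
primaries, which under heavy turnover biases `N_throughout` modestly
downward (roughly -10% at the strongest balanced-turnover setting tested).
Per-sex fits at strong bias frequently encounter primaries with no
recaptures of the rarer-captured sex; these are genuinely non-identifiable
and are reported as failures rather than as arbitrary large numbers. A
consequence, documented by the test suite, is that the surviving per-sex
estimates are conditioned on having recaptures and average slightly *below*
truth at high bias — mean-inflation from quasi-divergent fits is exactly
what this package refuses to produce.

## Tests of equal catchability

All five operate on captured individuals only (uncaptured animals have
unknown sex in real data). Significance is counted at alpha = 0.05 in the
replication studies (a conventional default; exposed as a parameter).

* **Zero-truncated Poisson**: rate fitted by moment matching
  (`lambda / (1 - e^-lambda)` = mean captures per captured individual,
  solved by Brent's method), chi-square goodness of fit with the model tail
  beyond `t` folded into the top cell and tail cells pooled until every
  expected count is >= 1; df = retained cells - 2. Mean captures of exactly
  1 (no recaptures) is a degenerate case and returns a NaN p-value with an
  explanatory note rather than a test result.
* **Chapman-style zero-truncated binomial**: as above but against
  `Binomial(t, p_hat)` truncated at zero, with `p_hat = total / (N_hat t)`
  from the M0 fit. The historical test this emulates is specified only
  loosely in the literature; the concrete formulation used here is recorded
  in each result's `method_detail`.
* **Sex chi-square**: 2x2 recaptured (>= 2 captures) vs never-recaptured by
  sex, with continuity correction. The correction makes the test
  conservative at small expected counts (measured type-I rate ~0.03 at 20
  captures/period).
* **Sex Fisher**: exact conditional test of the 2xK sex-by-capture-count
  table — scipy's hypergeometric test for 2x2, full network enumeration
  while the table space is small, otherwise Monte-Carlo sampling from the
  multivariate hypergeometric null (1999 tables, fixed seed, reported in
  `method_detail`), with the add-one p-value estimator.
* **Wilcoxon-Mann-Whitney**: two-sided normal approximation with the
  tie-correction term in the variance and no continuity correction, on
  per-individual capture counts. With all counts tied the statistic sits at
  its null mean and p = 1 by construction. For very small groups the
  normal approximation can drift from the exact permutation p-value by more
  than 0.1 in the middle of the distribution (heavily tied counts); near
  the 0.05 decision threshold at the study's sample sizes it is accurate.

## Replication studies

`experiments` sweeps bias grids (closed/open: 1, 1.5, 2, 3, 4; tests: up to
6) with 250 replicates per level by default. Per-replicate seeds derive
deterministically from (root seed, bias, replicate index), so any replicate
can be reproduced in isolation and identical specs give byte-identical
tables. Failed fits are counted and excluded from aggregate means; open
study tables report means *and* medians (separated-mode estimates are
right-skewed at high bias) of percent differences against each replicate's
own present-throughout truth.

The acceptance suite scales one study down: the open-population sign checks
run 100 replicates per series-by-bias cell (the effects probed are tens of
percentage points), while all quantitative reproductions use the full 250.
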