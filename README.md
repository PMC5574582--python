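# markrecap

Mark-recapture simulation and estimation with **sex-biased catchability**.

In many wildlife populations one sex is more catchable than the other (for
example, males ranging widely during the mating season). This heterogeneity
biases two things at once: closed-population abundance estimates, and the
naive sex ratio computed as marked males / marked females. A standard remedy
is to treat males and females as separate populations — estimate
N&#770;<sub>m</sub> and N&#770;<sub>f</sub> independently, report
N&#770;<sub>m</sub> + N&#770;<sub>f</sub> for abundance and
N&#770;<sub>m</sub> / N&#770;<sub>f</sub> for the sex ratio. `markrecap`
provides Monte-Carlo machinery to quantify how much that remedy helps, and
how well common tests of equal catchability detect the problem in the first
place.

The package contains:

* **Simulators** — a closed population with 8 sampling periods, and an open
  population under Pollock's robust design (12 periods in 4 primary blocks of
  3, with migration through a neighbouring pool between blocks). In each
  period a fixed number of distinct individuals is captured by sequential
  weighted sampling without replacement, males `bias` times as likely per
  draw as females.
* **Closed-population estimators** — Poisson log-linear models on the
  capture-frequency counts `f_1..f_t` with offset `log C(t, i)`:
  M0 (equal catchability) and the Mh heterogeneity family (Chao lower bound,
  Darroch, Poisson). The intercept estimates the unobserved count, so
  N&#770; = n + exp(&beta;&#770;<sub>0</sub>), with a delta-method standard
  error, deviance, BIC, and Pearson residuals for fit assessment.
* **Robust-design composite** — within-primary closed fits plus
  Jolly-Seber-type staying probabilities on the collapsed per-primary
  histories, targeting the number of individuals present during the entire
  study: N&#770;<sub>throughout</sub> = N&#770;<sub>1</sub> &middot;
  &phi;&#770;<sub>1</sub>&phi;&#770;<sub>2</sub>&phi;&#770;<sub>3</sub>.
* **Five tests of equal catchability** — zero-truncated Poisson and
  Chapman-style zero-truncated binomial goodness-of-fit tests (pooled
  frequency-of-capture distribution), and three subgroup tests on the sex
  labels: a continuity-corrected 2&times;2 chi-square of recaptured vs
  never-recaptured, an exact/Monte-Carlo Fisher test of the full
  sex &times; capture-count table, and a tie-corrected
  Wilcoxon-Mann-Whitney test on per-individual capture counts.
* **A replication runner** that sweeps bias grids with 250 replicates per
  level and emits summary CSV tables, plus a `markrecap` command-line
  interface and delimited / MARK `.inp` capture-history I/O.

## Worked example

Simulate a closed population of 300 (150 males, 150 females) in which males
are twice as catchable, with 40 individuals captured in each of 8 periods:

```sh
$ markrecap simulate-closed --population-size 300 --captures-per-period 40 \
      --bias 2 --seed 42 --out example.csv
true N = 300 (150 male / 150 female); 204 individuals observed -> example.csv

$ markrecap fit example.csv --model MhChao | head -4
quantity        value
model   MhChao
N_hat   322.3955
se      28.8591
```

The same data through the Python API, estimated with the sexes pooled versus
separated:

```python
import numpy as np
from markrecap import (ClosedSimConfig, simulate_closed, marked_counts,
                       estimate_with_grouping)

sim = simulate_closed(ClosedSimConfig(captures_per_period=40, bias=2.0),
                      np.random.default_rng(42))
mc = marked_counts(sim.matrix)
sep = estimate_with_grouping(sim.matrix, "separated")
```

which gives

```
marked: 123 males, 81 females, ratio 1.52
separated: N_m = 162.2, N_f = 156.6, N = 318.9, ratio 1.04
combined MhChao: N = 322.4 (se 28.9)
```

The naive marked ratio (1.52) badly overstates the true 1:1 sex ratio, while
the ratio of per-sex M0 estimates (1.04) recovers it. The five
equal-catchability tests on the same data show why the pooled
goodness-of-fit tests are not to be relied on — only the subgroup tests see
the twofold bias:

```
$ markrecap test-catchability example.csv
test        statistic  df  p_value   method
chapman     2.0887     2   0.351926  zero-truncated binomial, p_hat=0.1341, ...
ztp         0.4726     3   0.924867  zero-truncated Poisson, lambda_hat=0.9798, ...
sex_chisq   5.5318     1   0.018673  2x2 recaptured/not by sex, continuity corrected
sex_fisher  11.1861        0.008500  2x5 Monte-Carlo (1999 tables, seed 20170829)
sex_wmw     6051.5000      0.003032  asymptotic, tie-corrected variance, ...
```

Full replicated studies (250 populations per bias level) run through the
`replicate` subcommand, e.g.

```sh
markrecap replicate --study tests --bias-grid 1,1.5,2,3,4,5,6 \
    --reps 250 --seed 0 --out tests_40.csv
```

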