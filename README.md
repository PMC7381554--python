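# paradetect

Does fluid preservation (formalin fixation followed by ethanol storage, the
standard protocol of ichthyological collections) change how many parasites a
dissector finds in a fish? `paradetect` implements the statistical machinery
of that question as a tested Python pipeline: synthetic parasite-count
cohorts with realistic aggregation, per–host-parasite-pair negative-binomial
models with Bonferroni screening, fixed-effects meta-regression over the
per-pair treatment effects, and a simulation-based power analysis for
planning such experiments. It is aimed at parasite ecologists and
biostatisticians who work with overdispersed count data from paired
experimental designs.

## The models

**Counts.** Parasite burdens are aggregated, so each host–parasite pair is
modelled as NB2: `Y ~ NB(mu, k)` with `Var(Y) = mu + mu^2/k` and log-link
mean

```
log mu = b0 + b1 * 1{preserved} + b2 * length + u_tow,   u_tow ~ N(0, s^2)
```

(the tow random intercept applies to English sole only, which were collected
over several trawl tows). A pair's published prevalence `P` and mean
abundance `mu` are reconciled into a single NB law through the
zero-probability identity `1 - (k/(k+mu))^k = P`, solved for `k` by
root-finding on `log k`.

**Screening.** Pairs with pooled prevalence > 5% are retained; each retained
pair's treatment coefficient `b1` gets a Wald z-test, Bonferroni-corrected
across the whole retained family (m pairs), so the two-sided significance
threshold is `|z| > qnorm(1 - 0.05/(2m))` — about 3.11 at m = 27.

**Meta-regression.** Each pair contributes an effect size `y = b1` with
variance `v = SE^2`. Fixed-effects weighted least squares (weights `1/v`)
gives the cumulative effect and moderator models (life stage + taxonomic
group; organ of detection as non-exclusive presence/absence dummies with
muscle as reference), with the residual-heterogeneity statistic `Q_T`
(chi-square, k − p df) and moderator omnibus `Q_M` (p − 1 df).

**Power.** For a two-arm design, counts are drawn from `NB(mu0, k)` and
`NB(mu0 + delta, k)` where `delta` solves Cohen's
`d = delta / s_pooled`, `s_pooled^2 = (v(mu0) + v(mu0+delta))/2`. Each
replicate fits null and treatment NB GLMs; the treatment model "wins" when
its AIC is more than 2 units lower. Power is the win fraction over 1,000
replicates.

## Worked example

```python
from paradetect import PowerConfig, run_power_cell

res = run_power_cell(PowerConfig(n_per_group=50, effect_size_d=0.57,
                                 replicates=1000, seed=1))
print(f"delta = {res.mean_difference:.2f} parasites/host, "
      f"power = {res.power:.2f} +/- {res.mc_se:.3f}")
```

prints

```
delta = 1.50 parasites/host, power = 0.83 +/- 0.012
```

i.e. a moderate standardized effect of d = 0.57 corresponds, under the
default calibration (control mean 2.0 parasites/host, k ≈ 1.95), to a
difference of 1.5 parasites per host, and 50 fish per treatment detect it
about 83% of the time — comfortably above the conventional 0.80 planning
threshold.

The full experiment pipeline runs from the shell:

```bash
paradetect run-all --seed 1 --out-dir out/        # simulate -> screen -> meta
paradetect power --n-grid 10,25,50,100 --d-grid 0.2,0.57,0.8 --out power.csv
paradetect litsummary
```

`run-all` writes a cohort CSV, per-species length-balance checks, the
Bonferroni-screened pair table (with z-scores), the meta-regression tables
(coefficients, SEs, z, p plus `Q_T`/`Q_M` footers) and a manifest with
content hashes; the same seed always reproduces the same hashes.

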