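# Methods

## The estimand and the design

The package models a paired preservation experiment on fish parasites.
Fish of three species (walleye pollock, eulachon, English sole) are sorted
by standard length, paired, and one member of each pair is assigned to the
preservation treatment by a fair coin; the other becomes the control. The
estimand for each host–parasite pair is the log ratio of mean detected
abundance (preserved / control) — a change in *detectability*, since the
true burden is fixed at collection.

## Count model

Parasite counts are aggregated (variance far above the mean), so all count
models are NB2 with log link: `Var(Y) = mu + mu^2/k`. The per-pair model is

    log mu_i = b0 + b1 * preserved_i + b2 * length_i + u_{tow(i)}

with `u_tow ~ N(0, sigma^2)` for English sole only (its specimens came from
several trawl tows; the other species have no usable grouping). Standard
length enters uncentred in millimetres — this shifts only the intercept,
not the treatment contrast.

### Fitting

The NB likelihood is maximized directly (L-BFGS-B with analytic gradients)
over `(b, log k)`, with `k` bounded to `[1e-3, 1e6]`. Boundary hits are
flagged rather than raised: equidispersed or sparse pairs legitimately pin
`k` at the Poisson end, and the screening loop has to survive them. SEs
come from the numerically differentiated observed information at the
optimum; when `k` sits on a bound it is profiled out of the SE computation.
Convergence: relative log-likelihood tolerance 1e-8, at most 500
iterations; failure sets `converged = False` instead of raising.

The mixed model integrates the tow intercept out of the likelihood by
adaptive Gauss–Hermite quadrature: each group's integrand is centred at its
Laplace mode (damped 1-D Newton) and scaled by its curvature, then 5 GH
nodes are applied (node count configurable; 5 vs 15 nodes move the
log-likelihood by < 1e-3 on typical fits). `sigma` is bounded below at 0;
estimates at the boundary collapse to the fixed-effects GLM, and a
single-group input falls back to the GLM with a warning. Cross-checks in
the test suite: statsmodels `NegativeBinomial` for the GLM and R `glmmTMB`
for the GLMM (agreement to ~1e-3 on coefficients on fixture data).

AIC counts every estimated parameter: fixed effects + dispersion
(+ random-intercept SD for the mixed model). Wald p-values use the
standard-normal reference for count models; the Gaussian length-balance
models (statsmodels MixedLM, REML; OLS when no grouping exists) report t
statistics on `n − p` residual degrees of freedom.

## Screening and multiplicity

Prevalence (fraction of hosts infected, both arms pooled) must exceed 5%
*strictly* for a pair to enter the analysis; rarer pairs carry too little
information for a count model. The Bonferroni family is all retained pairs
across all three species jointly (m ≈ 27 under the default cohort), giving
a two-sided z threshold of about 3.11. Non-converged fits remain in the
family (conservative accounting) but are reported non-significant.

Wald z-tests on NB fits are anticonservative in the far tail at these
sample sizes (n ≈ 70–110 per pair) and dispersions (calibrated k between
0.04 and 0.5): the realized two-sided tail beyond the m = 27 Bonferroni
threshold is roughly 2–3 times its nominal 0.0019. The test suite measures
the consequence directly — over 200 replicate null cohorts at the study's
scale the realized family-wise error is about 0.08–0.10 rather than the
nominal 0.05, and the corresponding suite check deliberately fails to
document it. The package's SEs agree with statsmodels' independent NB
implementation to all printed digits on the same fits, so this is a
property of Wald screening on heavily overdispersed counts, not of the
implementation; an analysis wanting strict FWER control at these sizes
should prefer likelihood-ratio or parametric-bootstrap p-values, which the
published z/p reporting convention (and hence this package's screening
surface) does not use.

## Meta-regression

Effect sizes are the per-pair treatment coefficients with `v = SE^2`.
Because every pair is measured on the same cohort and the model is a
fixed-effects one, estimation is closed-form weighted least squares with
known weights `1/v`; `Cov(b) = (X'WX)^{-1}` with no residual scale
estimate, `Q_T` is the weighted residual sum of squares on `k − p` df, and
`Q_M` is the Wald chi-square that all non-intercept coefficients vanish
(`p − 1` df). No between-pair variance component (`tau^2`) is estimated —
the model is deliberately fixed-effects, not random-effects.

Codings: the stage+group model uses treatment contrasts with reference
*adult* and *Acanthocephala* (the group absent from the published
coefficient rows); the organ model uses muscle as the intercept and one
non-exclusive 0/1 indicator per remaining organ, so a parasite found in
several tissues sets several indicators. `Q_M` is invariant to the
reference choice (tested by re-encoding).

## Synthetic cohorts

The generator is first-class code, not a fixture. Each host–parasite pair
has a profile (prevalence target, mean-abundance target, stage, group,
organ set); the shipped default file mirrors the 27 screened pairs of the
motivating experiment with their printed prevalence/mean values. The NB
dispersion is calibrated per pair from the zero-probability identity
`1 − (k/(k+mu))^k = P`, solved on `log k`. Targets above the Poisson bound
`1 − exp(−mu)` are unattainable under overdispersion; those profiles fall
back to Poisson with a flag (none of the default profiles need it).

Because published summaries pool both arms, the generator sets the control
mean to `2 * target / (1 + exp(r))` so the pooled mean matches the target
for any treatment log-ratio `r` (and exactly equals it at `r = 0`).
Lengths are uniform on each species' published range, shifted to match the
published mean. Treatment labels come from the stratified pair
randomization; an odd leftover fish is assigned by an independent coin
toss (the original experiment's unequal arm sizes suggest attrition, which
the generator exposes as a `dropout` fraction defaulting to 0). Tow
intercepts default to SD 0.25 across 7 tows — no tow-level variance is
published, so this is a modest-clustering choice, config-exposed. Each
simulated count row is labelled with one organ drawn uniformly from the
profile's organ set; the screening–meta bridge then uses the organs
actually observed on positive rows, mirroring a "where parasites were
found" protocol.

What the generator does *not* emulate: stage/group/organ assignments per
pair are biologically plausible but synthetic (the source tables do not
print them per pair); counts are conditionally independent across taxa
within a host (no parasite–parasite interactions); lengths do not affect
counts by default (`length_slope = 0`); detection is all-or-nothing per
parasite with no dissector effects. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative model,
not fidelity of any particular biological co-occurrence structure.

## Power analysis

Cohen's `d` is bridged to a raw mean difference through the NB variance
law: `d = delta / s_pooled` with `s_pooled^2 = (v(mu0) + v(mu0+delta))/2`,
solved by root-finding (monotone in `d`). Note the bridge has a ceiling:
as `delta` grows, `s_pooled` grows like `delta / sqrt(2k)`, so `d` cannot
exceed `sqrt(2k)` (≈ 1.97 at the default `k`); larger requested effects
raise a domain error rather than silently saturating.

Defaults: control mean 2.0 parasites/host and `k` solved in closed form so
that `d = 0.57` corresponds to exactly 1.5 parasites/host (`k ≈ 1.946`);
the same calibration puts `d = 0.78` at ≈ 2.35 parasites/host. Both are
config-exposed for sensitivity analysis. Each power cell draws `n` counts
per arm, fits intercept-only and treatment NB GLMs, and scores a win when
the treatment model's AIC is more than 2 units lower — with one added
parameter this is exactly an LRT > 4 rule (and at margin 0, LRT > 2;
identity checked per-replicate in the tests). Cells run on independent
child seeds; per-replicate fit failures count as losses and are logged.
Reported power always carries its Monte-Carlo SE `sqrt(p(1−p)/reps)`.

## Problem sizes used in the shipped checks

The test suite runs the stochastic checks at sizes chosen to keep the
default run short while leaving binomial noise well inside the asserted
margins: power cells at 300 replicates (MC-SE ≈ 0.023, folded into the
assertions as a 2-SE allowance), family-wise-error control over 200
replicate cohorts at the full study scale, generator moment checks at
n = 1e5, meta-regression coverage at 1,000 replicates, GLMM variance
recovery over 100 replicate fits. `scripts/acceptance.py` runs the two
headline power cells at the full 1,000 replicates.

## Known limitations

- Wald (not profile-likelihood or bootstrap) inference throughout the
  screen; mildly anticonservative for very sparse pairs.
- Exact agreement with ADMB/TMB-based fitters is not expected beyond ~1e-2
  relative on hard pairs; optimizers and quadrature differ.
- The organ moderator model inherits whatever confounding exists between
  organs and taxa (e.g. a single taxon may be the only occupant of an
  organ, making that coefficient a pair effect in disguise).
- No zero-inflated or NB1 families; no crossed or nested random effects;
  no random-effects meta-analysis.
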