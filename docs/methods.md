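# Methods

## Scope and model chain

`crcrisk` implements the risk-modelling chain used in risk-adapted
colorectal-cancer (CRC) screening studies:

1. **Weighted scores.** A sex-specific lifestyle score
   `LS = Σ_k β_k x_k` over binary unfavorable-lifestyle indicators
   (high waist circumference, red-meat consumption, low fruit intake and,
   for men, smoking ≥ 15 pack-years) and a polygenic risk score
   `PRS = Σ_k β_k g_k` over 0/1/2 risk-allele dosages, with `β_k` per-factor
   / per-allele log odds ratios.  Candidate SNPs failing a 1-df chi-square
   test of Hardy–Weinberg proportions at `α` (default 0.05) are excluded
   before PRS construction.
2. **Relative risks.** Sex-stratified case-control odds ratios for the
   four-level lifestyle × PRS exposure (favorable+lower PRS as reference)
   against three contrasts: any neoplasm, non-advanced adenoma and advanced
   neoplasm, each versus healthy controls.  Fits are maximum-likelihood
   logistic regressions with Wald intervals; an LS×PRS product term is
   available as a sensitivity analysis.
3. **Absolute risk.** A Gail-type projection of the 10-year absolute risk of
   colorectal neoplasm for each profile, combining the relative risks with a
   registry-style composite incidence hazard calibrated through the
   attributable-risk identity and with competing non-CRC mortality.
4. **Screening yield.** Risk-adapted triage (high risk → colonoscopy; low
   risk → quantitative FIT, positive ≥ 100 ng Hb/ml → colonoscopy) evaluated
   by positive predictive value (PPV) and the number of colonoscopies needed
   to detect one lesion (NNS), for advanced and for any neoplasm.

## Absolute-risk model

Let `h(a)` be the composite (population-average) incidence hazard in age
band `a`, `m(a)` the competing mortality hazard, and `{(P_g, RR_g)}` the
population prevalence and relative risk of the risk profiles.  The
reference-profile baseline hazard is

    h1(a) = h(a) / Σ_g P_g RR_g  =  h(a) (1 − AR),   AR = 1 − 1/Σ_g P_g RR_g,

so the prevalence-weighted hazard reproduces `h(a)` exactly.  The divisor
may vary by band when age-specific attributable-risk parameters are
supplied (the default whenever the distribution carries band columns).
For profile `g`, with `λ_i = RR_g · h1_i` and `μ_i = m_i` constant on band
`i` of width `w_i`, the cause-specific cumulative incidence is accumulated
exactly per band:

    risk += S · λ_i/(λ_i+μ_i) · (1 − e^{−(λ_i+μ_i) w_i}),
    S    *= e^{−(λ_i+μ_i) w_i},

with `S` the all-cause survival entering the band and the limit `λ_i w_i S`
taken when `λ_i + μ_i = 0`.  No quadrature is involved; the test suite
cross-checks the band walk against an independent fine-grid Runge–Kutta
integration of the same ODE system (dt = 10⁻³ yr, agreement < 10⁻⁶) and
asserts refinement invariance (splitting a band changes nothing at 10⁻¹²).

Because risks are not linear in hazards, the prevalence-weighted profile
risks match the uncalibrated population projection only approximately; the
discrepancy is below 1 % relative whenever the 10-year risk is under ~10 %,
which the tests assert on the synthetic rate tables.

**Interval estimates.** The variance formula behind published absolute-risk
CIs in this setting is typically unstated; this package uses a parametric
bootstrap as its default: each of ≥ 2,000 seeded draws resamples every
profile's log-RR from `N(log RR_g, se_g)`, re-runs the calibration with the
fixed prevalences, re-projects, and takes the 2.5/97.5 percentiles.
Registry-rate uncertainty is ignored (registry denominators are large);
`uncertainty=False` gives a rates-fixed point estimate only.

**Units and conventions.** Rate files are per 100,000 person-years and
converted on read; internal hazards are per person-year.  Bands are
half-open `[start, end)`, contiguous; ages are exact reals; 5-year bands
mirror registry publication practice.  The shipped
`default_rate_table` is *synthetic*: magnitudes plausible for
adenoma-inclusive colorectal neoplasm in a screening-age East-Asian
population (incidence 220–580/10⁵ rising over ages 50–85, competing
mortality 400–5,500/10⁵; women scaled by 0.8/0.75).  Published absolute
risks can only be reproduced with the original registry incidence and
attributable-risk tables supplied as inputs; the package instead guarantees
the calibration, oracle-agreement and ordering properties above.

## Score construction choices

* HWE filter: plain 1-df chi-square against `p̂²/2p̂q̂/q̂²`; the significance
  level is configurable (0.05 default, not a universal standard).
  Monomorphic variants are excluded with their own reason code.
* Quantile convention: linear interpolation between order statistics
  (NumPy's default), configurable, because group membership of boundary
  subjects depends on it.  Ties at the median/90th-percentile cutpoint go
  to the upper (unfavorable / higher) group, matching the "≥ cutoff"
  definition of the higher-PRS group.
* Subjects with any failed genotype call among retained SNPs are dropped
  before scoring, not imputed — the same behaviour as excluding samples
  with failed SNP detection upstream.
* Lifestyle-score weights come from a supplied weight table or, by default
  in the pipeline, are refit per sex on the analysis cohort (logistic
  log-ORs of any neoplasm on that sex's indicator set).  A univariate
  screening helper (`screen_factors`, p < 0.1) is provided but not
  hard-wired, since the factor sets are fixed by convention here.

## Association-model choices

* The adjustment set behind published model-based ORs is usually not fully
  printed; the default here is age (continuous), configurable.  Crude 2×2
  ORs recomputed from printed cell counts therefore differ from adjusted
  ORs, and the package exposes both routes.
* Wald intervals (not profile likelihood), matching standard epidemiological
  reporting.  Zero cells in crude tables get the Haldane–Anscombe 0.5
  correction with an explicit warning.  Logistic fits flag coefficients
  beyond ±15 log-odds as probable separation and refuse rank-deficient
  designs.

## Synthetic cohort generator

The generator emulates the statistical margins of a Chinese screening-trial
case-control set (n = 1,880; 51.3 % male; outcome composition 1,213 / 464 /
203 controls / non-advanced / advanced):

* **Genotypes**: per variant, dosages from `((1−p)² + fpq, 2pq(1−f), p² + fpq)`
  with risk-allele frequency `p` and inbreeding coefficient `f`; `f = 0` is
  HWE, `f ≈ 0.6` reliably fails the filter at the default sample sizes.  An
  `exact_frequencies` mode realizes genotype *counts* by largest-remainder
  rounding so a panel's HWE pass/fail pattern is deterministic — used for
  the 24-SNP / 5-failing fixture.  The default panel draws per-allele ORs
  uniform in 1.05–1.30 and frequencies in 0.10–0.90, typical of validated
  CRC loci.
* **Lifestyle**: unfavorable-level prevalences per sex default to the
  screening-cohort margins (men: red meat 0.935, low fruit 0.393,
  smoking ≥ 15 py 0.481; women: red meat 0.914, low fruit 0.479).  A
  dichotomized waist prevalence is not published, so 0.50 (median split) is
  used.  Pack-years are drawn consistently with the smoking indicator.
* **Outcome**: two-stage logistic (any neoplasm given covariates and
  centered weighted dosages; advanced given neoplasm) rather than a
  multinomial model — it mirrors the three case-control contrasts and is
  simpler to parameterize.  Default effect sizes are modest log-ORs chosen
  to reproduce the qualitative risk gradients of such cohorts (male excess,
  age trend, unfavorable-lifestyle and per-allele effects); default intercepts
  (−1.5592, −0.9828) were calibrated once by bisection on a 200,000-subject
  draw so the marginal prevalences match 667/1880 and 203/667
  (`calibrate_outcome_intercepts` re-runs this for custom settings).
* **FIT**: class-conditional sensitivity (advanced 0.31, non-advanced 0.10)
  and specificity 0.92 are plausible defaults for a quantitative FIT at the
  100 ng Hb/ml cutoff, *not* estimates from any specific trial (in-trial
  operating characteristics were not published); they are config fields.
  A quantitative mode draws ng Hb/ml values consistent with the flag.
* **Fixtures**: `reference_cohort` reproduces the printed sex × outcome and
  factor margins exactly (counts assigned, not sampled) so summary
  statistics such as the male fraction and colonoscopy-only yield are
  seed-independent; `sample_flow_frame` reproduces the 3,825 → 94/1,294/557
  → 1,880 sequential QC exclusion flow with disjoint flags.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, correlated lifestyle factors, site/centre effects, participation
behaviour, lesion location/size, or repeat screening rounds.  Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generating model, not predictive performance on real screening data.

## Screening-yield choices

* The exact high-risk predicate combining LS and PRS used in published
  risk-adapted scenarios is generally figure-only; the triage rule is a
  configurable truth table over the four cells with shipped presets
  `both_high`, `either_high`, `ls_only`, `prs_only`, `all_high`.
* Detection is person-level: a colonoscopy detects the subject's true
  most-advanced lesion class, so `NNS × PPV = 1` exactly at full precision.
  Display rounding is 1 decimal; tests round only at the assert.
* Zero colonoscopies is an error; zero detections reports NNS = ∞ with a
  flag.

## Problem sizes and determinism

Simulation-based checks use 200 replicates for CI-coverage/rejection-rate
calibration (n = 5,000 per replicate), 2,000 SNPs (n = 2,000 each) for HWE
test calibration, 100 random band configurations for the projection oracle,
and 200–500 bootstrap draws in fast paths (the API default is 2,000).
All randomness flows through `numpy.random.default_rng` seeds carried in
configs; a fixed config + seed reproduces every output file byte for byte
(output headers embed the tool version, seed and a config hash, never
timestamps).

## Known limitations

* The absolute-risk module treats rate tables as inputs; whether a study
  used adenoma-inclusive neoplasm incidence or CRC incidence scaled by an
  adenoma multiplier must be resolved by the user's rate file.
* Wald inference degrades in sparse cells (the warning machinery flags
  separation but does not fall back to exact or penalized methods).
* The two-stage outcome model cannot encode covariate effects that differ
  between non-advanced and advanced lesions beyond the advanced-stage
  logistic's own terms.
* No multiple-testing adjustment is applied anywhere (none is standard in
  this reporting format).
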