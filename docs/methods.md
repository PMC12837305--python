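# Methods

`acthflow` re-implements, as a tested pipeline, a year-long observational
analysis of baseline plasma ACTH in healthy standard donkeys, miniature
donkeys and donkey–horse hybrids (mules/hinnies) in the US. This note
records the models, the synthetic-data conditions, the numerical choices,
and what the validation suite does and does not establish.

## Sampling design

Eighteen sampling events cover June 2019 – May 2020: twice monthly June
through November (first/second half of the month), once monthly December
through May. The five events from the second half of August through the end
of October form the seasonal period `mid_aug_late_oct`; the other thirteen
form `early_nov_early_aug`. Event labels are canonical ASCII
(`September_16-30`); the typographic print form with en-dashes and trailing
underscores is accepted on input. Collection dates are optional — the event
label alone fixes temporal position — and are validated against the event's
half-month bounds when present. Age is classed binary: ≤ 15 years "young",
> 15 "senior" (15.0 exactly is young). Missing ACTH is a first-class state,
because the exclusion rules count months without a measurement.

## Outlier screening (ROUT)

Screening runs separately per equid type per sampling event. Because an
event is a single batch, the robust-regression step of ROUT degenerates to
an intercept-only robust fit:

1. Tukey-bisquare M-estimate of location, IRLS from the median, tuning
   constant c = 4.685 (95 % Gaussian efficiency), residual scale fixed at
   1.4826·MAD of the input (which makes the screen scale-equivariant),
   convergence when the centre moves < 1e-8 relative, max 100 iterations.
2. Residuals r_j = x_j − centre.
3. RSDR = 68.27th percentile of |r_j| (linear interpolation) × n/(n−1).
4. Two-sided p_j from a t distribution with n−1 df applied to |r_j|/RSDR.
5. Step-up false-discovery scan at rate q = 1 %: sort p ascending, flag the
   largest prefix with p_(i) ≤ q·i/n.

Events with n < 3 are unscreenable (no flags); identical values give
RSDR = 0 and a degenerate, flag-free event. A flagged event flags the whole
calendar month for that animal (the month is the exclusion unit; months
with two events have twice the chance of a flag, so this keeps unequal
replication fair). August spans both periods, so a flagged August counts
toward the period of whichever half was flagged; September and October are
wholly inside the mid period.

Animal classification: `outlier_suspected_ppid` if ≥ 3 flagged months fall
within a single period (the "or" in the rule is read per period, consistent
with the month being the unit of analysis; a pooled `total` rule is
available as an option); else `insufficient_data` if ≥ 3 calendar months
lack a measurement; else `apparently_healthy`. Only healthy animals reach
the downstream stages. The pre-enrollment screen (exclude if the
pre-enrollment ACTH strictly exceeds 40 pg/mL; missing values keep the
animal with a warning) is provided as a library operation for observed
cohorts; synthetic cohorts are generated post-enrollment.

Measured operating characteristics (seeded, re-run by the test suite and
`scripts/acceptance.py`): on clean Gaussian events of n = 20 the any-flag
rate is ≈ 1.3 % (≤ 2 %); a single 10-SD contaminant is detected ≥ 99 % of
the time; on default synthetic cohorts the animal-level exclusion has
sensitivity 1.0 and specificity ≈ 0.98 across 100 seeds. A few flags on
clean animals per cohort are expected and correct: the screen applies
normal-theory calls to raw (right-skewed lognormal) concentrations, so
single-month false flags occur, but three in one period is rare.

## Synthetic cohorts

Generative model, per animal i and event e:

    ln ACTH_ie = profile[type(i), e] + b_i + m_e + l_loc(i) + eps_ie
    b_i  ~ N(0, sd_id²)        sd_id = 0.32
    m_e  ~ N(0, sd_month²)     sd_month = 0.13 (mid) / 0.41 (early)
    l    ~ N(0, sd_location²)  sd_location = 2e-5  (near-zero, as observed)
    eps  ~ N(0, sd_resid²)     sd_resid = 0.42 (mid) / 0.53 (early)

Choices that matter:

* **Profile = ln of the published per-event medians.** The median of a
  lognormal variable is exp of its ln-scale location, so printed medians are
  the direct estimates of the seasonal ln-ACTH profile. (Printed arithmetic
  means would not serve: in the source cohort they are inflated by surviving
  extreme animals — single measurements of 946, 1054 and 1250 pg/mL — and
  ln(mean) profiles would shrink the hybrid–donkey contrast to a fraction of
  its published ln-scale value.) Consistency check built into the tests:
  median × exp(σ²/2) reproduces the printed arithmetic means, e.g.
  94.4 × exp(0.148) = 109.5 ≈ 109.6 for standard donkeys in late September.
  The one event with no published hybrid data (June_1-15) is filled by
  geometric interpolation between its calendar neighbours.
* **Variance components from the published mixed models.** The printed
  "SD = 0.17" for the early-period animal variance contradicts its own
  variance 0.10; the variance is taken as authoritative (SD 0.32) for both
  periods.
* **Cohort roster.** Group sizes 19/14/28 (the analyzed cohort), with
  location, sex and age-class marginals apportioned to the published
  composition and shuffled independently within each group (seeded), so
  covariates are not artificially correlated with each other or with animal
  order.
* **Injected PPID-like animals** are multiplicative: default inflation 20×
  with chronic (all-event) elevation. Pituitary dysfunction elevates
  baseline ACTH year-round, and the magnitude matches the extreme
  measurements in the source cohort (1054 pg/mL against an event median of
  53.2 ≈ 20×). A power analysis of the screen under the default variance
  components shows why a small factor would be wrong as a default: at 5×
  the per-event detection probability is only 0.67–0.79 (the bump is
  ≈ 2.6 total-SD on the ln scale), whereas at 20× it is ≥ 0.996, making
  animal-level sensitivity effectively 1. Inflation, the affected period
  and the number of affected months are all configurable.
* **Insufficient-data animals** are emulated by blanking whole calendar
  months (seeded choice of months).
* One record per animal per event; no assay noise, trailering stress,
  freeze–thaw effects, covariate-dependent missingness, or within-animal
  serial structure beyond the shared intercept (the analysis itself assumes
  compound symmetry). The real cohort's structural gaps (e.g. hybrids
  unsampled in early June, n = 2 events) are reproducible through
  configuration but are not part of the defaults.

Everything is reproducible from one integer seed; the plan (roster,
injections, blanked months) and the noise draws use separate derived
streams, so truth labels can be computed without generating data.

## Reference limits

Per group and sampling event (hybrids are the only group with ≥ 20
analyzable animals):

1. **Box–Cox** transform, λ by profile maximum likelihood over [−3, 3]
   (bounded scalar minimization, xatol 1e-5; exact ties with the log
   transform resolve to λ = 0). The transform and its inverse use
   expm1/log1p forms, so the round-trip is exact to 1e-10 even for λ → 0.
2. **Normality check**: D'Agostino–Pearson omnibus K² (transformed skewness
   and kurtosis z-scores, χ² with 2 df), reported per event; not computed
   for n < 8 or constant input. Its type-I error at n = 28 is ≈ 0.057
   (measured over 100 000 simulations) — the χ² approximation is known to be
   slightly anticonservative at small n.
3. **Robust limit** on the transformed scale: iterative biweight location
   (median start, 6 refinement passes, cut-off c·MAD with c = 3.7, raw MAD)
   and a biweight midvariance-style scale made consistent for the normal SD
   by an asymptotic factor computed by quadrature (≈ 1.248 at c = 3.7).
   Upper limit = location + t_{(1+cov)/2, n−1}·√(1+1/n) × scale; the default
   coverage 0.95 makes the URL the 97.5th-percentile bound of a two-sided
   95 % reference interval (coverage is configurable — the convention is not
   stated in the source). On clean Gaussian data the limit converges to the
   1.96 quantile; on contaminated data it moves far less than mean + 2 SD.
4. **Back-transform** by the exact inverse; **90 % CI** by percentile
   bootstrap (default B = 2000; every resample re-fits λ and the robust
   limit). A CI upper bound above 1000 pg/mL marks the event `ci_unstable`
   (it cannot be precisely estimated). Events with n < 20 are
   `insufficient_n` and are not estimated, following the guidance that the
   robust method needs more than 20 observations.

Measured: for lognormal(3, 0.5) events with n = 200 the median URL across
replications is within 0.5 % of the true 97.5th percentile; the bootstrap
90 % CI attains 90 ± 3 % empirical coverage. The per-replication absolute
error is ≈ 6 % — that is the sampling SD of any location-plus-scale
percentile estimate at n = 200, not estimator bias.

## Mixed models

Per period: REML fit of ln(ACTH) ~ fixed effect + (1|animal) + (1|event) +
(1|location), via a single-group variance-components parameterization
(statsmodels MixedLM). Candidate fixed effects (age class, sex, equid type;
reference level standard donkeys) are screened univariably at p ≤ 0.05 with
a joint Wald F test for multi-level factors; a multivariable model is
assembled only when two or more survive. The shared animal intercept
realizes compound-symmetry correlation among an animal's repeated measures;
`covariance_structure_aic` compares it against an independence structure by
REML AIC (ties favour compound symmetry). Collinearity: numeric predictors
with |Pearson r| > 0.8 are reduced to the first in declared order (0.8
exactly keeps both).

Numerical choices:

* The likelihood surface has a weakly identified location component that is
  nearly aliased with equid type (hybrids are almost all at one site), so
  each model is fitted with two optimizers (L-BFGS, Powell) and the higher
  restricted likelihood is kept. Fits agree with lme4 (REML) to ~1e-4 on
  fixed effects and variance components; one such cross-check is a test.
* The fixed-effect covariance is recomputed in closed form as
  (XᵀV⁻¹X)⁻¹ at the estimated components; the Hessian-based covariance can
  be indefinite when a component sits on the boundary.
* Inference uses a t reference with a containment-style df (number of
  animals − number of fixed-effect parameters) as a pragmatic stand-in for
  the Kenward–Roger adjustment, which none of the available Python mixed
  model implementations provide; the df method is recorded in the model
  metadata, and no conclusion of the pipeline rests on exact p-values.
* Estimated marginal means of equid type come from the univariable model's
  design rows; the three pairwise contrasts are Bonferroni-adjusted
  (p × 3, capped at 1). Percent differences back-transform ln-scale
  contrasts: 100·(1−e^β) "lower" for β < 0, 100·(e^β−1) "higher" for β > 0,
  CI endpoints mapped through the same monotone transform.
* Records with missing ACTH are dropped listwise within a period.
* Near-zero variance components are retained (floored at 0), mirroring the
  near-zero location variance the source analysis itself reports.

**What recovery means under these conditions.** The period model is
additive, but the generating profile has a within-period seasonal trend and
a type×event interaction. The REML fit therefore absorbs, on top of the
configured stochastic components, Var(weighted per-event profile means)
into the month component (+0.017 mid, +0.152 early) and the profile
interaction into the residual (+0.009 mid, +0.053 early); both corrections
are computed in closed form by `experiments.expected_variance_components`,
and the recovered means match them to < 0.01. Sign recovery: the hybrid
coefficient is negative in both periods in ≈ 98 of 100 seeded replications;
the period-2 miniature coefficient (+0.03 in the source, |z| ≈ 0.4) has a
sign that is statistically noise by construction, so no test asserts it.

## Pipeline

`run_pipeline` chains simulate → screen → describe → reflimits → model from
one YAML config (unknown keys rejected), writes all tables as CSV with
stable column order plus a manifest (versions, seeds, resolved config), and
expands the global seed into per-stage seeds via SeedSequence([seed,
stage_index]) so stages can be re-run in isolation. Outputs are
byte-identical across runs with the same seed. A stage failure aborts with
the stage named and removes partial outputs. The `acthflow` CLI exposes the
stages individually; the numbered scripts under `analysis/` are the
narrative drivers.

## Problem sizes

The validation suite uses: 10 000 clean events (FDR control), 2 000
contaminated events (detection), 100 seeded cohorts (exclusion rules),
200 replications for URL bias and 500 for bootstrap coverage (B = 300;
percentile-CI coverage is insensitive to B beyond a few hundred), 100 000
simulations for the normality test's type-I error, and 100 seeded cohorts
× 2 periods for mixed-model recovery. `analysis/06_validation_report.py`
re-runs the same studies at smaller sizes for a quick narrative report.

## Limitations

* The synthetic generator reproduces the study's *statistical* structure,
  not its data-collection quirks; passing tests show the pipeline's
  operating characteristics under lognormal, compound-symmetric conditions,
  not robustness to assay artefacts, serial correlation, or informative
  missingness.
* The exact robust/bootstrap variant of the original reference-limit
  software is not recoverable from its description; constants here
  (biweight c = 3.7, 6 iterations, percentile bootstrap) are documented
  defaults, and external agreement on the deposited cohort is expected at
  the level of the method class, not bit-for-bit.
* URLs are one-sided reference limits, not clinical decision limits; they
  flag the need for further diagnostics and cannot separate healthy from
  PPID-positive animals.
* With 4 location levels nearly aliased with equid type, the location
  variance is weakly identified; retaining it (as the source analysis did)
  occasionally lets it absorb part of the type contrast in finite samples.
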