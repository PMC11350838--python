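# Methods

`radonrisk` estimates the shape of the dose–response between spatial indoor
radon exposure (sIR, in Bq/m³ — a community-average radon concentration
assigned to a residence from survey maps) and lung-cancer case odds in a
multi-site case-control design. Because the individual-level data such
analyses run on are not publicly deposited, the package pairs every analysis
stage with a synthetic-cohort generator whose defaults emulate the documented
structure of a pooled five-site study (n = 14,489; 8,927 cases / 5,562
controls), so the whole pipeline is testable end to end.

## Outcome model

All stages share one site-stratified logistic likelihood. For subject *i*
with case indicator *y\_i*, covariates *x\_i* (sex, age, smoking status, age
at smoking initiation, time since cessation, pack-years) and site *s(i)*:

    logit P(y_i = 1) = alpha_{s(i)} + x_i' gamma + f(d_i)

where *d\_i* is the sIR exposure and *f* is the exposure term under study
(absent, binned, parametric excess-odds-ratio, or spline). "Conditional on
study site" is implemented as per-site fixed intercepts (no global
intercept) under unconditional maximum likelihood: with five large strata
this is asymptotically equivalent to conditional logistic likelihood, and it
supports offset-based profiling, which the threshold models need. A matched
conditional-likelihood backend is out of scope.

Encoding details that affect interpretation:

- age enters centered at 60 years (numeric conditioning only; odds ratios
  are invariant to the centering, which is verified by test);
- smoking status uses never-smokers as reference; the continuous smoking
  sub-fields (age started, years since quitting, pack-years) are 0 for
  subjects they do not apply to, with the status indicators absorbing the
  level shift;
- fits are Newton–Raphson with step-halving; convergence at max |score|
  < 1e-8 or relative log-likelihood change < 1e-10; the covariance is the
  inverse observed information; designs are rejected as rank-deficient at a
  singular-value ratio of 1e-8; coefficients beyond |20| on the log-odds
  scale raise a separation warning rather than being returned silently.

## Binned odds ratios

Exposure is cut into left-closed bins (default edges 4, 25, 50, 75, 100,
150, 200, 250, 300, 400, 835 Bq/m³; the top bin is closed). Crude ORs are
2×2 cross-products against a switchable reference bin with Woolf intervals;
adjusted ORs come from a single logistic fit with bin indicators, and
re-referencing is contrast arithmetic on that fit — no refit, which makes
the re-referencing identity OR(A vs B)·OR(B vs C) = OR(A vs C) exact. A
non-empty bin with fewer than 5 subjects in either arm is merged into its
lower neighbour (the lowest bin merges upward) with a warning; this
reproduces the bracketed sparse top categories seen in published binned
tables.

## Parametric excess-odds-ratio models

Five parametric shapes for the odds ratio OR(d), with β the excess odds
ratio (EOR) per 100 Bq/m³ and δ a threshold parameter in Bq/m³:

| kind       | OR(d)                         | interpretation              |
|------------|-------------------------------|-----------------------------|
| `logit`    | exp(β·d/100)                  | log-linear in exposure      |
| `lnt`      | 1 + β·d/100                   | linear no-threshold         |
| `lnt_plus` | 1 + β·(d−δ)/100               | shifted linear              |
| `lt`       | 1 + β·max(0, d−δ)/100         | flat below a threshold      |
| `lmp`      | 1 + β·|d−δ|/100               | mirror point (J/V shape)    |

The subject odds are exp(α + x'γ)·(1 + β·g(d; δ)); (γ, β) are maximised by
Fisher scoring with a positivity barrier keeping 1 + β·g > 1e-6 (steps are
halved at the boundary). δ is profiled on a grid (default 0–200 Bq/m³ in
1-unit steps, clipped to the 99th exposure percentile) rather than jointly
optimised: the likelihood has kinks in δ, and grid profiling is robust and
reproducible; fits are warm-started along the grid. The β interval is
profile likelihood at the χ²₁ 95% cutoff (3.841); the δ interval is the set
of grid points within 1.92 log-likelihood units of the maximum.

Two structural caveats, verified by tests: LNT is LT with δ = 0, so the LT
profile maximum can never fall below the LNT likelihood; and `lnt_plus` is
not identifiable jointly with free stratum intercepts (1 + β(d−δ)/100
rescales into an LNT model with a different baseline), so its δ profile is
flat and ties resolve to the smallest grid value. The model is kept for
completeness of the family; its implied lowest-risk exposure should not be
over-read.

## Spline ensemble, lowest-risk exposure, Rubin pooling

Because knot choices and basis assumptions materially change a single
spline fit, the headline procedure averages over an ensemble. The default
grid is {restricted cubic, cubic B-spline} × {3, 4, 5 internal knots} ×
{quantile placement, equal spacing} = 12 members; knots live inside the
[Q1%, Q99%] exposure window. Restricted cubic bases use the
truncated-power natural-spline construction (linear tails); B-spline bases
drop their first column (the basis partitions unity, which would alias the
stratum intercepts) and put boundary knots at the data range. A quadratic
B-spline variant (`natural_quadratic`) is available but not in the default
grid.

Each member is weighted by its AIC improvement over the base model without
exposure, ΔAIC = AIC_base − AIC_spline, mapped through Akaike weights
w\_i ∝ exp(ΔAIC\_i/2) (computed with max-subtraction; a linear-in-ΔAIC
weighting was rejected as sign-ambiguous for worse-than-base members).
Members with ΔAIC < −2 — clearly worse than the base model — are dropped
before normalisation, unless fewer than two members would survive (common
under a flat truth), in which case all are retained with a warning.

Member curves are predicted case probabilities on a 1 Bq/m³ grid over
[Q1%, Q99%], evaluated at a fixed reference covariate profile (largest
site, male, age 60, former smoker at the former-smoker covariate means).
Odds ratios are invariant to this profile; absolute probabilities are not.

**Lowest-risk exposure (LRE).** Each member's LRE is the interior local
minimum of its curve, detected with a peak-prominence criterion
(`scipy.signal.find_peaks`, prominence ≥ 10% of the curve's dynamic range;
several qualifying minima resolve to the lowest). The prominence floor is
what separates a genuine J-shape — whose minimum carries most of the
curve's range — from the sub-percent noise wiggles that spline fits show
under a truly monotone dose–response; without it, pure-linear truths would
routinely yield spurious J-shapes. The ensemble LRE is the weight-
renormalised average over members with a qualifying minimum; its 95%
interval is the weighted between-model normal interval with the small-
sample (1 − Σw²) variance denominator. Monotone members are excluded from
LRE averaging but retained for OR pooling; if *every* member is monotone
the result carries an absent LRE, a prominent flag, and ORs referenced to
the minimum of the averaged curve.

**Pooled odds ratios.** ORs at requested exposures (default 25, 100, 158,
200 Bq/m³) are referenced to the pooled LRE and combined across members by
Rubin's rules under the ensemble weights: pooled log-OR θ̄ = Σwθ, within-
variance Ū = ΣwU, between-variance B = Σw(θ−θ̄)²/(1−Σw²), total
T = Ū + (1 + 1/m_eff)·B with m_eff = 1/Σw², interval exp(θ̄ ± 1.96√T).
Both variance components are included; the reference exposure may sit
below the curve window (the restricted cubic basis extrapolates linearly,
B-spline boundary knots sit at the data range), which is why an OR can be
reported at 25 Bq/m³ while the LRE search window starts near 30.

**Stratified analyses** rerun the ensemble within subgroups — histology
(each subtype's cases against *all* controls), smoking status, sex, age
groups (≤60, 60–68, 69–74, 75+), pack-year tertiles among current smokers,
study site — with a *common* reference exposure (default 58 Bq/m³) so
strata are comparable; per-stratum LREs are still reported. The stratifying
covariate and any covariate constant within a stratum are dropped from the
adjustment set; sites lacking either arm within a stratum are excluded from
it and logged.

## Synthetic cohort generator

The generator is the study-conditions stand-in, not a tuning dial. Defaults:

- **Exposure**: log-normal, log-mean ln(71.1), log-sd 0.50, truncated to
  [4, 835] Bq/m³ → median ≈ 71 Bq/m³ and ≈ 2% of subjects above 200 Bq/m³,
  the documented summaries. Only summaries, not a distribution, are
  published; the log-normal is the standard model for indoor radon.
- **Sites**: five, with the published size shares; per-site intercepts are
  tuned by bisection so each site's expected case fraction matches the
  published row percentages (overall case fraction 0.616 follows). Tuning
  the intercepts emulates case-control sampling while preserving
  within-site odds ratios — all that downstream stages consume.
- **Covariates**: sex (62% male), age ~ Normal(66, 10) truncated to
  [30, 94]; smoking status 19/45/36% never/former/current; age at
  initiation ~ Normal(17, 3) on [10, 40]; years since quitting ~
  Exponential(mean 12) capped at smoking duration; pack-years ~ Gamma
  (shape 2.2; means 22 former / 32 current). The published table gives
  marginals only; these sub-field laws are field-plausible choices, all
  config-overridable.
- **Covariate effects** (log-OR): current smoker 2.0, former 1.0, male
  0.25, age 0.02/yr, earlier initiation −0.03/yr, cessation −0.04/yr,
  pack-years 0.01/unit — order-of-magnitude plausible, overridable; the
  true effect sizes are not published.
- **True dose–response**: configurable (flat, log-linear, LNT, shifted,
  threshold, mirror point, or a tabulated J-shape); the default J-shape
  regime used in examples is the mirror point at 58 Bq/m³ with β = 0.9 per
  100 Bq/m³, chosen to match the reported OR ≈ 1.3 at 25 Bq/m³ relative to
  the reported lowest-risk exposure. An optional effect modifier assigns a
  different dose–response to one level of a covariate (used for subgroup
  power checks).

What the generator does **not** emulate: geography (no addresses, grids, or
survey linkage), the five real recruitment schemes, exposure measurement
error, or histology-specific dose–response (histology is assigned to cases
independently of exposure). Passing recovery tests therefore demonstrates
that the estimators recover the truths *of this generating model* at the
stated sample sizes — not that the epidemiological findings themselves are
reproduced.

## Problem sizes used in the test suite

Parameter-recovery suites run at the sizes the analyses target: LNT
recovery at n = 4,000 × 200 replicates (bias < 10%, profile-CI coverage in
[0.90, 0.98]); LRE recovery at the study size n = 14,489 × 50 seeds with a
six-member restricted-cubic ensemble (mean within 58 ± 8 Bq/m³, interval
coverage ≥ 85%); null calibration at 50 seeds (pooled OR intervals contain
1 at ≥ 90%) plus 25 pure-LNT seeds for the no-spurious-J-shape majority
check. Unit-level simulation checks (model-selection ranking, subgroup
ranking) run at 10–20 seeds with coarser δ grids; they are ranking checks,
not calibration claims.

## Known limitations

- No conditional (matched-set) likelihood and no robust/sandwich variance.
- The δ grid bounds the threshold search to 0–200 Bq/m³ by default;
  thresholds near the sparse top of the exposure range are not sought.
- The LRE interval is a between-model normal interval; it ignores
  within-member uncertainty about each member's minimum location.
- `lnt_plus` is reported but weakly identified (see above).
- Akaike weights treat members as exchangeable candidates; no correction
  is made for the members being fits to the same data.
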