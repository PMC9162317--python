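# Methods

## Analysis model

Every association is a per-phecode logistic regression within one population
stratum.  The measured-height PheWAS uses the within-stratum height Z-score
as the exposure; the MR-PheWAS replaces it with genetically-predicted height
from a one-sample two-stage least squares design: stage 1 is OLS of measured
height (cm) on the genetic risk score, adjusting for 10 principal components,
and the fitted values — centred and divided by the SD of measured height —
enter the second-stage logistic model, so both scans report odds ratios per
1 SD of measured height and are directly comparable.  Second-stage standard
errors are the naive logistic Wald SEs with no first-stage correction; this
matches the common practice of feeding predicted exposure into a standard
PheWAS engine and is anti-conservative when the instrument is weak, so a
first-stage F below 10 attaches a weak-instrument flag to all downstream
results.  The first stage adjusts for PCs only by default (age and sex can be
added through `stage1_covariates`); the second stage adjusts for age, sex,
and PC1–10, with an optional BMI sensitivity model.

Assumptions are the usual instrumental-variable triple: the score is
associated with height (checked by F and R²), independent of confounders of
the height–disease relationship, and affects disease only through height (no
horizontal pleiotropy — *not* interrogated here; single aggregate-score
estimators such as MR-Egger or weighted median are out of scope).

Cross-stratum synthesis: inverse-variance weighted fixed-effects
meta-analysis (w = 1/se²) with Cochran's Q on k−1 df; the two-stratum
heterogeneity test z = (β₁−β₂)/√(se₁²+se₂²) is identical to the k=2 Q.
Phenome-wide significance is 0.05 divided by the number of phecodes actually
tested in the analysis subset; meta-analysis results use the larger stratum's
threshold.  Effect sizes are compared across strata on the Z′ scale,
Z′ = β/(se·√n), with an intercept-included OLS slope (a slope of 1 means
equivalent effects); direction concordance uses a 1-df chi-square goodness of
fit of the concordant count against 50% (exact binomial available), with
zero estimates excluded from the denominator.

## Data cleaning

Heights (inches): provisional person mean over all measurements, one pass
dropping measurements deviating strictly more than 3 inches, one
recomputation, exclusion of persons with final mean ≤ 50 or ≥ 100 inches,
then a single conversion to cm.  The outlier pass deliberately does not
iterate to a fixed point: iteration can cascade exclusions and is harder to
reason about.  Weights (pounds): restricted to ±1.5 years around enrollment;
the 60-lb rule is applied as deviation from the person's in-window mean
weight (an absolute 60-lb floor would exclude almost nobody plausible); BMI
is mean weight (kg) over squared height (m), i.e. weight is averaged first
and divided once.  QC runs in native units and converts once to avoid
compounding rounding.

Phecodes: exact-string (vocabulary, code) mapping, no hierarchy expansion.
≥ 2 mapped events (distinct (person, date, code); dates need not be
distinct days per code) → case, 0 → control, exactly 1 → missing — the
standard phecode convention for the ambiguous one-code person.  Analyses
keep phecodes with ≥ 200 cases **and** ≥ 200 controls, re-applied within
every analysis subset so each subset's Bonferroni denominator reflects what
was actually tested there.  Related-phecode exclusion ranges are not applied
by default; `assign_phecodes(exclusion_map=...)` is the hook.

## Genetic risk score

Score = Σ β̂ⱼ dⱼ with dⱼ the effect-allele dosage ∈ [0,2].  Variants are
matched by id and verified against the allele pair; opposite orientation
flips the dosage (2−d); a pair matching in neither orientation is dropped
and logged, and more than half the table unmatched is a hard error.  Missing
dosages are mean-imputed (2 × cohort effect-allele frequency), preserving
the score mean.  Palindromic A/T and C/G variants are retained by default
under the assumption that the genotype file is strand-consistent with the
weights (`drop_palindromic=True` to drop them); both policies are recorded
in the match log because published analyses rarely state them.

## Numerical choices

Logistic fits use IRLS with convergence at max|Δβ| < 1e-8 or 25 iterations;
Wald SEs come from the inverse observed information and two-sided p-values
from the normal approximation.  Quasi-complete separation is declared when
any fitted probability leaves [1e-10, 1−1e-10] while a coefficient exceeds
10 in absolute value; such fits are flagged non-converged, excluded from
reports, and never abort the sweep.  No Firth correction is applied — the
200/200 filter makes separation rare.  Missing covariates are handled by
listwise deletion, with case/control counts reported post-deletion;
zero-variance covariates (e.g. sex in a sex-stratified run) are dropped with
a warning.  p-values are floored at 1e-320.  Standard errors reconstructed
from printed p-values use an inverse normal evaluated in log space
(`ndtri_exp`), so the identity se → p → se holds to 1e-12 relative down to
p ≈ 1e-310.

## Synthetic cohort generator

The generator draws dosages Binomial(2, fⱼ) with fⱼ ~ U(0.05, 0.5), scales
Gaussian raw weights so the true score's theoretical variance
Σβⱼ²·2fⱼ(1−fⱼ) makes the reference population hit `target_r2` (default
0.18) of the within-covariate height variance exactly, and solves the
residual variance in closed form per population so that total
within-covariate variance is constant; a population with attenuation a then
realises R² = target_r2·a²/a_ref² (a = 0.52 reproduces a 4.8%-vs-18%
two-population contrast).  A target exceeding 1 − c²/σ² (confounder loading
c over residual SD σ) is rejected with the maximum attainable R² named.

Fixed cohort structure, chosen once to mirror an older, male-skewed veteran
biobank: age U(40, 80) years; sex Bernoulli(0.9 male); height = 163.8 cm
+ 13.5·male − 0.05·(age−62) + genetic + confounder + noise, giving a mean
near 176 cm and total SD near 8 cm; PCs are independent standard normals;
BMI ~ N(30.1, 5) clipped to [18, 55], independent of height.  The residual
SD is 7.0 cm and the confounder U ~ N(0,1) loads on height with 2.0 cm per
SD — large enough that confounded phecodes are decisively detected by the
measured-height scan at n = 50,000 while remaining a modest share of height
variance.  Baseline phecode prevalences are U(0.05, 0.25) (a free choice;
real phenome prevalence distributions are far more skewed), and disease
log-odds include small age (0.01/yr) and sex (0.2) terms.

Binary traits are drawn **directly from the logistic model**
logit p = α_k + γ_k z(H) + δ_k z(U) + covariate terms (not a probit
liability), so the second-stage logistic regression recovers γ_k without
link mismatch and parameter recovery is an exact acceptance surface.  γ_k
equals `gamma_scale` (default 0.3 log-odds per SD) for causal phecodes and 0
otherwise; δ_k equals `confounder_scale` for confounded phecodes.  Because U
is independent of genotype by construction, measured-height estimates on
confounded phecodes are biased away from zero while MR estimates are centred
on zero — the class-separation property the acceptance suite verifies.
Cases emit 2 + Poisson(2) qualifying ICD codes on distinct dates before
enrollment; 5% of non-cases emit exactly one (exercising the one-code rule);
raw vitals are emitted as duplicate exact records plus occasional gross
outliers (+8 in, +100 lb, out-of-window weights) engineered so the QC rules
remove them and recover the true values exactly.

What the generator does **not** emulate: LD between variants, imputation
uncertainty, relatedness, ancestry inference, skewed prevalence and
utilisation-driven code intensity, height–BMI correlation, or pleiotropic
instruments.  Passing tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to those real-data
features.

## Study sizes used in checks

Truth recovery runs 10 replicates of n = 50,000 persons × 200 variants × 60
phecodes (20 causal / 20 confounded / 20 null); type-I calibration runs 4
replicates of n = 10,000 × 500 null phecodes; the instrument emulation uses
one two-population cohort of n = 50,000; the Wald-ratio identity uses
n = 1,000.  `scripts/acceptance.py` uses the same conditions with 3 recovery
and 2 null replicates.  At these sizes the Monte-Carlo standard error of the
mean causal estimate is ≈ 0.001 on a true γ of 0.3, and the binomial 95%
band for a 0.05 rejection rate over 200 tests is ≈ ±0.03.

## Known limitations

Naive second-stage SEs (above); no pleiotropy-robust estimators; exact-string
ICD mapping without hierarchy roll-up; phecode exclusion ranges off by
default; no random-effects meta-analysis (fixed effects only); the
first-stage covariate set is PCs-only by default.  The attenuation scalar is
a deliberate simplification of cross-population transferability — it
reproduces the qualitative strong/weak-instrument contrast with one
parameter but carries no information about LD or allele-frequency
differences.
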