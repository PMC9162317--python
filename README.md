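# heightmr

Tools for asking, phenome-wide, whether adult height *causes* disease or is
merely correlated with it.  `heightmr` implements a complete PheWAS /
MR-PheWAS pipeline over EHR-style data: cleaning of longitudinal height and
weight vitals, phecode case/control assignment from ICD-9/10 events,
construction of a weighted height genetic risk score (GRS), logistic
phenome-wide scans of measured and genetically-predicted height, Bonferroni
phenome-wide significance, cross-population comparison, effect-modification
by comorbidity strata, and inverse-variance fixed-effects meta-analysis.
Because individual-level biobank data are access-restricted, the package
ships a seeded synthetic-cohort generator that emulates the statistical
structure of such a study — two populations with instrument R² near 18% and
4.8%, and a phenome of causal, confounded, and null binary traits with a
truth table — so every stage is testable offline.

## The model

For phecode *k* in one population stratum, the **PheWAS** fits

&nbsp;&nbsp;logit P(Y<sub>ik</sub> = 1) = α<sub>k</sub> + β<sub>k</sub> z(H<sub>i</sub>) + covariates (age, sex, PC1–10),

with z(H) the within-stratum height Z-score, so exp(β<sub>k</sub>) is the OR
per SD of height.  The **MR-PheWAS** replaces z(H) with genetically-predicted
height from a two-stage least squares (2SLS) design: stage 1 regresses
measured height on the GRS (Σ<sub>j</sub> β̂<sub>j</sub> d<sub>ij</sub>,
per-allele weights in cm) plus PCs, and the fitted value, standardised by the
SD of measured height, enters the second-stage logistic model.  Because the
genotype is insensitive to the environmental confounders of measured height,
a significant MR association supports an effect of height itself.  Strata are
compared by the two-sample heterogeneity test z = (β₁−β₂)/√(se₁²+se₂²), and
populations are combined by IVW fixed effects (w = 1/se², Cochran Q for
heterogeneity).

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from heightmr import assoc, grs
from heightmr.simulate import SimConfig, PopulationSpec, generate_cohort

cfg = SimConfig(n_individuals=20_000, n_variants=200, n_phecodes=12,
                populations=(PopulationSpec("EA", 1.0, 1.0),), seed=42)
cohort = generate_cohort(cfg, emit_icd=False, emit_measurements=False)

scores, log = grs.compute_grs(cohort.dosages, cohort.variant_alleles, cohort.weights)
diag = grs.variance_explained(scores, cohort.height_cm, cohort.covariates[["age", "sex"]])
print(f"instrument R^2 = {diag.r2:.3f}, first-stage F = {diag.f_stat:.0f}")

covars = cohort.covariates[["age", "sex"] + [f"pc{i}" for i in range(1, 11)]]
pcs = cohort.covariates[[f"pc{i}" for i in range(1, 11)]]
stage1 = assoc.stage1_predict(cohort.height_cm, scores, pcs)
mr = assoc.mr_phewas(stage1, cohort.status, covars)
mr = mr.merge(cohort.truth[["phecode", "class"]], on="phecode")
print(f"phenome-wide significance threshold = {assoc.bonferroni_threshold(len(mr)):.1e}")
for _, r in mr.sort_values("p").head(4).iterrows():
    print(f"phecode {r.phecode} ({r['class']:>10}): OR {r.or_:.2f}, p {r.p:.1e}")
```

prints

```
instrument R^2 = 0.177, first-stage F = 4298
phenome-wide significance threshold = 4.2e-03
phecode 103 (    causal): OR 1.50, p 4.2e-20
phecode 102 (    causal): OR 1.36, p 6.8e-12
phecode 104 (    causal): OR 1.40, p 1.3e-10
phecode 101 (    causal): OR 1.33, p 9.2e-06
```

The GRS explains ≈ 18% of within-covariate height variance as configured, and
the four phecodes the MR scan ranks on top are exactly the generator's
causal ones (OR per SD of height near the true e<sup>0.3</sup> ≈ 1.35);
confounded phecodes — associated with measured height through a shared
non-genetic factor — do not reach significance under the genetic exposure.

Meta-analysis works directly from summary statistics: with per-population
odds ratios and p-values, `meta.se_from_p` reconstructs the standard errors
and `meta.ivw_meta` the combined OR:

```python
import math
from heightmr.meta import se_from_p, ivw_meta
betas = [math.log(1.47), math.log(1.66)]          # OR per SD, two populations
ses = [se_from_p(betas[0], 2.0e-41), se_from_p(betas[1], 1.3e-4)]
print(round(ivw_meta(betas, ses).or_, 2))          # -> 1.48
```

A `heightmr` command-line interface mirrors the library (`simulate`, `qc`,
`grs`, `phewas`, `mr-phewas`, `meta`, `stratify`, `report`); `report` runs the
whole pipeline from a YAML config and writes per-stage TSVs plus a JSON
manifest of thresholds and filter counts.

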