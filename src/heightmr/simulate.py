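"""Seeded synthetic EHR cohorts with the statistical structure the analysis assumes.

The generator emulates a biobank of mostly older male veterans with two
populations whose height genetic instrument differs in strength, and a phenome
of binary phecodes drawn from a logistic model with known causal, confounded,
and null height effects — so every downstream stage (QC, scoring, PheWAS,
MR-PheWAS, meta-analysis, stratification) is exercisable offline against a
truth table.

Model
-----
Dosages ``g_ij ~ Binomial(2, f_j)`` with allele frequencies drawn uniformly;
the true score is ``S_i = sum_j beta_j g_ij`` with weights scaled so that, in
the reference population, S explains exactly ``target_r2`` of the
within-covariate height variance.  Height is

    H_i = mu + b_sex sex_i + b_age (age_i - 62) + a_pop (S_i - E[S]) + c U_i + eps_i

with confounder ``U ~ N(0,1)`` independent of genotype, and the residual
variance of eps solved in closed form so that the total within-covariate
variance is the same in every population; a population's attenuation factor
``a`` then yields a realized instrument R^2 of ``target_r2 * a^2 / a_ref^2``
(e.g. a = 0.52 emulates the 4.8%-vs-18% contrast between populations).

Binary phecode k is drawn directly from a logistic (not probit-liability)
model, ``logit p_ik = alpha_k + gamma_k z(H_i) + delta_k z(U_i) + covariate
terms``, with z-scores taken within population, so downstream logistic
regression recovers gamma_k without link mismatch.  Cases emit
``2 + Poisson(2)`` qualifying ICD codes; a configurable fraction of non-cases
emit exactly one (exercising the one-code rule); controls emit none.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .phenoqc import IN_TO_CM, LB_TO_KG

HEIGHT_BASE_CM = 163.8        # female baseline
SEX_EFFECT_CM = 13.5          # male - female
AGE_EFFECT_CM = -0.05         # per year, centered at 62
AGE_CENTER = 62.0
RESID_SD_CM = 7.0             # within-covariate height SD
DISEASE_AGE_EFFECT = 0.01     # log-odds per year, centered at 60
DISEASE_SEX_EFFECT = 0.2
BMI_MEAN, BMI_SD = 30.1, 5.0
N_PCS = 10


@dataclass(frozen=True)
class PopulationSpec:
    """One population stratum: label, sample fraction, instrument attenuation.

    Attenuation ``a`` multiplies the true per-allele effects — a one-parameter
    stand-in for LD/allele-frequency transferability loss.
    """

    label: str
    fraction: float
    attenuation: float = 1.0


@dataclass
class SimConfig:
    n_individuals: int = 10_000
    n_variants: int = 300
    allele_freq_range: tuple = (0.05, 0.5)
    target_r2: float = 0.18
    n_phecodes: int = 60
    effect_classes: dict = field(
        default_factory=lambda: {"causal": 1 / 3, "confounded": 1 / 3, "null": 1 / 3}
    )
    gamma_scale: float = 0.3
    confounder_scale: float = 0.3
    confounder_height_cm: float = 2.0
    baseline_prevalence_range: tuple = (0.05, 0.25)
    populations: tuple = (PopulationSpec("EA", 0.79, 1.0),
                          PopulationSpec("AA", 0.21, 0.52))
    one_code_fraction: float = 0.05
    outlier_fraction: float = 0.03
    male_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.target_r2 < 1.0:
            raise ValueError("target_r2 must lie in (0, 1)")
        if abs(sum(self.effect_classes.values()) - 1.0) > 1e-9:
            raise ValueError("effect-class proportions must sum to 1")
        if abs(sum(p.fraction for p in self.populations) - 1.0) > 1e-9:
            raise ValueError("population fractions must sum to 1")
        for p in self.populations:
            if not 0.0 < p.attenuation <= 1.0:
                raise ValueError("attenuation factors must lie in (0, 1]")
        lo, hi = self.allele_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("allele_freq_range must lie in (0, 1)")
        lo, hi = self.baseline_prevalence_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("baseline_prevalence_range must lie in (0, 1)")


@dataclass
class SyntheticCohort:
    """Generated cohort bundle: everything the pipeline consumes, plus truth."""

    covariates: pd.DataFrame          # person_id-indexed: age, sex, pc1..pc10, population, enrollment_date
    height_cm: pd.Series              # true cleaned height
    bmi: pd.Series
    dosages: pd.DataFrame             # person x variant, as stored (counted-allele orientation)
    variant_alleles: pd.DataFrame     # variant_id, counted_allele, other_allele
    weights: pd.DataFrame             # instrument weights table
    status: pd.DataFrame              # person x phecode truth status (1/0)
    truth: pd.DataFrame               # phecode, class, gamma, delta, prevalence
    phecode_map: pd.DataFrame
    icd_events: pd.DataFrame | None
    height_measurements: pd.DataFrame | None
    weight_measurements: pd.DataFrame | None
    config: SimConfig


def _largest_remainder_counts(total: int, fractions) -> np.ndarray:
    raw = np.asarray(fractions, dtype=float) * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def max_attainable_r2(config: SimConfig) -> float:
    """Largest reference-population R^2 the residual-variance budget permits."""
    return 1.0 - config.confounder_height_cm**2 / RESID_SD_CM**2


def generate_cohort(config: SimConfig, *, emit_icd: bool = True,
                    emit_measurements: bool = True) -> SyntheticCohort:
    """Draw a full synthetic cohort; reproducible from ``config.seed``.

    The ``emit_*`` flags skip the (expensive) raw-record layers without
    changing the core cohort — separate child RNG streams are used per layer.
    """
    resid_var = RESID_SD_CM**2
    c = config.confounder_height_cm
    a_ref = max(p.attenuation for p in config.populations)
    var_s_target = config.target_r2 * resid_var / a_ref**2
    # closed-form residual budget; tightest in the reference population
    if resid_var - a_ref**2 * var_s_target - c**2 < 0:
        raise ValueError(
            f"target_r2={config.target_r2} unreachable: with a confounder "
            f"loading of {c} cm the maximum attainable R^2 is "
            f"{max_attainable_r2(config):.4f}"
        )

    seq = np.random.SeedSequence(config.seed)
    rng, rng_meas, rng_icd = (np.random.default_rng(s) for s in seq.spawn(3))
    n = config.n_individuals
    m = config.n_variants

    # --- instrument ---------------------------------------------------------
    freqs = rng.uniform(*config.allele_freq_range, size=m)
    beta_raw = rng.normal(size=m)
    var_raw = float(np.sum(beta_raw**2 * 2.0 * freqs * (1.0 - freqs)))
    betas = beta_raw * math.sqrt(var_s_target / var_raw)
    variant_ids = [f"rs{100000 + j}" for j in range(m)]
    bases = np.array(list("ACGT"))
    ea_idx = rng.integers(0, 4, size=m)
    oa_idx = (ea_idx + rng.integers(1, 4, size=m)) % 4
    weights = pd.DataFrame({
        "rsid": variant_ids,
        "chr": [str(j % 22 + 1) for j in range(m)],
        "pos": [10_000 + 1_000 * j for j in range(m)],
        "effect_allele": bases[ea_idx],
        "other_allele": bases[oa_idx],
        "beta": betas,
    })

    # --- persons ------------------------------------------------------------
    person_ids = pd.Index([f"P{i:06d}" for i in range(n)], name="person_id")
    age = rng.uniform(40.0, 80.0, size=n)
    sex = (rng.random(n) < config.male_fraction).astype(int)  # 1 = male
    pcs = rng.normal(size=(n, N_PCS))
    enroll_offset = rng.integers(0, 2556, size=n)  # days from 2011-01-01
    enrollment = pd.Timestamp("2011-01-01") + pd.to_timedelta(enroll_offset, unit="D")

    pop_counts = _largest_remainder_counts(n, [p.fraction for p in config.populations])
    pop_label = np.repeat([p.label for p in config.populations], pop_counts)
    attenuation = np.repeat([p.attenuation for p in config.populations], pop_counts)

    dosages_effect = rng.binomial(2, freqs, size=(n, m)).astype(float)
    score = dosages_effect @ betas
    mean_s = float(2.0 * np.sum(freqs * betas))
    u = rng.normal(size=n)

    eps_sd = np.sqrt(resid_var - attenuation**2 * var_s_target - c**2)
    eps = rng.normal(size=n) * eps_sd
    height = (HEIGHT_BASE_CM + SEX_EFFECT_CM * sex
              + AGE_EFFECT_CM * (age - AGE_CENTER)
              + attenuation * (score - mean_s) + c * u + eps)

    # within-population z-scores of height and confounder
    z_h = np.empty(n)
    z_u = np.empty(n)
    for p in config.populations:
        mask = pop_label == p.label
        if mask.sum() == 0:
            continue
        for src, dst in ((height, z_h), (u, z_u)):
            sd = src[mask].std() or 1.0
            dst[mask] = (src[mask] - src[mask].mean()) / sd

    # --- phenome ------------------------------------------------------------
    class_names = list(config.effect_classes)
    class_counts = _largest_remainder_counts(
        config.n_phecodes, [config.effect_classes[k] for k in class_names]
    )
    classes = np.repeat(class_names, class_counts)
    gamma = np.where(classes == "causal", config.gamma_scale, 0.0)
    delta = np.where(classes == "confounded", config.confounder_scale, 0.0)
    prev = rng.uniform(*config.baseline_prevalence_range, size=config.n_phecodes)
    alpha = np.log(prev / (1.0 - prev))
    phecodes = [f"{101 + k}" for k in range(config.n_phecodes)]
    truth = pd.DataFrame({"phecode": phecodes, "class": classes,
                          "gamma": gamma, "delta": delta, "prevalence": prev})

    lin = (alpha[None, :] + np.outer(z_h, gamma) + np.outer(z_u, delta)
           + (DISEASE_AGE_EFFECT * (age - 60.0) + DISEASE_SEX_EFFECT * sex)[:, None])
    p_case = 1.0 / (1.0 + np.exp(-lin))
    status_arr = (rng.random((n, config.n_phecodes)) < p_case).astype(float)
    status = pd.DataFrame(status_arr, index=person_ids, columns=phecodes)

    bmi = np.clip(rng.normal(BMI_MEAN, BMI_SD, size=n), 18.0, 55.0)

    covariates = pd.DataFrame(
        {"age": age, "sex": sex,
         **{f"pc{i + 1}": pcs[:, i] for i in range(N_PCS)},
         "population": pop_label,
         "enrollment_date": enrollment.strftime("%Y-%m-%d")},
        index=person_ids,
    )

    # storage allele orientation: a fraction of variants stored counting the
    # other allele (dosage flipped) to exercise orientation resolution
    flip = rng.random(m) < 0.2
    stored = dosages_effect.copy()
    stored[:, flip] = 2.0 - stored[:, flip]
    counted = np.where(flip, weights["other_allele"], weights["effect_allele"])
    other = np.where(flip, weights["effect_allele"], weights["other_allele"])
    dosages = pd.DataFrame(stored, index=person_ids, columns=variant_ids)
    variant_alleles = pd.DataFrame(
        {"variant_id": variant_ids, "chr": weights["chr"], "pos": weights["pos"],
         "counted_allele": counted, "other_allele": other}
    )

    phecode_map = pd.DataFrame(
        [(voc, f"{pre}-{pc}", pc) for pc in phecodes
         for voc, pre in (("ICD9", "D9"), ("ICD10", "D10"))],
        columns=["vocabulary", "code", "phecode"],
    )

    height_meas = weight_meas = None
    if emit_measurements:
        height_meas, weight_meas = _emit_measurements(
            rng_meas, person_ids, height, bmi, enrollment, config.outlier_fraction
        )
    icd_events = None
    if emit_icd:
        icd_events = _emit_icd(rng_icd, person_ids, status_arr, phecodes,
                               enrollment, config.one_code_fraction)

    return SyntheticCohort(
        covariates=covariates,
        height_cm=pd.Series(height, index=person_ids, name="height_cm"),
        bmi=pd.Series(bmi, index=person_ids, name="bmi"),
        dosages=dosages, variant_alleles=variant_alleles, weights=weights,
        status=status, truth=truth, phecode_map=phecode_map,
        icd_events=icd_events, height_measurements=height_meas,
        weight_measurements=weight_meas, config=config,
    )


def _emit_measurements(rng, person_ids, height_cm, bmi, enrollment, outlier_fraction):
    """Raw vitals whose QC reduction recovers the true height/BMI exactly.

    Each person gets two identical height records (inches) and two identical
    in-window weight records (pounds); a fraction get an additional gross
    outlier (height +8 in, weight +100 lb) that the deviation rules remove,
    and a fraction get an out-of-window weight record.
    """
    n = len(person_ids)
    h_in = height_cm / IN_TO_CM
    w_lb = bmi * (height_cm / 100.0) ** 2 / LB_TO_KG
    h_rows, w_rows = [], []
    h_outlier = rng.random(n) < outlier_fraction
    w_outlier = rng.random(n) < outlier_fraction
    w_outside = rng.random(n) < outlier_fraction
    for i, pid in enumerate(person_ids):
        e = enrollment[i]
        d1, d2 = (e - pd.Timedelta(days=30)), (e + pd.Timedelta(days=90))
        h_rows += [(pid, d1.date().isoformat(), h_in[i]),
                   (pid, d2.date().isoformat(), h_in[i])]
        if h_outlier[i]:
            h_rows.append((pid, d2.date().isoformat(), h_in[i] + 8.0))
        w_rows += [(pid, d1.date().isoformat(), w_lb[i]),
                   (pid, d2.date().isoformat(), w_lb[i])]
        if w_outlier[i]:
            w_rows.append((pid, d2.date().isoformat(), w_lb[i] + 100.0))
        if w_outside[i]:
            far = e + pd.Timedelta(days=800)
            w_rows.append((pid, far.date().isoformat(), w_lb[i] + 20.0))
    cols = ["person_id", "date", "value"]
    return pd.DataFrame(h_rows, columns=cols), pd.DataFrame(w_rows, columns=cols)


def _emit_icd(rng, person_ids, status_arr, phecodes, enrollment, one_code_fraction):
    """Long-format ICD events realising the phecode truth under the 2-code rule."""
    rows = []
    n = len(person_ids)
    for k, pc in enumerate(phecodes):
        cases = np.flatnonzero(status_arr[:, k] == 1.0)
        n_codes = 2 + rng.poisson(2.0, size=cases.size)
        non_cases = np.flatnonzero(status_arr[:, k] == 0.0)
        single = non_cases[rng.random(non_cases.size) < one_code_fraction]
        for idx_arr, counts in ((cases, n_codes), (single, np.ones(single.size, int))):
            for i, cnt in zip(idx_arr, counts):
                base = enrollment[i]
                # distinct dates so the two-code rule cannot be defeated by
                # the (person, date, code) de-duplication
                offs = rng.choice(1825, size=cnt, replace=False) + 1
                vocs = rng.random(cnt) < 0.5
                for o, v9 in zip(offs, vocs):
                    voc = "ICD9" if v9 else "ICD10"
                    pre = "D9" if v9 else "D10"
                    date = (base - pd.Timedelta(days=int(o))).date().isoformat()
                    rows.append((person_ids[i], date, voc, f"{pre}-{pc}"))
    return pd.DataFrame(rows, columns=["person_id", "date", "vocabulary", "code"])


FIXTURE_FILES = {
    "weights": "weights.tsv",
    "dosages": "dosages.tsv",
    "variants": "variants.tsv",
    "covariates": "covariates.csv",
    "height_measurements": "height_measurements.csv",
    "weight_measurements": "weight_measurements.csv",
    "icd_events": "icd_events.csv",
    "phecode_map": "phecode_map.csv",
    "truth": "truth.csv",
    "metadata": "metadata.json",
}


def write_fixture(cohort: SyntheticCohort, outdir, *, vcf: bool = False) -> dict:
    """Write the cohort in the exact external formats the pipeline consumes.

    Returns the path map.  Re-writing the same cohort yields byte-identical
    files.  With ``vcf=True`` dosages are additionally written as a DS-format
    VCF.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in FIXTURE_FILES.items()}

    cohort.weights.to_csv(paths["weights"], sep="\t", index=False)
    cohort.dosages.to_csv(paths["dosages"], sep="\t")
    cohort.variant_alleles.to_csv(paths["variants"], sep="\t", index=False)
    cohort.covariates.to_csv(paths["covariates"])
    cohort.phecode_map.to_csv(paths["phecode_map"], index=False)
    cohort.truth.to_csv(paths["truth"], index=False)
    empty = pd.DataFrame(columns=["person_id", "date", "value"])
    (cohort.height_measurements if cohort.height_measurements is not None
     else empty).to_csv(paths["height_measurements"], index=False)
    (cohort.weight_measurements if cohort.weight_measurements is not None
     else empty).to_csv(paths["weight_measurements"], index=False)
    empty_icd = pd.DataFrame(columns=["person_id", "date", "vocabulary", "code"])
    (cohort.icd_events if cohort.icd_events is not None
     else empty_icd).to_csv(paths["icd_events"], index=False)

    cfg = asdict(cohort.config)
    cfg["populations"] = [asdict(p) for p in cohort.config.populations]
    meta = {
        "seed": cohort.config.seed,
        "config": cfg,
        "n_individuals": int(len(cohort.covariates)),
        "n_variants": int(cohort.dosages.shape[1]),
        "n_phecodes": int(cohort.status.shape[1]),
    }
    paths["metadata"].write_text(json.dumps(meta, sort_keys=True, indent=2,
                                            default=str) + "\n")
    if vcf:
        from .grs import write_dosages_vcf
        paths["dosages_vcf"] = out / "dosages.vcf"
        write_dosages_vcf(cohort.dosages, cohort.variant_alleles, paths["dosages_vcf"])
    return paths
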