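"""Reproducible simulation studies over the synthetic cohort.

These runners wire the generator to the analysis stages at fixed study
conditions and summarise the outcome: instrument-R^2 emulation across two
populations, truth recovery of causal effects, behaviour of measured-height
versus MR estimates under non-genetic confounding, type-I calibration under
the global null, and the exact Wald-ratio identity of 2SLS.  They are used by
the acceptance checks and are convenient for power exploration.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from . import assoc, grs
from .simulate import PopulationSpec, SimConfig, generate_cohort

RECOVERY_GAMMA = 0.3
RECOVERY_DELTA = 0.3


def _analysis_frames(cohort):
    cov = cohort.covariates
    covars = cov[["age", "sex"] + [f"pc{i}" for i in range(1, 11)]]
    pcs = cov[[f"pc{i}" for i in range(1, 11)]]
    return covars, pcs


def instrument_emulation(n: int = 50_000, seed: int = 0, *,
                         n_variants: int = 200, target_r2: float = 0.18,
                         attenuation: float = 0.52) -> dict:
    """Realized instrument R^2 (given age/sex) in a strong- and a weak-
    instrument population sharing one weights table."""
    cfg = SimConfig(
        n_individuals=n, n_variants=n_variants, n_phecodes=2,
        target_r2=target_r2,
        populations=(PopulationSpec("EA", 0.79, 1.0),
                     PopulationSpec("AA", 0.21, attenuation)),
        seed=seed,
    )
    cohort = generate_cohort(cfg, emit_icd=False, emit_measurements=False)
    scores, _ = grs.compute_grs(cohort.dosages, cohort.variant_alleles,
                                cohort.weights)
    out = {}
    for pop in ("EA", "AA"):
        mask = cohort.covariates["population"] == pop
        diag = grs.variance_explained(
            scores[mask], cohort.height_cm[mask],
            cohort.covariates.loc[mask, ["age", "sex"]])
        out[pop] = {"r2": diag.r2, "f": diag.f_stat, "n": diag.n}
    return out


def _one_recovery_seed(seed: int, n: int, n_phecodes: int, n_variants: int):
    cfg = SimConfig(
        n_individuals=n, n_variants=n_variants, n_phecodes=n_phecodes,
        gamma_scale=RECOVERY_GAMMA, confounder_scale=RECOVERY_DELTA,
        populations=(PopulationSpec("EA", 1.0, 1.0),), seed=seed,
    )
    cohort = generate_cohort(cfg, emit_icd=False, emit_measurements=False)
    scores, _ = grs.compute_grs(cohort.dosages, cohort.variant_alleles,
                                cohort.weights)
    covars, pcs = _analysis_frames(cohort)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        measured = assoc.phewas_measured(cohort.height_cm, cohort.status, covars)
        s1 = assoc.stage1_predict(cohort.height_cm, scores, pcs)
        mr = assoc.mr_phewas(s1, cohort.status, covars)
    truth = cohort.truth.set_index("phecode")
    mr = mr.set_index("phecode").join(truth["class"])
    measured = measured.set_index("phecode").join(truth["class"])
    return measured, mr


def parameter_recovery(*, n: int = 50_000, n_phecodes: int = 60,
                       n_variants: int = 200, seeds=range(10)) -> dict:
    """Truth recovery across seeds: causal MR betas, and rejection rates at
    alpha = 0.05 for confounded phecodes under the MR and measured models."""
    causal_betas, mr_conf_p, meas_conf_p = [], [], []
    for seed in seeds:
        measured, mr = _one_recovery_seed(seed, n, n_phecodes, n_variants)
        causal_betas += list(mr.loc[mr["class"] == "causal", "beta"])
        mr_conf_p += list(mr.loc[mr["class"] == "confounded", "p"])
        meas_conf_p += list(measured.loc[measured["class"] == "confounded", "p"])
    mr_conf_p = np.asarray(mr_conf_p)
    meas_conf_p = np.asarray(meas_conf_p)
    return {
        "true_gamma": RECOVERY_GAMMA,
        "causal_beta_mean": float(np.mean(causal_betas)),
        "n_causal": len(causal_betas),
        "mr_confounded_rejection": float(np.mean(mr_conf_p < 0.05)),
        "measured_confounded_rejection": float(np.mean(meas_conf_p < 0.05)),
        "n_confounded": int(mr_conf_p.size),
    }


def type1_calibration(*, n: int = 10_000, n_phecodes: int = 500,
                      n_variants: int = 200, seeds=range(4)) -> dict:
    """MR-PheWAS p-values under the global null (no height or confounder
    effects): pooled Kolmogorov-Smirnov uniformity p and empirical alpha."""
    pvals = []
    for seed in seeds:
        cfg = SimConfig(
            n_individuals=n, n_variants=n_variants, n_phecodes=n_phecodes,
            effect_classes={"null": 1.0}, gamma_scale=0.0, confounder_scale=0.0,
            populations=(PopulationSpec("EA", 1.0, 1.0),), seed=seed,
        )
        cohort = generate_cohort(cfg, emit_icd=False, emit_measurements=False)
        scores, _ = grs.compute_grs(cohort.dosages, cohort.variant_alleles,
                                    cohort.weights)
        covars, pcs = _analysis_frames(cohort)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1 = assoc.stage1_predict(cohort.height_cm, scores, pcs)
            mr = assoc.mr_phewas(s1, cohort.status, covars)
        pvals += list(mr.loc[mr["converged"], "p"])
    pvals = np.asarray(pvals)
    ks = stats.kstest(pvals, "uniform")
    return {
        "n_tests": int(pvals.size),
        "ks_p": float(ks.pvalue),
        "alpha_at_005": float(np.mean(pvals < 0.05)),
    }


def wald_ratio_identity(*, n: int = 1_000, seed: int = 0) -> dict:
    """Relative difference between the 2SLS slope and cov(y,G)/cov(H,G) for a
    continuous outcome with no covariates (an exact OLS identity)."""
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, 0.3, size=n).astype(float)
    height = 1.5 * g + rng.normal(scale=6.0, size=n)
    y = 0.25 * height + rng.normal(size=n)
    slope = assoc.two_stage_least_squares(y, height, g)
    oracle = np.cov(y, g, ddof=0)[0, 1] / np.cov(height, g, ddof=0)[0, 1]
    return {"slope": float(slope), "oracle": float(oracle),
            "rel_err": float(abs(slope - oracle) / abs(oracle)), "n": n}
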