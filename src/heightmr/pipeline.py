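"""End-to-end orchestration: config -> QC -> GRS -> PheWAS/MR-PheWAS -> meta,
plus the presentation surfaces (Manhattan-style plot data, cross-population
scatter/Venn counts).

All outputs are plain TSV/CSV plus one JSON manifest recording thresholds,
filter counts (``n_input = n_retained + n_excluded`` at every filter), and
every exclusion with its reason, so a run is auditable and re-running on
identical inputs is byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, grs, meta, phenoqc

DEFAULT_COVARIATES = ["age", "sex"] + [f"pc{i}" for i in range(1, 11)]
DEFAULT_STAGE1_COVARIATES = [f"pc{i}" for i in range(1, 11)]

# phecode group/system by integer range (approximate standard groups)
PHECODE_GROUPS = [
    (0, 140, "infectious diseases"),
    (140, 240, "neoplasms"),
    (240, 280, "endocrine/metabolic"),
    (280, 290, "hematopoietic"),
    (290, 320, "mental disorders"),
    (320, 360, "neurological"),
    (360, 390, "sense organs"),
    (390, 460, "circulatory system"),
    (460, 520, "respiratory"),
    (520, 580, "digestive"),
    (580, 630, "genitourinary"),
    (630, 680, "pregnancy complications"),
    (680, 710, "dermatologic"),
    (710, 740, "musculoskeletal"),
    (740, 760, "congenital anomalies"),
    (760, 800, "symptoms"),
    (800, 1010, "injuries & poisonings"),
]


class PipelineError(RuntimeError):
    """Hard failure of a pipeline stage; the message names the stage."""


def phecode_group(code) -> str:
    try:
        val = float(code)
    except (TypeError, ValueError):
        return "other"
    for lo, hi, name in PHECODE_GROUPS:
        if lo <= val < hi:
            return name
    return "other"


@dataclass
class RunConfig:
    """Paths and analysis settings for one pipeline run."""

    weights: str
    dosages: str                       # TSV matrix or .vcf (DS field)
    covariates: str
    height_measurements: str
    weight_measurements: str
    icd_events: str
    phecode_map: str
    outdir: str
    variants: str | None = None        # allele-orientation TSV (for TSV dosages)
    populations: list = field(default_factory=list)  # empty = all present
    covariate_names: list = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    stage1_covariate_names: list = field(
        default_factory=lambda: list(DEFAULT_STAGE1_COVARIATES))
    min_cases: int = 200
    min_controls: int = 200
    add_bmi: bool = False
    strata: list = field(default_factory=list)  # [{"name":..., "phecodes":[...]}]
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _read(path, stage: str, reader, **kw):
    p = Path(path)
    if not p.exists():
        raise PipelineError(f"{stage} stage: input file not found: {p}")
    try:
        return reader(p, **kw)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError(f"{stage} stage: failed reading {p}: {exc}") from exc


def load_inputs(config: RunConfig) -> dict:
    """Read every input table, with stage-named errors on failure."""
    cov = _read(config.covariates, "inputs", pd.read_csv, index_col="person_id")
    inputs = {
        "covariates": cov,
        "height_measurements": _read(config.height_measurements, "pheno_qc",
                                     pd.read_csv),
        "weight_measurements": _read(config.weight_measurements, "pheno_qc",
                                     pd.read_csv),
        "icd_events": _read(config.icd_events, "pheno_qc", pd.read_csv,
                            dtype={"code": str}),
        "phecode_map": _read(config.phecode_map, "pheno_qc", pd.read_csv,
                             dtype={"code": str, "phecode": str}),
        "weights": _read(config.weights, "grs_instrument", grs.read_weights),
    }
    if str(config.dosages).endswith(".vcf") or str(config.dosages).endswith(".vcf.gz"):
        dos, alleles = _read(config.dosages, "grs_instrument", grs.read_dosages_vcf)
    else:
        dos = _read(config.dosages, "grs_instrument", pd.read_csv, sep="\t",
                    index_col="person_id")
        if config.variants is None:
            raise PipelineError(
                "grs_instrument stage: TSV dosages need a variants allele table")
        alleles = _read(config.variants, "grs_instrument", pd.read_csv, sep="\t")
    inputs["dosages"] = dos
    inputs["variant_alleles"] = alleles
    return inputs


def stage_qc(inputs: dict, config: RunConfig) -> dict:
    """Height/BMI cleaning and phecode matrix construction + filtering."""
    heights, excluded = phenoqc.clean_heights(inputs["height_measurements"])
    cov = inputs["covariates"]
    enrollment = pd.to_datetime(cov["enrollment_date"])
    bmi = phenoqc.clean_bmis(inputs["weight_measurements"], heights, enrollment)
    persons = cov.index.intersection(heights.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix = phenoqc.assign_phecodes(
            inputs["icd_events"], inputs["phecode_map"], persons)
        filtered = phenoqc.filter_phecodes(matrix, config.min_cases,
                                           config.min_controls)
    return {"heights": heights, "bmi": bmi, "height_exclusions": excluded,
            "matrix": matrix, "filtered": filtered, "persons": persons}


def stage_grs(inputs: dict) -> dict:
    scores, match_log = grs.compute_grs(
        inputs["dosages"], inputs["variant_alleles"], inputs["weights"])
    return {"scores": scores, "match_log": match_log}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the result bundle under ``config.outdir``.

    Per-phecode soft errors (non-convergence) never abort; any stage hard
    error raises :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = load_inputs(config)
    qc = stage_qc(inputs, config)
    g = stage_grs(inputs)

    cov = inputs["covariates"]
    pops = config.populations or sorted(cov["population"].unique())
    missing_pops = set(pops) - set(cov["population"].unique())
    if missing_pops:
        raise PipelineError(f"assoc_engine stage: populations {sorted(missing_pops)} "
                            "absent from covariate table")

    status_all = qc["filtered"].status
    results = {}
    manifest: dict = {
        "seed": config.seed,
        "filters": {
            "height": {
                "n_input": int(inputs["height_measurements"]["person_id"].nunique()),
                "n_retained": int(len(qc["heights"])),
                "n_excluded": int(len(qc["height_exclusions"])),
            },
            "phecodes": {
                "n_input": int(qc["matrix"].status.shape[1]),
                "n_retained": int(status_all.shape[1]),
                "n_excluded": int(qc["matrix"].status.shape[1]
                                  - status_all.shape[1]),
            },
        },
        "grs": {
            "n_variants": int(len(inputs["weights"])),
            "n_used": int(g["match_log"]["status"]
                          .isin(["matched", "flipped"]).sum()),
        },
        "populations": {},
    }

    per_pop_mr = {}
    for pop in pops:
        pids = cov.index[cov["population"] == pop].intersection(qc["heights"].index)
        h = qc["heights"].loc[pids]
        covars = cov.loc[pids, [c for c in config.covariate_names
                                if c in cov.columns]]
        status = status_all.loc[pids]
        # re-filter within stratum: thresholds apply to phecodes tested here
        counts_ok = [c for c in status.columns
                     if (status[c] == 1).sum() >= config.min_cases
                     and (status[c] == 0).sum() >= config.min_controls]
        status = status[counts_ok]
        if status.shape[1] == 0:
            warnings.warn(f"population {pop}: no phecode passes the filter")
            continue
        alpha = assoc.bonferroni_threshold(status.shape[1])

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            measured = assoc.phewas_measured(h, status, covars)
            s1_cov = cov.loc[pids, [c for c in config.stage1_covariate_names
                                    if c in cov.columns]]
            s1 = assoc.stage1_predict(h, g["scores"].loc[pids], s1_cov)
            genetic = assoc.mr_phewas(s1, status, covars)
            models = {"measured": measured, "genetic": genetic}
            if config.add_bmi:
                bmi = qc["bmi"].loc[pids].rename("bmi").to_frame()
                models["genetic_bmi"] = assoc.mr_phewas(
                    s1, status, covars, extra_covariates=bmi)

        diag = grs.variance_explained(g["scores"].loc[pids], h)
        manifest["populations"][pop] = {
            "n_persons": int(len(pids)),
            "n_phecodes_tested": int(status.shape[1]),
            "alpha": alpha,
            "stage1_f": s1.f_stat,
            "grs_r2": diag.r2,
            "weak_instrument": bool(s1.weak_instrument),
        }
        for tag, df in models.items():
            path = outdir / f"{tag}_{pop}.tsv"
            annotated = df.copy()
            annotated.insert(1, "group", [phecode_group(c)
                                          for c in annotated["phecode"]])
            annotated.to_csv(path, sep="\t", index=False)
            results[f"{tag}_{pop}"] = annotated
        per_pop_mr[pop] = genetic

    if len(per_pop_mr) >= 2:
        meta_df = meta.meta_analyze_results(per_pop_mr)
        meta_df.to_csv(outdir / "meta_genetic.tsv", sep="\t", index=False)
        results["meta_genetic"] = meta_df
        # meta-analysis significance: threshold of the larger stratum
        largest = max(manifest["populations"],
                      key=lambda p: manifest["populations"][p]["n_persons"])
        manifest["meta_alpha"] = manifest["populations"][largest]["alpha"]

    for spec_raw in config.strata:
        spec = meta.StratumSpec(spec_raw["name"], tuple(str(p) for p in
                                                        spec_raw["phecodes"]))
        pop = pops[0]
        pids = cov.index[cov["population"] == pop].intersection(qc["heights"].index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            strat = meta.stratified_mr(
                qc["heights"].loc[pids], g["scores"].loc[pids],
                status_all.loc[pids],
                cov.loc[pids, [c for c in config.covariate_names
                               if c in cov.columns]],
                spec,
                stage1_covariates=cov.loc[pids,
                                          [c for c in config.stage1_covariate_names
                                           if c in cov.columns]],
                min_cases=config.min_cases, min_controls=config.min_controls)
        strat["heterogeneity"].to_csv(
            outdir / f"stratified_{spec.name}_heterogeneity.tsv",
            sep="\t", index=False)
        for side in ("with", "without"):
            strat[side].to_csv(outdir / f"stratified_{spec.name}_{side}.tsv",
                               sep="\t", index=False)
        results[f"stratified_{spec.name}"] = strat

    qc["height_exclusions"].to_csv(outdir / "height_exclusions.csv", index=False)
    g["match_log"].to_csv(outdir / "grs_match_log.tsv", sep="\t", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    results["manifest"] = manifest
    return results


def manhattan_data(results: pd.DataFrame, *, parent_only: bool = False
                   ) -> pd.DataFrame:
    """Plot table for a PheWAS Manhattan: signed -log10(p) per phecode.

    Negative-beta associations plot below the axis; rows are ordered by
    phecode group then id; the lowest-p association per group gets
    ``label=True``; ``parent_only`` restricts to phecodes with at most one
    decimal place (427.2 shown, 427.21 not).  Non-converged fits are dropped;
    p = 0 is clamped to the smallest positive float with a warning.
    """
    df = results[results["converged"]].copy()
    if parent_only:
        decimals = df["phecode"].astype(str).str.split(".").str[1].fillna("")
        df = df[decimals.str.len() <= 1]
    if (df["p"] <= 0).any():
        warnings.warn("clamping p = 0 to the smallest positive float")
        df.loc[df["p"] <= 0, "p"] = 5e-324
    if "group" not in df.columns:
        df["group"] = [phecode_group(c) for c in df["phecode"]]
    df["y"] = np.sign(df["beta"]) * (-np.log10(df["p"]))
    df["_num"] = pd.to_numeric(df["phecode"], errors="coerce")
    df = df.sort_values(["group", "_num", "phecode"]).drop(columns="_num")
    df["label"] = False
    idx = df.groupby("group")["p"].idxmin()
    df.loc[idx, "label"] = True
    return df.reset_index(drop=True)


def comparison_scatter(results_a: pd.DataFrame, results_b: pd.DataFrame,
                       alpha_a: float, alpha_b: float) -> tuple[pd.DataFrame, dict]:
    """OR-vs-OR scatter table between two analyses plus Venn counts.

    Each joined phecode is categorised as significant in A only, B only, both,
    or neither; the Venn counts cover the three significant categories.
    """
    a = results_a[results_a["converged"]].set_index("phecode")
    b = results_b[results_b["converged"]].set_index("phecode")
    joint = a.join(b, how="inner", lsuffix="_a", rsuffix="_b")
    if joint.empty:
        raise ValueError("no phecodes in common between the two result sets")
    sig_a = joint["p_a"] < alpha_a
    sig_b = joint["p_b"] < alpha_b
    category = np.select(
        [sig_a & sig_b, sig_a & ~sig_b, ~sig_a & sig_b],
        ["both", "a_only", "b_only"], default="neither")
    table = pd.DataFrame({
        "phecode": joint.index, "or_a": joint["or__a"], "or_b": joint["or__b"],
        "p_a": joint["p_a"], "p_b": joint["p_b"], "category": category,
    }).reset_index(drop=True)
    venn = {
        "a_only": int((category == "a_only").sum()),
        "b_only": int((category == "b_only").sum()),
        "both": int((category == "both").sum()),
    }
    return table, venn
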