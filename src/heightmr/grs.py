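"""Weighted height genetic risk score (GRS) and instrument diagnostics.

The instrument is a table of independent height-associated variants with
per-allele effects in cm (the discovery-GWAS betas).  The score for person *i*
is ``sum_j beta_j * d_ij`` where ``d_ij`` is the dosage of the effect allele.
When a genotype file counts the opposite allele the dosage is flipped to
``2 - d``; variants whose allele pair matches in neither orientation are
dropped and logged.  Missing dosages are mean-imputed (2 x cohort effect-allele
frequency), which preserves the score mean.

Diagnostics quantify instrument quality and cross-sample transferability:
variance in height explained (R^2) and the first-stage F statistic,
direction concordance of effect estimates between two samples (chi-square
goodness of fit against 50%), the Z' standardisation
``Z' = beta / (se * sqrt(n))`` and the slope of the best-fit line between two
sets of effect estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

WEIGHT_COLUMNS = ["rsid", "chr", "pos", "effect_allele", "other_allele", "beta"]


class WeakInstrumentError(ValueError):
    """Raised when the score carries no information about the exposure."""


def validate_weights(weights: pd.DataFrame) -> pd.DataFrame:
    """Check a weights table (PGS-Catalog-style) and return it unchanged."""
    missing = set(WEIGHT_COLUMNS) - set(weights.columns)
    if missing:
        raise ValueError(f"weights table missing columns {sorted(missing)}")
    if weights["rsid"].duplicated().any():
        raise ValueError("weights table has duplicate variant ids")
    if not np.all(np.isfinite(weights["beta"].to_numpy(dtype=float))):
        raise ValueError("weights table has non-finite betas")
    for col in ("effect_allele", "other_allele"):
        alleles = weights[col].astype(str)
        if (alleles.str.len() == 0).any() or not alleles.str.fullmatch("[ACGT]+").all():
            raise ValueError(f"{col} must be non-empty A/C/G/T strings")
    return weights


def read_weights(path) -> pd.DataFrame:
    """Read a tab-separated weights table with header rsid/chr/pos/effect_allele/other_allele/beta."""
    return validate_weights(pd.read_csv(path, sep="\t", dtype={"rsid": str, "chr": str}))


def write_weights(weights: pd.DataFrame, path) -> None:
    validate_weights(weights)[WEIGHT_COLUMNS].to_csv(path, sep="\t", index=False)


def is_palindromic(a1: str, a2: str) -> bool:
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    return len(a1) == 1 and len(a2) == 1 and comp.get(a1) == a2


def compute_grs(dosages: pd.DataFrame, variant_alleles: pd.DataFrame,
                weights: pd.DataFrame, *, drop_palindromic: bool = False,
                max_unmatched_frac: float = 0.5) -> tuple[pd.Series, pd.DataFrame]:
    """Score every person against a weights table.

    Parameters
    ----------
    dosages
        person x variant dosage matrix in [0, 2] (NaN = missing); columns are
        variant ids.  Dosages count the `counted_allele` of `variant_alleles`.
    variant_alleles
        Columns variant_id, counted_allele, other_allele describing the
        genotype file's allele orientation.
    weights
        Validated weights table.
    drop_palindromic
        Drop A/T and C/G variants (strand-ambiguous); by default they are
        retained under the assumption that the genotype file is
        strand-consistent with the weights.

    Returns
    -------
    (scores, match_log) — per-person score and a per-variant log with status in
    {matched, flipped, dropped_palindromic, dropped_allele_mismatch,
    dropped_not_in_genotypes, dropped_all_missing}.
    """
    weights = validate_weights(weights)
    alleles = variant_alleles.set_index("variant_id")
    log_rows: list[tuple[str, str]] = []
    cols: list[np.ndarray] = []
    betas: list[float] = []

    for row in weights.itertuples(index=False):
        rid, ea, oa, beta = row.rsid, row.effect_allele, row.other_allele, row.beta
        if rid not in alleles.index or rid not in dosages.columns:
            log_rows.append((rid, "dropped_not_in_genotypes"))
            continue
        if drop_palindromic and is_palindromic(ea, oa):
            log_rows.append((rid, "dropped_palindromic"))
            continue
        counted = alleles.at[rid, "counted_allele"]
        other = alleles.at[rid, "other_allele"]
        d = dosages[rid].to_numpy(dtype=float)
        if counted == ea and other == oa:
            status = "matched"
        elif counted == oa and other == ea:
            d = 2.0 - d
            status = "flipped"
        else:
            log_rows.append((rid, "dropped_allele_mismatch"))
            continue
        if np.isnan(d).all():
            log_rows.append((rid, "dropped_all_missing"))
            continue
        if np.isnan(d).any():
            d = np.where(np.isnan(d), np.nanmean(d), d)
        log_rows.append((rid, status))
        cols.append(d)
        betas.append(float(beta))

    match_log = pd.DataFrame(log_rows, columns=["rsid", "status"])
    n_used = int(match_log["status"].isin(["matched", "flipped"]).sum())
    if n_used < (1.0 - max_unmatched_frac) * len(weights):
        raise ValueError(
            f"only {n_used}/{len(weights)} weight variants matched the genotypes "
            f"(more than {max_unmatched_frac:.0%} unmatched)"
        )
    if cols:
        score = np.column_stack(cols) @ np.asarray(betas)
    else:
        score = np.zeros(len(dosages))
    return pd.Series(score, index=dosages.index, name="grs"), match_log


@dataclass
class InstrumentDiagnostics:
    r2: float
    f_stat: float
    n: int
    n_matched: int = 0
    n_flipped: int = 0
    n_dropped: int = 0


def variance_explained(score, height_cm, covariates: pd.DataFrame | None = None
                       ) -> InstrumentDiagnostics:
    """R^2 of height on the score (partial R^2 given covariates) and F statistic.

    With no covariates, R^2 is the squared Pearson correlation and
    ``F = R^2 (n-2) / (1-R^2)``; with covariates both variables are
    residualised first and the partial-F degrees of freedom are adjusted.
    """
    s = np.asarray(score, dtype=float)
    h = np.asarray(height_cm, dtype=float)
    ok = np.isfinite(s) & np.isfinite(h)
    if covariates is not None:
        c = np.asarray(covariates, dtype=float)
        ok &= np.all(np.isfinite(c), axis=1)
        c = c[ok]
    s, h = s[ok], h[ok]
    n = s.size
    if n < 3:
        raise ValueError("need at least 3 persons with both score and height")
    if np.var(s) == 0:
        raise WeakInstrumentError("score has zero variance; R^2 undefined")
    k = 0
    if covariates is not None and c.shape[1] > 0:
        k = c.shape[1]
        design = np.column_stack([np.ones(n), c])
        s = s - design @ np.linalg.lstsq(design, s, rcond=None)[0]
        h = h - design @ np.linalg.lstsq(design, h, rcond=None)[0]
        if np.var(s) == 0:
            raise WeakInstrumentError("score collinear with covariates")
    r = np.corrcoef(s, h)[0, 1]
    r2 = float(r * r)
    dof = n - 2 - k
    f = float(r2 * dof / (1.0 - r2)) if r2 < 1.0 else float("inf")
    return InstrumentDiagnostics(r2=r2, f_stat=f, n=n)


def direction_concordance(beta_a, beta_b, *, method: str = "chisq"
                          ) -> tuple[float, float]:
    """Proportion of paired estimates with the same sign, and its p-value.

    Pairs where either estimate is exactly zero are excluded from the
    denominator.  The default test is a 1-df chi-square goodness of fit of the
    concordant count against the 50% null; ``method='binomial'`` gives the
    exact two-sided binomial test.
    """
    a = np.asarray(beta_a, dtype=float)
    b = np.asarray(beta_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired estimates must have equal length")
    usable = (a != 0) & (b != 0) & np.isfinite(a) & np.isfinite(b)
    n = int(usable.sum())
    if n < 2:
        raise ValueError("fewer than 2 usable (nonzero) pairs")
    conc = int((np.sign(a[usable]) == np.sign(b[usable])).sum())
    prop = conc / n
    if method == "chisq":
        chi2 = (2.0 * conc - n) ** 2 / n
        p = float(stats.chi2.sf(chi2, df=1))
    elif method == "binomial":
        p = float(stats.binomtest(conc, n, 0.5).pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return prop, p


def zprime(beta: float, se: float, n: float) -> float:
    """Standardised effect size Z' = beta / (se * sqrt(n))."""
    if se <= 0:
        raise ValueError("se must be positive")
    if n <= 0:
        raise ValueError("n must be positive")
    return float(beta / (se * np.sqrt(n)))


@dataclass
class SlopeFit:
    slope: float
    ci_low: float
    ci_high: float
    r: float
    intercept: float


def effect_slope(y_effects, x_effects) -> SlopeFit:
    """OLS slope (with intercept) of one effect-estimate set on another.

    Returns the slope, its Wald 95% CI, and the Pearson correlation.  A slope
    of 1 indicates equivalent effect sizes in the two samples.
    """
    y = np.asarray(y_effects, dtype=float)
    x = np.asarray(x_effects, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired estimates")
    if np.var(x) == 0:
        raise ValueError("zero variance in x effects")
    fit = stats.linregress(x, y)
    half = 1.959963984540054 * fit.stderr
    return SlopeFit(slope=float(fit.slope), ci_low=float(fit.slope - half),
                    ci_high=float(fit.slope + half), r=float(fit.rvalue),
                    intercept=float(fit.intercept))


def read_dosages_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a dosage VCF (FORMAT field DS) into (dosages, variant_alleles).

    The counted allele is ALT; missing DS values become NaN.  Variant ids fall
    back to ``chrom:pos`` when ID is absent.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        ids, counted, other, cols = [], [], [], []
        for rec in vcf:
            vid = rec.id or f"{rec.chrom}:{rec.pos}"
            ids.append(vid)
            counted.append(rec.alts[0] if rec.alts else ".")
            other.append(rec.ref)
            ds = np.full(len(samples), np.nan)
            for i, s in enumerate(samples):
                val = rec.samples[s].get("DS")
                if val is not None:
                    ds[i] = float(val[0] if isinstance(val, tuple) else val)
            cols.append(ds)
    dosages = pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="person_id"), columns=ids,
    )
    alleles = pd.DataFrame(
        {"variant_id": ids, "counted_allele": counted, "other_allele": other}
    )
    return dosages, alleles


def write_dosages_vcf(dosages: pd.DataFrame, variants: pd.DataFrame, path) -> None:
    """Write a person x variant dosage matrix as an uncompressed VCF with DS.

    `variants` needs columns variant_id, chr, pos, counted_allele,
    other_allele; ALT is the counted allele.
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">')
    for chrom in pd.unique(variants["chr"].astype(str)):
        header.contigs.add(chrom)
    for pid in dosages.index:
        header.add_sample(str(pid))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in variants.itertuples(index=False):
            rec = out.new_record(
                contig=str(row.chr), start=int(row.pos) - 1,
                alleles=(row.other_allele, row.counted_allele), id=str(row.variant_id),
            )
            vals = dosages[row.variant_id].to_numpy(dtype=float)
            for pid, v in zip(dosages.index, vals):
                rec.samples[str(pid)]["DS"] = None if np.isnan(v) else float(v)
            out.write(rec)
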