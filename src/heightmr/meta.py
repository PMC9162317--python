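"""Cross-population synthesis: fixed-effects meta-analysis, heterogeneity,
summary-statistic reconstruction, concordance, and stratified runs.

Inverse-variance weighted (IVW) fixed-effects combination: weights
``w_i = 1/se_i^2``, combined ``beta = sum(w b)/sum(w)``,
``se = 1/sqrt(sum w)``; Cochran's ``Q = sum w (b - beta)^2`` is chi-square
with k-1 df under homogeneity.  The two-stratum heterogeneity test
``z = (b1 - b2)/sqrt(se1^2 + se2^2)`` is algebraically the k=2 Cochran Q.

`se_from_p` reconstructs a standard error from a printed effect and p-value
via the inverse normal; the far tail is evaluated in log space
(`scipy.special.ndtri_exp`) so p-values far below 1e-300 round-trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from . import assoc

_LN10 = math.log(10.0)


def p_from_z(z: float) -> float:
    """Two-sided normal p from a z statistic (floored at the tiniest positive float)."""
    return max(2.0 * float(stats.norm.sf(abs(z))), 5e-324)


def log10_p_from_z(z: float) -> float:
    """Two-sided normal log10 p, exact in the far tail."""
    return (math.log(2.0) + float(stats.norm.logsf(abs(z)))) / _LN10


def z_from_p(p: float | None = None, *, log10_p: float | None = None) -> float:
    """|z| such that the two-sided normal p equals the given p (or 10**log10_p)."""
    if (p is None) == (log10_p is None):
        raise ValueError("give exactly one of p or log10_p")
    if p is not None:
        if not 0.0 < p < 1.0:
            raise ValueError("p must lie strictly in (0, 1)")
        log10_p = math.log10(p)
    if log10_p >= 0.0:
        raise ValueError("log10_p must be negative")
    # ndtri_exp(y) = Phi^{-1}(exp(y)); the lower-tail quantile of p/2 is -|z|
    return float(-special.ndtri_exp(log10_p * _LN10 - math.log(2.0)))


def se_from_p(beta: float, p: float | None = None, *,
              log10_p: float | None = None) -> float:
    """Reconstruct se = |beta| / z from an effect estimate and its p-value.

    Accurate deep into the tail (tested to p = 1e-310 via ``log10_p``); used to
    rebuild per-population standard errors from published OR + p pairs.
    """
    if beta == 0:
        raise ValueError("beta must be nonzero (z undefined)")
    z = z_from_p(p, log10_p=log10_p)
    return abs(beta) / z


def se_from_or_ci(or_low: float, or_high: float) -> float:
    """Log-odds se from a 95% CI on an odds ratio: (ln hi - ln lo) / (2 * 1.96)."""
    if not 0 < or_low < or_high:
        raise ValueError("need 0 < or_low < or_high")
    return (math.log(or_high) - math.log(or_low)) / (2.0 * 1.959963984540054)


@dataclass
class MetaResult:
    beta: float
    se: float
    p: float
    k: int
    q: float
    het_p: float
    betas: list = field(default_factory=list)
    ses: list = field(default_factory=list)

    @property
    def or_(self) -> float:
        return math.exp(self.beta)


def ivw_meta(betas, ses) -> MetaResult:
    """Inverse-variance weighted fixed-effects meta-analysis across strata."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size != s.size or b.size < 1:
        raise ValueError("need k >= 1 matched (beta, se) pairs")
    if np.any(s <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (b - beta) ** 2))
    het_p = float(stats.chi2.sf(q, df=b.size - 1)) if b.size > 1 else float("nan")
    return MetaResult(beta=beta, se=se, p=p_from_z(beta / se), k=int(b.size),
                      q=q, het_p=het_p, betas=list(b), ses=list(s))


def heterogeneity_two_strata(beta1: float, se1: float, beta2: float, se2: float
                             ) -> tuple[float, float]:
    """Two-stratum heterogeneity test: z = (b1-b2)/sqrt(se1^2+se2^2), two-sided p."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (beta1 - beta2) / math.sqrt(se1**2 + se2**2)
    return float(z), p_from_z(z)


@dataclass(frozen=True)
class StratumSpec:
    """A stratifying condition defined by a set of phecodes.

    Membership = case (by the >=2-code rule) on any defining phecode; controls
    and one-code (missing) persons count as absent.  Defining phecodes are
    excluded from the outcome sweep within strata.
    """

    name: str
    phecodes: tuple


CHD_STRATUM = StratumSpec(
    "CHD", ("411", "411.1", "411.2", "411.3", "411.4", "411.41", "411.8", "411.9")
)
DIABETES_STRATUM = StratumSpec(
    "diabetes",
    ("250", "250.1", "250.11", "250.12", "250.13", "250.14", "250.15",
     "250.2", "250.21", "250.22", "250.23", "250.24", "250.25", "250.6", "249"),
)


def stratum_membership(status: pd.DataFrame, stratum: StratumSpec) -> pd.Series:
    defining = [p for p in stratum.phecodes if p in status.columns]
    if not defining:
        raise ValueError(f"no defining phecode of stratum {stratum.name!r} in matrix")
    return (status[defining] == 1.0).any(axis=1)


def stratified_mr(height_cm: pd.Series, grs: pd.Series, status: pd.DataFrame,
                  covariates: pd.DataFrame | None, stratum: StratumSpec, *,
                  stage1_covariates: pd.DataFrame | None = None,
                  outcome_phecodes=None, min_cases: int = 200,
                  min_controls: int = 200) -> dict:
    """MR-PheWAS run separately in stratum members and non-members.

    Stage 1 is refit within each stratum; outcome phecodes failing the
    case/control filter within a stratum are skipped there; per-phecode
    heterogeneity between strata is tested for phecodes analysed in both.
    """
    member = stratum_membership(status, stratum)
    if member.sum() == 0 or (~member).sum() == 0:
        empty = "member" if member.sum() == 0 else "non-member"
        raise ValueError(f"stratum {stratum.name!r}: {empty} group is empty")
    defining = set(stratum.phecodes)
    outcomes = [c for c in (outcome_phecodes or status.columns) if c not in defining]

    results = {}
    for label, mask in (("with", member), ("without", ~member)):
        idx = mask[mask].index
        sub = status.loc[idx, outcomes]
        n_case = (sub == 1.0).sum(axis=0)
        n_ctrl = (sub == 0.0).sum(axis=0)
        usable = [c for c in outcomes
                  if n_case[c] >= min_cases and n_ctrl[c] >= min_controls]
        s1 = assoc.stage1_predict(
            height_cm.loc[idx], grs.loc[idx],
            stage1_covariates.loc[idx] if stage1_covariates is not None else None,
        )
        res = assoc.mr_phewas(
            s1, sub,
            covariates.loc[idx] if covariates is not None else None,
            phecodes=usable,
        )
        res["stratum"] = f"{label}_{stratum.name}"
        results[label] = res

    merged = results["without"].merge(
        results["with"], on="phecode", suffixes=("_without", "_with")
    )
    het = []
    for row in merged.itertuples(index=False):
        if not (row.converged_without and row.converged_with):
            continue
        z, p = heterogeneity_two_strata(
            row.beta_without, row.se_without, row.beta_with, row.se_with
        )
        het.append((row.phecode, z, p))
    return {
        "with": results["with"],
        "without": results["without"],
        "heterogeneity": pd.DataFrame(het, columns=["phecode", "z", "het_p"]),
    }


def concordance_summary(results_a: pd.DataFrame, results_b: pd.DataFrame,
                        alpha_a: float, alpha_b: float, *,
                        method: str = "chisq") -> dict:
    """Compare two result sets: Venn counts of significant sets, direction
    concordance among their union, and the Z'-scale effect slope.

    Result frames need columns phecode, beta, se, p, n_case, n_control,
    converged.  Z' = beta / (se sqrt(n)) with n = n_case + n_control; the
    slope is OLS of A's Z' on B's Z' among the union of significant phecodes.
    """
    from . import grs as grs_mod

    a = results_a[results_a["converged"]].set_index("phecode")
    b = results_b[results_b["converged"]].set_index("phecode")
    joint = a.join(b, how="inner", lsuffix="_a", rsuffix="_b")
    if joint.empty:
        raise ValueError("no phecodes in common between the two result sets")
    sig_a = joint["p_a"] < alpha_a
    sig_b = joint["p_b"] < alpha_b
    union = joint[sig_a | sig_b]
    venn = {
        "a_only": int((sig_a & ~sig_b).sum()),
        "b_only": int((~sig_a & sig_b).sum()),
        "both": int((sig_a & sig_b).sum()),
    }
    out = {"venn": venn, "n_joined": int(len(joint)), "n_union": int(len(union))}
    if len(union) >= 2:
        prop, p = grs_mod.direction_concordance(
            union["beta_a"], union["beta_b"], method=method
        )
        out["concordant_proportion"] = prop
        out["concordance_p"] = p
    zp_a = [grs_mod.zprime(r.beta_a, r.se_a, r.n_case_a + r.n_control_a)
            for r in union.itertuples()]
    zp_b = [grs_mod.zprime(r.beta_b, r.se_b, r.n_case_b + r.n_control_b)
            for r in union.itertuples()]
    scatter = pd.DataFrame(
        {"phecode": union.index, "zprime_a": zp_a, "zprime_b": zp_b}
    ).reset_index(drop=True)
    out["zprime"] = scatter
    if len(union) >= 3 and np.var(zp_b) > 0:
        fit = grs_mod.effect_slope(zp_a, zp_b)
        out["slope"] = fit.slope
        out["slope_ci"] = (fit.ci_low, fit.ci_high)
        out["slope_r"] = fit.r
    return out


def meta_analyze_results(results_by_stratum: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """IVW meta-analysis per phecode across per-stratum association results."""
    frames = []
    for name, df in results_by_stratum.items():
        sub = df[df["converged"]][["phecode", "beta", "se"]].copy()
        sub["stratum"] = name
        frames.append(sub)
    stacked = pd.concat(frames, ignore_index=True)
    rows = []
    for code, grp in stacked.groupby("phecode", sort=True):
        m = ivw_meta(grp["beta"].to_numpy(), grp["se"].to_numpy())
        rows.append((code, m.beta, m.se, math.exp(m.beta), m.p, m.k, m.q, m.het_p))
    return pd.DataFrame(
        rows, columns=["phecode", "beta", "se", "or_", "p", "k", "q", "het_p"]
    )
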