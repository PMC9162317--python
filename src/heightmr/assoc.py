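"""Per-phecode association models: measured-height PheWAS and 2SLS MR-PheWAS.

Both sweeps share one logistic engine: maximum likelihood by iteratively
reweighted least squares (IRLS), Wald standard errors from the inverse
observed information, and two-sided normal p-values.  A fit is flagged
non-converged on iteration overrun or detected quasi-complete separation and
is excluded from reports, never aborting the phenome sweep.

The exposure is standardised so every odds ratio is per 1 SD of measured
height: the PheWAS regresses case status on the within-stratum height Z-score;
the MR-PheWAS regresses it on genetically-predicted height — the stage-1
fitted value of height on the GRS (plus PCs) — standardised by the SD of
measured height, so one unit of predicted height corresponds to one height
Z-score unit.  Second-stage standard errors are the naive logistic Wald SEs
(no first-stage correction), which is anti-conservative when the instrument is
weak; a first-stage F < 10 attaches a weak-instrument warning to all
downstream results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special, stats

MAX_ITER = 25
TOL = 1e-8
SEPARATION_PROB = 1e-10
SEPARATION_BETA = 10.0
WEAK_F = 10.0

RESULT_COLUMNS = ["phecode", "model", "n_case", "n_control", "beta", "se",
                  "or_", "p", "converged"]


class RankDeficientError(ValueError):
    """Design matrix is rank deficient (e.g. a constant predictor)."""


@dataclass
class LogisticFit:
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    converged: bool
    separated: bool
    n_iter: int
    n: int


def fit_logistic(y, X, *, max_iter: int = MAX_ITER, tol: float = TOL) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    Converges when ``max |delta beta| < tol``; otherwise the fit is flagged.
    Separation is declared when any fitted probability is below 1e-10 (or
    above 1 - 1e-10) together with a diverging coefficient.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("y and X must align")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    n, k = X.shape
    try:
        linalg.cho_factor(X.T @ X)
    except linalg.LinAlgError as exc:
        raise RankDeficientError("design matrix is rank deficient") from exc

    beta = np.zeros(k)
    converged = False
    info = np.eye(k)
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        info = (X * w[:, None]).T @ X
        grad = X.T @ (y - mu)
        try:
            delta = linalg.solve(info, grad, assume_a="pos")
        except linalg.LinAlgError as exc:
            raise RankDeficientError("information matrix is singular") from exc
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break

    mu = special.expit(np.clip(X @ beta, -30.0, 30.0))
    separated = bool(
        ((mu < SEPARATION_PROB) | (mu > 1.0 - SEPARATION_PROB)).any()
        and np.max(np.abs(beta)) > SEPARATION_BETA
    )
    se = np.sqrt(np.diag(linalg.inv(info)))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), 1e-320)
    return LogisticFit(beta=beta, se=se, p=p,
                       converged=converged and not separated,
                       separated=separated, n_iter=it, n=n)


def bonferroni_threshold(n_phecodes_tested: int) -> float:
    """Phenome-wide significance threshold 0.05 / (number of phecodes tested)."""
    if n_phecodes_tested < 1:
        raise ValueError("need at least one tested phecode")
    return 0.05 / n_phecodes_tested


def _prepare_covariates(covariates: pd.DataFrame | None, index: pd.Index
                        ) -> pd.DataFrame:
    if covariates is None:
        return pd.DataFrame(index=index)
    cov = covariates.loc[index].astype(float)
    constant = [c for c in cov.columns if cov[c].nunique(dropna=True) <= 1]
    if constant:
        warnings.warn(f"dropping zero-variance covariates {constant}", stacklevel=3)
        cov = cov.drop(columns=constant)
    return cov


def _sweep(exposure: pd.Series, status: pd.DataFrame,
           covariates: pd.DataFrame | None, model_tag: str,
           phecodes=None) -> pd.DataFrame:
    """Shared per-phecode logistic sweep; soft-fails each phecode."""
    idx = exposure.index
    cov = _prepare_covariates(covariates, idx)
    base_ok = exposure.notna().to_numpy()
    if len(cov.columns):
        base_ok &= cov.notna().all(axis=1).to_numpy()
    covs = cov.to_numpy(dtype=float) if len(cov.columns) else np.empty((len(idx), 0))
    expo = exposure.to_numpy(dtype=float)
    codes = list(status.columns) if phecodes is None else [str(p) for p in phecodes]

    rows = []
    for code in codes:
        y_all = status[code].to_numpy(dtype=float)
        ok = base_ok & ~np.isnan(y_all)
        y = y_all[ok]
        X = np.column_stack([np.ones(ok.sum()), expo[ok], covs[ok]])
        n_case = int(y.sum())
        n_control = int(ok.sum() - n_case)
        try:
            fit = fit_logistic(y, X)
            beta, se, p, conv = fit.beta[1], fit.se[1], fit.p[1], fit.converged
        except (RankDeficientError, ValueError) as exc:
            warnings.warn(f"phecode {code}: {exc}", stacklevel=3)
            beta = se = p = np.nan
            conv = False
        rows.append((code, model_tag, n_case, n_control, float(beta), float(se),
                     float(np.exp(beta)), float(p), bool(conv)))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def phewas_measured(height_cm: pd.Series, status: pd.DataFrame,
                    covariates: pd.DataFrame | None, *, phecodes=None
                    ) -> pd.DataFrame:
    """Measured-height PheWAS within one analysis stratum.

    Height is standardised to mean 0, SD 1 within the stratum, so the
    reported log-odds beta (and OR) is per 1 SD of measured height.
    """
    h = height_cm.astype(float)
    z = (h - h.mean()) / h.std(ddof=0)
    return _sweep(z, status, covariates, "measured", phecodes)


@dataclass
class Stage1Fit:
    """First-stage linear regression of measured height on the GRS.

    ``predicted`` is the fitted height standardised by the SD of measured
    height, so one unit equals one measured-height Z-score unit.
    """

    grs_coef: float
    grs_se: float
    intercept: float
    sd_height: float
    f_stat: float
    predicted: pd.Series
    weak_instrument: bool
    covariate_coefs: dict = field(default_factory=dict)


def stage1_predict(height_cm: pd.Series, grs: pd.Series,
                   covariates: pd.DataFrame | None = None) -> Stage1Fit:
    """OLS of measured height on the GRS (plus PCs), yielding predicted height.

    The instrument-strength F statistic is the squared t-statistic of the GRS
    coefficient; F < 10 flags a weak instrument.
    """
    import statsmodels.api as sm

    h = height_cm.astype(float)
    g = grs.loc[h.index].astype(float)
    if g.std(ddof=0) == 0:
        raise WeakInstrumentGRSError("GRS has zero variance")
    cov = _prepare_covariates(covariates, h.index)
    X = pd.concat([g.rename("grs"), cov], axis=1)
    X = sm.add_constant(X, prepend=True)
    res = sm.OLS(h, X, missing="drop").fit()
    sd_h = float(h.std(ddof=0))
    fitted = res.fittedvalues
    predicted = (fitted - fitted.mean()) / sd_h
    f_stat = float((res.params["grs"] / res.bse["grs"]) ** 2)
    weak = f_stat < WEAK_F
    if weak:
        warnings.warn(
            f"weak instrument: first-stage F = {f_stat:.2f} < {WEAK_F}",
            stacklevel=2,
        )
    return Stage1Fit(
        grs_coef=float(res.params["grs"]), grs_se=float(res.bse["grs"]),
        intercept=float(res.params["const"]), sd_height=sd_h, f_stat=f_stat,
        predicted=predicted.rename("predicted_height_sd"),
        weak_instrument=weak,
        covariate_coefs={c: float(res.params[c]) for c in cov.columns},
    )


class WeakInstrumentGRSError(ValueError):
    pass


def mr_phewas(stage1: Stage1Fit, status: pd.DataFrame,
              covariates: pd.DataFrame | None, *,
              extra_covariates: pd.DataFrame | None = None,
              phecodes=None) -> pd.DataFrame:
    """Two-stage least squares MR-PheWAS (second stage).

    Logistic regression of each phecode on standardised genetically-predicted
    height plus covariates; with ``extra_covariates`` (e.g. BMI) the result is
    the sensitivity model tagged ``genetic+BMI``.
    """
    tag = "genetic"
    cov = covariates
    if extra_covariates is not None:
        tag = "genetic+BMI"
        cov = pd.concat(
            [covariates, extra_covariates.loc[stage1.predicted.index]], axis=1
        ) if covariates is not None else extra_covariates
    out = _sweep(stage1.predicted, status, cov, tag, phecodes)
    out["weak_instrument"] = stage1.weak_instrument
    return out


def two_stage_least_squares(y, exposure, instrument) -> float:
    """2SLS slope for a continuous outcome with a single instrument.

    Stage 1 regresses the exposure on the instrument; stage 2 regresses the
    outcome on the stage-1 fitted values.  With no covariates this equals the
    Wald ratio cov(y, G) / cov(exposure, G) exactly.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(exposure, dtype=float)
    g = np.asarray(instrument, dtype=float)
    b1 = np.cov(x, g, ddof=0)[0, 1] / np.var(g)
    fitted = b1 * g
    return float(np.cov(y, fitted, ddof=0)[0, 1] / np.var(fitted))
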