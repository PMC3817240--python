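"""Per-SNP case/control logistic association with covariate adjustment.

Mirrors the PLINK-style workflow: additive minor-allele dosage coding,
logistic regression by iteratively reweighted least squares, two-sided
Wald tests, and 95% CIs on the odds-ratio scale.  Missing genotypes are
handled pairwise-complete (the sample is dropped for that SNP only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "AssocRecord",
    "fit_snp_logistic",
    "association_scan",
    "wald_p_from_or_ci",
    "significant_snps",
    "irls_logistic",
]

Z975 = 1.959964  # Phi^{-1}(0.975), the conventional 95% multiplier


@dataclass
class AssocRecord:
    """One SNP's association result (Table-style OR/L95/U95/P columns)."""

    snp: str
    beta: float
    se: float
    or_: float
    l95: float
    u95: float
    p: float
    n_used: int
    maf: float
    status: str = "ok"  # ok | monomorphic | insufficient | separation | nonconverged


def irls_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-8):
    """Logistic regression by IRLS.

    Converges when the relative change in log-likelihood drops below
    ``tol``.  Returns (beta, se, converged).  ``se`` comes from the
    inverse observed information.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        grad = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        eta = X @ beta
        # log-likelihood via the numerically stable log(1+exp) form
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if ll_old > -np.inf and abs(ll - ll_old) < tol * (abs(ll_old) + 1e-12):
            converged = True
            break
        ll_old = ll
    eta = X @ beta
    mu = expit(eta)
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
    return beta, se, converged


def fit_snp_logistic(study, snp_index: int, covariate_names=("age",)) -> AssocRecord:
    """Additive logistic fit of case status on one SNP's dosage plus
    covariates; Wald z = beta/se, CI = exp(beta +/- 1.959964*se).

    Monomorphic or data-poor SNPs come back with a reason in ``status``
    and missing statistics; separation (|beta| > 10) or non-convergence
    flags the record with ``p`` set missing.
    """
    if study.phenotype is None:
        raise ValueError("study has no phenotype attached")
    g = study.G[:, snp_index]
    keep = ~np.isnan(g)
    cov = None
    if covariate_names:
        cov = study.covariates[list(covariate_names)].to_numpy(dtype=float)
        keep &= ~np.isnan(cov).any(axis=1)
    g_used = g[keep]
    y = study.phenotype[keep]
    snp = study.variants[snp_index].id
    n_used = int(keep.sum())
    maf = float(np.nan) if n_used == 0 else float(min(g_used.mean() / 2, 1 - g_used.mean() / 2))

    blank = dict(beta=np.nan, se=np.nan, or_=np.nan, l95=np.nan, u95=np.nan, p=np.nan)
    if n_used == 0 or np.all(g_used == g_used[0]):
        return AssocRecord(snp=snp, n_used=n_used, maf=maf, status="monomorphic", **blank)
    if (y == 1).sum() < 10 or (y == 0).sum() < 10:
        return AssocRecord(snp=snp, n_used=n_used, maf=maf, status="insufficient", **blank)

    cols = [np.ones(n_used), g_used]
    if cov is not None:
        cols.extend(cov[keep][:, i] for i in range(cov.shape[1]))
    X = np.column_stack(cols)
    beta_vec, se_vec, converged = irls_logistic(X, y.astype(float))
    beta, se = float(beta_vec[1]), float(se_vec[1])
    status = "ok"
    p = 2.0 * norm.sf(abs(beta) / se) if se > 0 else np.nan
    if abs(beta) > 10:
        status, p = "separation", np.nan
    elif not converged:
        status, p = "nonconverged", np.nan
    with np.errstate(over="ignore"):
        return AssocRecord(
            snp=snp, beta=beta, se=se, or_=float(np.exp(beta)),
            l95=float(np.exp(beta - Z975 * se)), u95=float(np.exp(beta + Z975 * se)),
            p=float(p) if p == p else np.nan, n_used=n_used, maf=maf, status=status,
        )


def association_scan(study, covariate_names=("age",)) -> pd.DataFrame:
    """Fit every SNP; returns a Table-3-shaped frame (one row per SNP)."""
    recs = [fit_snp_logistic(study, j, covariate_names) for j in range(study.n_snp)]
    return pd.DataFrame([vars(r) for r in recs])


def wald_p_from_or_ci(or_: float, l95: float, u95: float) -> float:
    """Recover the two-sided Wald P from a printed OR and its 95% CI.

    se = (ln U95 - ln L95) / (2 * 1.959964); p = 2*Phi(-|ln OR| / se).
    Used to verify published association tables from their own rounding.
    """
    if not (0 < l95 <= or_ <= u95):
        raise ValueError(f"require 0 < L95 <= OR <= U95, got ({or_}, {l95}, {u95})")
    se = (np.log(u95) - np.log(l95)) / (2.0 * Z975)
    if se == 0:
        return 0.0 if or_ != 1.0 else 1.0
    return float(2.0 * norm.sf(abs(np.log(or_)) / se))


def significant_snps(records, alpha: float = 0.05) -> list[int]:
    """Indices of records with p strictly below alpha (missing p excluded)."""
    if isinstance(records, pd.DataFrame):
        ps = records["p"].to_numpy(dtype=float)
    else:
        ps = np.array([r.p for r in records], dtype=float)
    return [i for i, p in enumerate(ps) if p == p and p < alpha]
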