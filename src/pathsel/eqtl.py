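"""Additive linear-regression eQTL scan with permutation significance.

Each SNP/probe pair is tested by ordinary least squares of normalized
expression on allele dosage (two-sided t-test on the slope); empirical
significance comes from permuting the expression vector, with the usual
add-one correction so no permutation p can be exactly zero.  Pairs are
labeled cis when SNP and probe sit on the same chromosome within 1 Mb
(inclusive), trans otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _all_perms
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EQTLRecord",
    "eqtl_test",
    "eqtl_permutation_p",
    "classify_cis_trans",
    "eqtl_scan",
]


@dataclass
class EQTLRecord:
    snp: str
    probe: str
    beta: float
    nominal_p: float
    permutation_p: float
    distance_bp: float  # signed SNP - probe, NaN across chromosomes
    label: str  # "cis" | "trans"


def _complete(dosage, expression):
    g = np.asarray(dosage, dtype=float)
    e = np.asarray(expression, dtype=float)
    keep = ~(np.isnan(g) | np.isnan(e))
    return g[keep], e[keep]


def _check_testable(g: np.ndarray, e: np.ndarray) -> None:
    values, counts = np.unique(g, return_counts=True)
    if values.size < 2 or np.ptp(e) == 0:
        raise ValueError("constant dosage or constant expression")
    if values.size == 2 and g.size < 10:
        raise ValueError("two dosage classes require n >= 10")


def eqtl_test(dosage, expression) -> tuple[float, float]:
    """OLS slope of expression on dosage and its two-sided t-test p."""
    g, e = _complete(dosage, expression)
    _check_testable(g, e)
    res = stats.linregress(g, e)
    return float(res.slope), float(res.pvalue)


def _abs_t_from_r2(r2: np.ndarray, df: int) -> np.ndarray:
    r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
    return np.sqrt(r2 * df / (1.0 - r2))


def eqtl_permutation_p(dosage, expression, B: int = 10_000, seed: int = 0,
                       exact: bool = False) -> float:
    """Permutation p for the slope's |t|.

    Expression labels are shuffled B times; p = (1 + #{|t_perm| >=
    |t_obs|}) / (B + 1).  With ``exact=True`` every permutation of the
    expression vector is enumerated instead (identity included), giving
    p = #{|t_perm| >= |t_obs|} / n!; feasible only for tiny n.
    """
    g, e = _complete(dosage, expression)
    _check_testable(g, e)
    n = g.size
    gc = g - g.mean()
    ec = e - e.mean()
    ng = np.linalg.norm(gc)
    ne = np.linalg.norm(ec)
    r_obs = float(gc @ ec / (ng * ne))
    df = n - 2
    t_obs = _abs_t_from_r2(np.array([r_obs ** 2]), df)[0]
    if exact:
        count = 0
        total = factorial(n)
        for perm in _all_perms(range(n)):
            r = float(gc @ ec[list(perm)] / (ng * ne))
            if _abs_t_from_r2(np.array([r ** 2]), df)[0] >= t_obs - 1e-12:
                count += 1
        return count / total
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    # permuted centered expression keeps its norm: batch the dot products
    P = np.empty((B, n))
    for b in range(B):
        P[b] = ec[rng.permutation(n)]
    r = (P @ gc) / (ng * ne)
    t = _abs_t_from_r2(r ** 2, df)
    return float((1 + int(np.sum(t >= t_obs - 1e-12))) / (B + 1))


def classify_cis_trans(snp, probe, window_bp: int = 1_000_000) -> str:
    """cis iff same chromosome and |SNP - probe| <= window_bp (inclusive)."""
    if snp.chrom != probe.chrom:
        return "trans"
    return "cis" if abs(snp.pos_bp - probe.pos_bp) <= window_bp else "trans"


def eqtl_scan(study, expression, snp_indices=None, probe_indices=None,
              B: int = 10_000, seed: int = 0, window_bp: int = 1_000_000) -> pd.DataFrame:
    """Test every (SNP, probe) combination from the given index sets.

    Expression columns are aligned to the study samples by id.  Pairs
    that are untestable (constant dosage/expression) are reported with
    missing statistics and a reason.
    """
    expr = expression.aligned_to(study.samples)
    snp_indices = range(study.n_snp) if snp_indices is None else snp_indices
    probe_indices = range(len(expr.probes)) if probe_indices is None else probe_indices
    rows = []
    for si in snp_indices:
        v = study.variants[si]
        g = study.G[:, si]
        for pi in probe_indices:
            probe = expr.probes[pi]
            dist = (v.pos_bp - probe.pos_bp) if v.chrom == probe.chrom else np.nan
            label = classify_cis_trans(v, probe, window_bp)
            row = dict(snp=v.id, probe=probe.id, beta=np.nan, nominal_p=np.nan,
                       permutation_p=np.nan, distance_bp=dist, label=label, reason="")
            try:
                beta, p = eqtl_test(g, expr.E[pi])
                pp = eqtl_permutation_p(g, expr.E[pi], B=B,
                                        seed=seed + 131 * si + pi)
                row.update(beta=beta, nominal_p=p, permutation_p=pp)
            except ValueError as err:
                row["reason"] = str(err)
            rows.append(row)
    return pd.DataFrame(rows)
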