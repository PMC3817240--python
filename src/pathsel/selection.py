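"""EHH / iHH / iHS selection scan and the gene-window empirical caller.

EHH at distance x from a core SNP is the probability that two randomly
drawn haplotypes carrying the same core allele are identical over the
whole interval from the core out to x.  iHH integrates the EHH curve
over genetic distance (trapezoid rule, each direction truncated at the
first point where EHH drops below the 0.05 floor, Voight et al.'s
convention).  The unstandardized score ln(iHH_A / iHH_D) is standardized
to mean 0, sd 1 within derived-allele-frequency bins, so extreme values
in either tail flag unusually long haplotypes around one allele —
the footprint of a recent partial sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EHHCurve",
    "IHSRecord",
    "GeneSelectionRecord",
    "ehh",
    "ihh",
    "ihs_scan",
    "select_candidate_loci",
    "gene_window_scan",
    "window_candidates",
]

EHH_FLOOR = 0.05


@dataclass
class EHHCurve:
    """EHH decay for one core allele class, both directions.

    ``left``/``right`` are (distance_cM, EHH) arrays ordered outward from
    the core; distance is |cM - cM_core| and the core itself (distance 0,
    EHH 1) is the first entry of each.  ``*_hit_floor`` records whether
    the decay reached ``floor`` before the panel edge.
    """

    core_index: int
    allele_class: str  # "ancestral" | "derived"
    n_carriers: int
    left: np.ndarray
    right: np.ndarray
    left_hit_floor: bool
    right_hit_floor: bool
    floor: float


@dataclass
class IHSRecord:
    snp: str
    index: int
    daf: float
    ihh_a: float
    ihh_d: float
    uihs: float
    ihs: float = float("nan")
    bin_id: int = -1
    truncated: bool = False


@dataclass
class GeneSelectionRecord:
    gene: str
    index_snp: str
    window_indices: list[int]
    n_significant: int
    empirical_fraction: float
    candidate: bool
    short_window: bool = False


# ---------------------------------------------------------------------------
# EHH


def _ehh_one_side(H: np.ndarray, carriers: np.ndarray, core: int, step: int,
                  cm: np.ndarray, floor: float):
    """Walk outward (step=+1 right, -1 left) refining the carrier
    partition by each successive SNP; stop after the first EHH < floor
    (that point is kept) or at the panel edge."""
    n_c = carriers.size
    denom = n_c * (n_c - 1)
    dist = [0.0]
    vals = [1.0]
    group = np.zeros(n_c, dtype=np.int64)
    hit_floor = False
    j = core + step
    m = H.shape[1]
    while 0 <= j < m:
        keys = group * 2 + H[carriers, j]
        _, group = np.unique(keys, return_inverse=True)
        counts = np.bincount(group)
        e = float((counts * (counts - 1)).sum() / denom)
        dist.append(abs(cm[j] - cm[core]))
        vals.append(e)
        if e < floor:
            hit_floor = True
            break
        j += step
    return np.array(dist), np.array(vals), hit_floor


def ehh(panel, core_index: int, allele_class: str, floor: float = 0.0) -> EHHCurve:
    """EHH decay curve for one core allele class.

    By default the curve runs to the panel edge (or to EHH = 0, beyond
    which it cannot recover); pass ``floor`` to stop early, as the iHS
    scan does.  Requires >= 2 carriers of the class's allele.
    """
    if allele_class not in ("ancestral", "derived"):
        raise ValueError("allele_class must be 'ancestral' or 'derived'")
    target = 1 if allele_class == "derived" else 0
    carriers = np.nonzero(panel.H[:, core_index] == target)[0]
    if carriers.size < 2:
        raise ValueError(
            f"core {core_index}: fewer than 2 {allele_class} carriers"
        )
    cm = panel.map_cM
    if np.isnan(cm).any():
        raise ValueError("panel lacks genetic-map positions (attach a map first)")
    ld, lv, lhit = _ehh_one_side(panel.H, carriers, core_index, -1, cm, floor)
    rd, rv, rhit = _ehh_one_side(panel.H, carriers, core_index, +1, cm, floor)
    return EHHCurve(core_index, allele_class, carriers.size,
                    np.column_stack([ld, lv]), np.column_stack([rd, rv]),
                    lhit, rhit, floor)


def ihh(curve: EHHCurve, floor: float = EHH_FLOOR) -> tuple[float, bool]:
    """Integrate EHH over genetic distance (cM), trapezoid rule.

    Each direction is truncated at the first point with EHH < floor
    (the closing trapezoid down to that point is included).  Returns
    (iHH, truncated) where ``truncated`` is True when either direction
    ran off the panel edge before reaching the floor.
    """
    if curve.left[-1, 0] == 0.0 and curve.right[-1, 0] == 0.0:
        raise ValueError("zero genetic-map span around the core")
    total = 0.0
    truncated = False
    for side in (curve.left, curve.right):
        d, e = side[:, 0], side[:, 1]
        below = np.nonzero(e < floor)[0]
        stop = below[0] if below.size else len(e) - 1
        if below.size == 0:
            truncated = True  # edge reached while still above the floor
        total += float(np.trapezoid(e[: stop + 1], d[: stop + 1]))
    return total, truncated


# ---------------------------------------------------------------------------
# iHS scan


def _merge_small_bins(bin_ids: np.ndarray, n_bins: int, min_size: int = 10) -> np.ndarray:
    """Relabel frequency bins so each has >= min_size members, merging
    undersized bins into their lower neighbor (or upward at the left edge)."""
    remap = np.arange(n_bins)
    counts = np.bincount(bin_ids, minlength=n_bins)
    merged_any = False
    # iterate until stable
    for _ in range(n_bins):
        sizes = np.bincount(remap[bin_ids], minlength=n_bins)
        occupied = [b for b in range(n_bins) if sizes[b] > 0]
        small = [b for b in occupied if sizes[b] < min_size]
        if not small or len(occupied) == 1:
            break
        b = small[0]
        neighbors = [o for o in occupied if o != b]
        lower = [o for o in neighbors if o < b]
        upper = [o for o in neighbors if o > b]
        tgt = max(lower) if lower else min(upper)
        remap[remap == b] = tgt
        merged_any = True
    if merged_any:
        warnings.warn("iHS frequency bins with <10 SNPs merged with neighbors")
    return remap[bin_ids]


def ihs_scan(panel, maf_min: float = 0.05, bin_width: float = 0.05,
             floor: float = EHH_FLOOR, include_inferred_ancestral: bool = True) -> pd.DataFrame:
    """Standardized iHS for every eligible core SNP.

    Cores need MAF > ``maf_min`` and a resolved (or inferred, unless
    disabled) ancestral state.  uiHS = ln(iHH_A / iHH_D), standardized
    within derived-allele-frequency bins of width ``bin_width`` (bins
    with fewer than 10 scored SNPs are merged).  SNPs whose EHH never
    reaches the floor before the panel edge, or with zero iHH, are
    excluded with a reason code.  Columns: snp, index, daf, ihh_a,
    ihh_d, uihs, ihs, bin_id, reason (empty for scored SNPs).
    """
    daf = panel.derived_freq()
    rows = []
    for j in range(panel.n_snp):
        v = panel.variants[j]
        maf = min(daf[j], 1 - daf[j])
        base = dict(snp=v.id, index=j, daf=float(daf[j]), ihh_a=np.nan,
                    ihh_d=np.nan, uihs=np.nan, ihs=np.nan, bin_id=-1)
        if maf <= maf_min:
            rows.append({**base, "reason": "maf"})
            continue
        if v.ancestral == "unknown" or (v.ancestral_inferred and not include_inferred_ancestral):
            rows.append({**base, "reason": "ancestral"})
            continue
        try:
            curve_a = ehh(panel, j, "ancestral", floor=floor)
            curve_d = ehh(panel, j, "derived", floor=floor)
        except ValueError:
            rows.append({**base, "reason": "carriers"})
            continue
        ihh_a, trunc_a = ihh(curve_a, floor)
        ihh_d, trunc_d = ihh(curve_d, floor)
        base.update(ihh_a=ihh_a, ihh_d=ihh_d)
        if trunc_a or trunc_d:
            rows.append({**base, "reason": "truncated"})
            continue
        if ihh_a <= 0 or ihh_d <= 0:
            rows.append({**base, "reason": "zero_ihh"})
            continue
        base["uihs"] = float(np.log(ihh_a / ihh_d))
        rows.append({**base, "reason": ""})
    df = pd.DataFrame(rows)
    scored = df["reason"] == ""
    if scored.sum() == 0:
        return df
    dafs = df.loc[scored, "daf"].to_numpy()
    n_bins = int(np.ceil(1.0 / bin_width))
    bin_ids = np.minimum((dafs / bin_width).astype(int), n_bins - 1)
    bin_ids = _merge_small_bins(bin_ids, n_bins)
    u = df.loc[scored, "uihs"].to_numpy()
    z = np.full(u.shape, np.nan)
    for b in np.unique(bin_ids):
        sel = bin_ids == b
        mu, sd = u[sel].mean(), u[sel].std(ddof=0)
        z[sel] = 0.0 if sd == 0 else (u[sel] - mu) / sd
    df.loc[scored, "ihs"] = z
    df.loc[scored, "bin_id"] = bin_ids
    return df


# ---------------------------------------------------------------------------
# joins and window scan


def select_candidate_loci(ihs_df: pd.DataFrame, assoc_df: pd.DataFrame,
                          ihs_threshold: float = 1.65, alpha: float = 0.05) -> pd.DataFrame:
    """SNPs that are both associated (p < alpha, strict) and extreme in
    |iHS| (> threshold, strict), sorted by |iHS| descending."""
    merged = assoc_df.merge(ihs_df[["snp", "daf", "ihs"]], on="snp", how="inner")
    keep = (merged["p"] < alpha) & (merged["ihs"].abs() > ihs_threshold)
    out = merged[keep].copy()
    out["abs_ihs"] = out["ihs"].abs()
    return out.sort_values("abs_ihs", ascending=False).drop(columns="abs_ihs").reset_index(drop=True)


def window_candidates(gene_counts: np.ndarray, window_counts: np.ndarray,
                      upper_fraction: float = 0.10):
    """Flag genes whose window count reaches the (1 - upper_fraction)
    quantile of the genome-wide sliding-window count distribution;
    also return, per gene, the fraction of windows with >= its count."""
    window_counts = np.asarray(window_counts, dtype=float)
    gene_counts = np.asarray(gene_counts, dtype=float)
    q = np.quantile(window_counts, 1.0 - upper_fraction)
    # a gene with no significant SNPs is never a candidate, even when the
    # genome-wide distribution is all zeros
    flags = (gene_counts >= q) & (gene_counts > 0)
    fractions = np.array([(window_counts >= c).mean() for c in gene_counts])
    return flags, fractions, float(q)


def gene_window_scan(ihs_df: pd.DataFrame, genes, variants,
                     window_snps: int = 50, sig_threshold: float = 2.0,
                     upper_fraction: float = 0.10) -> list[GeneSelectionRecord]:
    """Gene-level empirical selection caller.

    For each gene: the index SNP is the scored SNP nearest the gene
    midpoint; its window is ``window_snps`` scored SNPs centered there
    (clipped at the panel edge; flagged short when fewer are available);
    the count of |iHS| > sig_threshold in the window is referred to the
    distribution of counts over all genome-wide sliding windows, and the
    gene is a candidate iff its count reaches the upper
    ``upper_fraction`` tail of that distribution.
    """
    scored = ihs_df[ihs_df["reason"] == ""].reset_index(drop=True)
    if scored.empty:
        return [GeneSelectionRecord(g.name, "", [], 0, 1.0, False, True) for g in genes]
    pos = np.array([variants[i].pos_bp for i in scored["index"]])
    chroms = np.array([variants[i].chrom for i in scored["index"]])
    sig = (scored["ihs"].abs() > sig_threshold).to_numpy().astype(int)

    # genome-wide sliding-window count distribution, per chromosome
    window_counts = []
    for c in np.unique(chroms):
        s = sig[chroms == c]
        w = min(window_snps, s.size)
        csum = np.concatenate([[0], np.cumsum(s)])
        window_counts.append(csum[w:] - csum[:-w])
    window_counts = np.concatenate(window_counts)

    half = window_snps // 2
    records = []
    gene_counts = []
    metas = []
    for g in genes:
        on_chrom = np.nonzero(chroms == g.chrom)[0]
        if on_chrom.size == 0:
            metas.append(None)
            gene_counts.append(0)
            continue
        nearest = on_chrom[np.argmin(np.abs(pos[on_chrom] - g.midpoint_bp))]
        rank = int(np.searchsorted(on_chrom, nearest))
        lo = max(0, rank - half)
        hi = min(on_chrom.size, lo + window_snps)
        lo = max(0, hi - window_snps)
        win = on_chrom[lo:hi]
        short = win.size < window_snps
        count = int(sig[win].sum())
        gene_counts.append(count)
        metas.append((scored["snp"].iloc[nearest], [int(scored["index"].iloc[i]) for i in win], short))
    flags, fractions, _ = window_candidates(np.array(gene_counts), window_counts, upper_fraction)
    for g, count, meta, flag, frac in zip(genes, gene_counts, metas, flags, fractions):
        if meta is None:
            records.append(GeneSelectionRecord(g.name, "", [], 0, 1.0, False, True))
        else:
            idx_snp, win_idx, short = meta
            records.append(GeneSelectionRecord(g.name, idx_snp, win_idx, count,
                                               float(frac), bool(flag), short))
    return records
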