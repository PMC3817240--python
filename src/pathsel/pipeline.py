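"""Orchestration of the full evidence chain and the report shapes.

The pipeline runs: per-SNP logistic association -> gene/pathway ARTP ->
iHS selection scan -> candidate-locus join (assoc p < alpha and |iHS| >
suggestive threshold) -> gene-window empirical scan -> eQTL on the
surviving loci -> a per-SNP evidence summary table.  Every stage's
output is persisted so the final report is recomputable from the stage
files, and the whole run is deterministic under the config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import artp as _artp
from . import eqtl as _eqtl
from . import selection as _selection
from .association import association_scan, significant_snps
from .core_io import GenotypeStudy, PipelineConfig, assign_snps_to_genes

__all__ = [
    "EvidenceSummary",
    "run_pipeline",
    "summarize_fixture_table3",
    "cohort_descriptives",
    "load_table1_fixture",
    "load_table3_fixture",
    "load_table5_fixture",
]

log = logging.getLogger("pathsel")


# ---------------------------------------------------------------------------
# packaged fixtures


def _fixture(name: str) -> pd.DataFrame:
    with resources.files("pathsel.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", na_values=["NA"])


def load_table1_fixture() -> pd.DataFrame:
    """Cohort characteristic counts (cases/controls)."""
    return _fixture("table1_cohort.tsv")


def load_table3_fixture() -> pd.DataFrame:
    """Association + iHS table for the 27 doubly-supported SNPs."""
    return _fixture("table3_assoc_ihs.tsv")


def load_table5_fixture() -> pd.DataFrame:
    """The five loci supported by every evidence layer."""
    return _fixture("table5_positive_loci.tsv")


# ---------------------------------------------------------------------------
# fixture arithmetic


def summarize_fixture_table3(fixture: pd.DataFrame,
                             thresholds=(1.65, 2.0)) -> dict:
    """Argmax of |iHS_ASN| and counts passing each threshold."""
    if fixture.empty or fixture["ihs_asn"].dropna().empty:
        return {"max_snp": None, "max_abs_ihs": np.nan,
                "counts": {float(t): 0 for t in thresholds}}
    abs_ihs = fixture["ihs_asn"].abs()
    i = abs_ihs.idxmax()
    return {
        "max_snp": str(fixture.loc[i, "snp"]),
        "max_abs_ihs": float(abs_ihs[i]),
        "counts": {float(t): int((abs_ihs.dropna() > t).sum()) for t in thresholds},
    }


def cohort_descriptives(counts: dict[str, int], total: int, missing: int = 0) -> pd.DataFrame:
    """Percentage table over non-missing subjects, one decimal.

    percentage = 100 * count / (total - missing).
    """
    if total <= missing:
        raise ValueError(f"total ({total}) must exceed missing ({missing})")
    denom = total - missing
    rows = [
        {"category": k, "count": int(v), "percent": round(100.0 * v / denom, 1)}
        for k, v in counts.items()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end run


@dataclass
class EvidenceSummary:
    """All persisted stage outputs plus the final per-SNP summary."""

    assoc_table: pd.DataFrame
    artp_table: pd.DataFrame
    pathway_p: float
    ihs_table: pd.DataFrame
    candidate_table: pd.DataFrame
    gene_scan_table: pd.DataFrame
    eqtl_table: pd.DataFrame
    summary_table: pd.DataFrame
    config: PipelineConfig
    manifest: dict


def _genotype_counts(study: GenotypeStudy, snp_index: int) -> tuple[int, int, int]:
    g = study.G[:, snp_index]
    g = g[~np.isnan(g)]
    return int((g == 2).sum()), int((g == 1).sum()), int((g == 0).sum())  # mm, Mm, MM


def _write_stage(outdir: Path | None, name: str, df: pd.DataFrame) -> None:
    if outdir is not None:
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig, panel, study, genes,
                 expression=None, outdir=None, prefilter_alpha=None) -> EvidenceSummary:
    """Execute the whole evidence chain on aligned inputs.

    ``panel`` (phased, mapped) feeds the selection scan; ``study``
    (dosages + phenotype + age) feeds association/ARTP/eQTL; ``genes``
    are flank-extended intervals; ``expression`` is optional.  With
    ``prefilter_alpha`` set, ARTP only sees SNPs whose observed
    association p is below it (the selection-biased workflow some
    published analyses use); default is all SNPs per gene.
    """
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    stage = "association"
    try:
        assoc = association_scan(study)
        log.info("association: %d SNPs, %d significant at %.3g",
                 len(assoc), len(significant_snps(assoc, config.assoc_alpha)),
                 config.assoc_alpha)
        _write_stage(outdir, "assoc", assoc)

        stage = "artp"
        gene_snps = assign_snps_to_genes(study.variants, genes, config.gene_flank_bp)
        if prefilter_alpha is not None:
            sig = set(significant_snps(assoc, prefilter_alpha))
            gene_snps = {g: [i for i in idx if i in sig] for g, idx in gene_snps.items()}
        gene_rows, minp_cols, gene_names = [], [], []
        for g in genes:
            idx = gene_snps.get(g.name, [])
            if not idx:
                gene_rows.append({"gene": g.name, "n_snps": 0, "p": np.nan})
                continue
            P = _artp.permutation_p_matrix(study, idx, config.n_permutations,
                                           seed=config.rng_seed + 7)
            p, diag = _artp.artp_gene_p(P)
            gene_rows.append({"gene": g.name, "n_snps": len(idx), "p": p})
            minp_cols.append(diag["minp"])
            gene_names.append(g.name)
        artp_table = pd.DataFrame(gene_rows)
        pathway_p = np.nan
        if minp_cols:
            pathway_p, _ = _artp.artp_pathway_p(minp_cols)
        log.info("artp: %d genes, pathway p=%.4g", len(gene_names), pathway_p)
        _write_stage(outdir, "artp", artp_table)

        stage = "ihs_scan"
        ihs_table = _selection.ihs_scan(panel, maf_min=config.maf_min,
                                        bin_width=config.ihs_bin_width)
        _write_stage(outdir, "ihs", ihs_table)

        stage = "candidate_join"
        candidates = _selection.select_candidate_loci(
            ihs_table, assoc, config.ihs_suggestive, config.assoc_alpha)
        log.info("candidate loci: %d pass p<%.3g and |iHS|>%.3g",
                 len(candidates), config.assoc_alpha, config.ihs_suggestive)
        _write_stage(outdir, "candidates", candidates)

        stage = "gene_window_scan"
        scan = _selection.gene_window_scan(
            ihs_table, genes, panel.variants, config.window_snps,
            config.ihs_strong, config.window_upper_fraction)
        gene_scan_table = pd.DataFrame([
            {"gene": r.gene, "index_snp": r.index_snp, "n_significant": r.n_significant,
             "empirical_fraction": r.empirical_fraction, "candidate": r.candidate,
             "short_window": r.short_window}
            for r in scan
        ])
        _write_stage(outdir, "gene_scan", gene_scan_table)

        stage = "eqtl"
        snp_ids = {v.id: i for i, v in enumerate(study.variants)}
        surviving = [snp_ids[s] for s in candidates["snp"] if s in snp_ids]
        if expression is not None and surviving:
            eqtl_table = _eqtl.eqtl_scan(
                study, expression, snp_indices=surviving,
                B=config.n_permutations, seed=config.rng_seed + 13,
                window_bp=config.cis_window_bp)
        else:
            eqtl_table = pd.DataFrame(
                columns=["snp", "probe", "beta", "nominal_p", "permutation_p",
                         "distance_bp", "label", "reason"])
        _write_stage(outdir, "eqtl", eqtl_table)

        stage = "summary"
        summary = build_summary(study, assoc, artp_table, ihs_table,
                                gene_scan_table, eqtl_table, candidates,
                                gene_snps)
        _write_stage(outdir, "summary", summary)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    manifest = {"config": asdict(config), "n_snps": study.n_snp,
                "n_samples": study.n_samples, "n_genes": len(genes),
                "pathway_p": None if pathway_p != pathway_p else float(pathway_p)}
    if outdir is not None:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return EvidenceSummary(assoc, artp_table, float(pathway_p), ihs_table,
                           candidates, gene_scan_table, eqtl_table, summary,
                           config, manifest)


def build_summary(study, assoc, artp_table, ihs_table, gene_scan_table,
                  eqtl_table, candidates, gene_snps) -> pd.DataFrame:
    """Per-candidate-SNP evidence summary (the final report shape).

    One row per candidate locus: genotype counts (minor-allele coding),
    its own iHS, the window-scan empirical fraction of its gene, the
    association p, the gene ARTP p, and the best cis-eQTL permutation p.
    Re-running this join on the persisted stage tables reproduces the
    summary exactly (no hidden state).
    """
    snp_ids = {v.id: i for i, v in enumerate(study.variants)}
    snp_gene = {}
    for g, idx in gene_snps.items():
        for i in idx:
            snp_gene.setdefault(study.variants[i].id, g)
    artp_p = dict(zip(artp_table["gene"], artp_table["p"]))
    frac = dict(zip(gene_scan_table["gene"], gene_scan_table["empirical_fraction"]))
    cand_flag = dict(zip(gene_scan_table["gene"], gene_scan_table["candidate"]))
    rows = []
    for _, r in candidates.iterrows():
        snp = r["snp"]
        j = snp_ids[snp]
        mm, Mm, MM = _genotype_counts(study, j)
        gene = snp_gene.get(snp, "")
        cis = eqtl_table[(eqtl_table["snp"] == snp) & (eqtl_table["label"] == "cis")]
        best_cis = float(cis["permutation_p"].min()) if len(cis) else np.nan
        rows.append({
            "snp": snp, "gene": gene, "mm": mm, "Mm": Mm, "MM": MM,
            "loci_ihs": float(r["ihs"]), "gene_fraction": frac.get(gene, np.nan),
            "gene_candidate": bool(cand_flag.get(gene, False)),
            "loci_p": float(r["p"]), "gene_artp_p": artp_p.get(gene, np.nan),
            "cis_eqtl_p": best_cis,
        })
    return pd.DataFrame(rows, columns=["snp", "gene", "mm", "Mm", "MM", "loci_ihs",
                                       "gene_fraction", "gene_candidate", "loci_p",
                                       "gene_artp_p", "cis_eqtl_p"])
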