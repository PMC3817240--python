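"""Domain types, coordinate conventions and file readers/writers.

Coordinates are 1-based inclusive everywhere except BED input, which is
0-based half-open and converted on read (VCF convention dominates the
pipeline).  Haplotype matrices code 1 = derived allele; dosage matrices
count copies of the dataset's minor allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariantInfo",
    "HaplotypePanel",
    "GenotypeStudy",
    "GeneAnnotation",
    "ExpressionMatrix",
    "ProbeInfo",
    "PipelineConfig",
    "GeneticMap",
    "read_vcf",
    "write_vcf",
    "read_genetic_map",
    "attach_genetic_map",
    "read_bed_genes",
    "read_phenotype_table",
    "read_expression_table",
    "assign_snps_to_genes",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class VariantInfo:
    """One biallelic SNP.

    ``ancestral`` is ``"ref"``, ``"alt"`` or ``"unknown"``.  When the
    ancestral state had to be inferred (major allele taken as ancestral),
    ``ancestral_inferred`` is set so downstream consumers can exclude
    those sites.
    """

    id: str
    chrom: str
    pos_bp: int
    ref: str = "A"
    alt: str = "G"
    ancestral: str = "unknown"
    map_cM: float = float("nan")
    ancestral_inferred: bool = False

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"{self.id}: pos_bp must be >= 1, got {self.pos_bp}")
        if self.ancestral not in ("ref", "alt", "unknown"):
            raise ValueError(f"{self.id}: bad ancestral state {self.ancestral!r}")


@dataclass
class HaplotypePanel:
    """Phased haplotypes on one chromosome; ``H[i, j] = 1`` means haplotype
    *i* carries the derived allele at SNP *j*."""

    variants: list[VariantInfo]
    H: np.ndarray
    samples: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=np.int8)
        if self.H.ndim != 2:
            raise ValueError("H must be 2-D")
        if self.H.shape[0] % 2 != 0:
            raise ValueError("haplotype row count must be even (phased pairs)")
        if self.H.shape[1] != len(self.variants):
            raise ValueError("column count must equal number of variants")
        if not np.isin(self.H, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")
        chroms = {v.chrom for v in self.variants}
        if len(chroms) > 1:
            raise ValueError("a HaplotypePanel spans a single chromosome")

    @property
    def n_hap(self) -> int:
        return self.H.shape[0]

    @property
    def n_snp(self) -> int:
        return self.H.shape[1]

    @property
    def pos_bp(self) -> np.ndarray:
        return np.array([v.pos_bp for v in self.variants])

    @property
    def map_cM(self) -> np.ndarray:
        return np.array([v.map_cM for v in self.variants])

    def derived_freq(self) -> np.ndarray:
        return self.H.mean(axis=0)

    def to_dosage(self) -> np.ndarray:
        """Per-sample derived-allele dosage (consecutive haplotype pairs)."""
        return (self.H[0::2].astype(float) + self.H[1::2]).copy()


@dataclass
class GenotypeStudy:
    """Unphased dosage matrix plus case/control phenotype and covariates.

    ``G[i, j]`` counts copies of the dataset minor allele, ``np.nan`` for
    missing.  ``phenotype`` may be None until a phenotype table is
    attached.
    """

    variants: list[VariantInfo]
    G: np.ndarray
    samples: list[str]
    phenotype: np.ndarray | None = None
    covariates: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.shape != (len(self.samples), len(self.variants)):
            raise ValueError("G must be n_samples x n_variants")
        ok = np.isnan(self.G) | np.isin(self.G, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0/1/2 or missing")
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype, dtype=int)
            if self.phenotype.shape != (len(self.samples),):
                raise ValueError("phenotype length mismatch")
            if not np.isin(self.phenotype, (0, 1)).all():
                raise ValueError("phenotype must be 0/1")
        if self.covariates is not None and len(self.covariates) != len(self.samples):
            raise ValueError("covariate row count mismatch")

    @property
    def n_samples(self) -> int:
        return self.G.shape[0]

    @property
    def n_snp(self) -> int:
        return self.G.shape[1]

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.G).mean(axis=0)

    def maf(self) -> np.ndarray:
        f = np.nanmean(self.G, axis=0) / 2.0
        return np.minimum(f, 1.0 - f)


@dataclass
class GeneAnnotation:
    """Gene interval, 1-based inclusive, with symmetric flank extension."""

    name: str
    chrom: str
    start_bp: int
    end_bp: int
    flank_bp: int = 0

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"{self.name}: start_bp > end_bp")
        if self.flank_bp < 0:
            raise ValueError(f"{self.name}: flank_bp must be >= 0")

    @property
    def midpoint_bp(self) -> float:
        return 0.5 * (self.start_bp + self.end_bp)


@dataclass
class ProbeInfo:
    id: str
    chrom: str
    pos_bp: int


@dataclass
class ExpressionMatrix:
    """Normalized expression, probes x samples, aligned to a study by id."""

    probes: list[ProbeInfo]
    E: np.ndarray
    samples: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        if self.E.shape != (len(self.probes), len(self.samples)):
            raise ValueError("E must be n_probes x n_samples")
        if np.isnan(self.E).all(axis=1).any():
            raise ValueError("all-missing probe rows are not allowed")

    def aligned_to(self, samples: list[str]) -> "ExpressionMatrix":
        """Return a copy whose columns follow ``samples`` (by id)."""
        idx = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise ValueError(f"samples absent from expression matrix: {missing[:5]}")
        order = [idx[s] for s in samples]
        return ExpressionMatrix(self.probes, self.E[:, order], list(samples), dict(self.meta))


@dataclass
class PipelineConfig:
    """Thresholds and sizes steering the whole evidence chain."""

    assoc_alpha: float = 0.05
    ihs_suggestive: float = 1.65
    ihs_strong: float = 2.0
    window_snps: int = 50
    window_upper_fraction: float = 0.10
    cis_window_bp: int = 1_000_000
    gene_flank_bp: int = 100_000
    n_permutations: int = 10_000
    maf_min: float = 0.05
    ihs_bin_width: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.assoc_alpha < 1):
            raise ValueError("assoc_alpha must be in (0,1)")
        if not (0 < self.window_upper_fraction < 1):
            raise ValueError("window_upper_fraction must be in (0,1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.ihs_suggestive <= 0 or self.ihs_strong <= 0:
            raise ValueError("iHS thresholds must be positive")
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if self.window_snps < 1 or self.cis_window_bp < 0 or self.gene_flank_bp < 0:
            raise ValueError("window/flank sizes must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# genetic map


class GeneticMap:
    """Per-chromosome linear interpolator bp -> cM.

    Positions outside the mapped range extrapolate with the nearest
    interval's cM/bp rate.  A single-point chromosome falls back to a
    constant 1 cM/Mb (with a warning at construction).
    """

    FALLBACK_CM_PER_BP = 1e-6  # 1 cM/Mb

    def __init__(self, points: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._points = {}
        for chrom, (bp, cm) in points.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            order = np.argsort(bp)
            bp, cm = bp[order], cm[order]
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"chromosome {chrom}: cM not monotone in bp")
            if len(bp) == 1:
                warnings.warn(
                    f"chromosome {chrom}: single map point, using constant "
                    "1 cM/Mb fallback rate"
                )
            self._points[chrom] = (bp, cm)

    def cm_at(self, chrom: str, pos_bp) -> np.ndarray:
        if chrom not in self._points:
            raise KeyError(f"chromosome {chrom} not in genetic map")
        bp, cm = self._points[chrom]
        pos = np.atleast_1d(np.asarray(pos_bp, dtype=float))
        if len(bp) == 1:
            out = cm[0] + (pos - bp[0]) * self.FALLBACK_CM_PER_BP
        else:
            out = np.interp(pos, bp, cm)
            # linear extrapolation with the terminal interval's rate
            left = pos < bp[0]
            if left.any():
                rate = (cm[1] - cm[0]) / (bp[1] - bp[0])
                out[left] = cm[0] + (pos[left] - bp[0]) * rate
            right = pos > bp[-1]
            if right.any():
                rate = (cm[-1] - cm[-2]) / (bp[-1] - bp[-2])
                out[right] = cm[-1] + (pos[right] - bp[-1]) * rate
        return out if np.ndim(pos_bp) else float(out[0])


def read_genetic_map(path) -> GeneticMap:
    """Read a 4-column map (chrom, id, cM, bp); cM must be monotone per
    chromosome, checked with the offending line reported."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#",
        names=["chrom", "id", "cM", "bp"], dtype={"chrom": str},
    )
    if df.empty:
        raise ValueError(f"{path}: empty genetic map")
    points = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.reset_index()
        order = np.argsort(sub["bp"].to_numpy())
        cm = sub["cM"].to_numpy()[order]
        bad = np.nonzero(np.diff(cm) < 0)[0]
        if bad.size:
            line = int(sub["index"][order[bad[0] + 1]]) + 1
            raise ValueError(f"{path}: non-monotone cM at line {line} (chromosome {chrom})")
        points[str(chrom)] = (sub["bp"].to_numpy()[order], cm)
    return GeneticMap(points)


def attach_genetic_map(panel: HaplotypePanel, gmap: GeneticMap) -> HaplotypePanel:
    """Fill each variant's map_cM in place (and return the panel)."""
    for v in panel.variants:
        v.map_cM = float(gmap.cm_at(v.chrom, v.pos_bp))
    return panel


# ---------------------------------------------------------------------------
# VCF


def _finalize_variant(vid, chrom, pos, ref, alt, aa) -> VariantInfo:
    if aa is None:
        anc = "unknown"
    elif aa == ref:
        anc = "ref"
    elif aa == alt:
        anc = "alt"
    else:
        anc = "unknown"
    return VariantInfo(id=vid, chrom=chrom, pos_bp=pos, ref=ref, alt=alt, ancestral=anc)


def read_vcf(path, require_phased: bool = False):
    """Read a biallelic-SNP VCF.

    Phased mode returns a :class:`HaplotypePanel` (two rows per sample, in
    genome order) with 1 = derived allele; the ancestral allele comes from
    the ``AA`` INFO tag when present, otherwise the major allele is taken
    as ancestral and the variant flagged ``ancestral_inferred``.  Unphased
    mode returns a :class:`GenotypeStudy` of minor-allele dosages.
    Non-biallelic records are skipped; the count is in ``meta["n_skipped"]``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantInfo] = []
    columns = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = rec.genotypes  # [a0, a1, phased]
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if require_phased:
            col = np.empty(2 * len(samples), dtype=np.int8)
            for i, g in enumerate(gts):
                if len(g) < 3 or not g[2]:
                    raise ValueError(
                        f"{path}: unphased genotype for sample {samples[i]} "
                        f"at record {vid} but phased input required"
                    )
                if g[0] < 0 or g[1] < 0:
                    raise ValueError(f"{path}: missing allele at {vid} in phased mode")
                col[2 * i] = g[0]
                col[2 * i + 1] = g[1]
        else:
            col = np.empty(len(samples), dtype=float)
            for i, g in enumerate(gts):
                if g[0] < 0 or g[1] < 0:
                    col[i] = np.nan
                else:
                    col[i] = g[0] + g[1]
        aa = rec.INFO.get("AA")
        variants.append(_finalize_variant(vid, rec.CHROM, rec.POS, rec.REF, rec.ALT[0], aa))
        columns.append(col)
    if not variants:
        raise ValueError(f"{path}: no usable biallelic records")

    meta = {"n_skipped": n_skipped, "source": str(path)}
    if require_phased:
        H = np.column_stack(columns)  # alt-allele coding so far
        for j, v in enumerate(variants):
            if v.ancestral == "unknown":
                # fallback: major allele ancestral
                alt_freq = H[:, j].mean()
                v.ancestral = "alt" if alt_freq > 0.5 else "ref"
                v.ancestral_inferred = True
            if v.ancestral == "alt":
                H[:, j] = 1 - H[:, j]  # derived = ref allele
        return HaplotypePanel(variants, H, samples, meta)

    G = np.column_stack(columns)  # alt dosage
    for j, v in enumerate(variants):
        alt_freq = np.nanmean(G[:, j]) / 2.0
        if alt_freq > 0.5:  # minor allele is REF: recode
            G[:, j] = 2.0 - G[:, j]
    return GenotypeStudy(variants, G, samples, meta=meta)


def write_vcf(path, panel_or_study, chrom: str | None = None) -> None:
    """Write a minimal VCF 4.2 with GT (and AA INFO where known).

    For a :class:`HaplotypePanel` the derived/ancestral coding is mapped
    back to ref/alt so a read round-trips the binary matrix exactly.
    """
    obj = panel_or_study
    phased = isinstance(obj, HaplotypePanel)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted({v.chrom for v in obj.variants})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(obj.samples) + "\n")
        for j, v in enumerate(obj.variants):
            if v.ancestral == "ref":
                info = f"AA={v.ref}"
            elif v.ancestral == "alt":
                info = f"AA={v.alt}"
            else:
                info = "."
            if phased:
                col = obj.H[:, j]
                if v.ancestral == "alt":  # derived==1 means ref allele
                    col = 1 - col
                gts = "\t".join(f"{col[2*i]}|{col[2*i+1]}" for i in range(len(obj.samples)))
            else:
                vals = obj.G[:, j]
                out = []
                for x in vals:
                    if np.isnan(x):
                        out.append("./.")
                    else:
                        n = int(x)
                        out.append(["0/0", "0/1", "1/1"][n])
                gts = "\t".join(out)
            fh.write(
                f"{v.chrom}\t{v.pos_bp}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# other tabular readers


def read_bed_genes(path, flank_bp: int = 0) -> list[GeneAnnotation]:
    """Read gene intervals from BED (0-based half-open, converted to
    1-based inclusive on read)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
        dtype={"chrom": str},
    )
    return [
        GeneAnnotation(
            name=str(r.name_), chrom=str(r.chrom),
            start_bp=int(r.start) + 1, end_bp=int(r.end), flank_bp=flank_bp,
        )
        for r in df.rename(columns={"name": "name_"}).itertuples()
    ]


def read_phenotype_table(path) -> pd.DataFrame:
    """TSV with columns sample, status (0/1), age, optional extras."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = {"sample", "status", "age"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing phenotype columns {sorted(missing)}")
    if not df["status"].isin([0, 1]).all():
        raise ValueError(f"{path}: status must be 0/1")
    return df.set_index("sample")


def attach_phenotype(study: GenotypeStudy, pheno: pd.DataFrame) -> GenotypeStudy:
    """Align a phenotype table to the study's samples and attach it."""
    missing = [s for s in study.samples if s not in pheno.index]
    if missing:
        raise ValueError(f"phenotype table lacks samples: {missing[:5]}")
    sub = pheno.loc[study.samples]
    study.phenotype = sub["status"].to_numpy(dtype=int)
    study.covariates = sub.drop(columns=["status"])
    study.__post_init__()
    return study


def read_expression_table(path) -> ExpressionMatrix:
    """TSV: probe, chrom, pos, then one column per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"probe": str, "chrom": str})
    probes = [ProbeInfo(str(r.probe), str(r.chrom), int(r.pos)) for r in df.itertuples()]
    sample_cols = [c for c in df.columns if c not in ("probe", "chrom", "pos")]
    E = df[sample_cols].to_numpy(dtype=float)
    return ExpressionMatrix(probes, E, sample_cols)


def write_expression_table(path, expr: ExpressionMatrix) -> None:
    df = pd.DataFrame(expr.E, columns=expr.samples)
    df.insert(0, "pos", [p.pos_bp for p in expr.probes])
    df.insert(0, "chrom", [p.chrom for p in expr.probes])
    df.insert(0, "probe", [p.id for p in expr.probes])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene assignment


def assign_snps_to_genes(
    variants: list[VariantInfo],
    genes: list[GeneAnnotation],
    flank_bp: int | None = None,
) -> dict[str, list[int]]:
    """Map gene name -> indices of SNPs within [start-flank, end+flank],
    1-based inclusive on both boundaries.  A SNP may land in several genes.
    ``flank_bp`` overrides each gene's own flank when given."""
    out: dict[str, list[int]] = {}
    pos = np.array([v.pos_bp for v in variants])
    chrom = np.array([v.chrom for v in variants])
    for g in genes:
        f = g.flank_bp if flank_bp is None else flank_bp
        mask = (chrom == g.chrom) & (pos >= g.start_bp - f) & (pos <= g.end_bp + f)
        out[g.name] = list(np.nonzero(mask)[0])
    return out
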