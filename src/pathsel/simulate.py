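"""Synthetic genotype, phenotype and expression generators with known truth.

The haplotype generator uses a founder-mosaic copying model: a small pool
of founder haplotypes is drawn with uniform derived-allele frequencies,
and each descendant haplotype is stitched together from founder segments
of fixed SNP length, with a small per-site flip probability standing in
for mutation/genotyping error.  This produces block-wise linkage
disequilibrium — the property the haplotype statistics actually consume —
at negligible cost, without modelling demography.

A selective sweep is imposed directly: one derived-carrying haplotype at
the chosen core SNP is replicated over randomly chosen non-carriers until
the derived frequency reaches its target, each replicate picking up fresh
flips away from the core so haplotype homozygosity decays with distance,
as it does around a real partial sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .core_io import (
    ExpressionMatrix,
    GenotypeStudy,
    HaplotypePanel,
    ProbeInfo,
    VariantInfo,
)

__all__ = [
    "SimulationSpec",
    "simulate_neutral_panel",
    "simulate_sweep",
    "simulate_phenotype",
    "simulate_expression",
]


@dataclass
class SimulationSpec:
    """Ground-truth description of one synthetic study.

    Frequencies live in (0,1); ``n_haplotypes`` must be even (two per
    sample).  ``causal_snps`` maps SNP index -> per-allele log-odds;
    ``cis_pairs`` entries are (snp index, probe index, beta, noise sd).
    """

    n_haplotypes: int = 2000
    n_snps: int = 2000
    n_founders: int = 40
    mosaic_block_len: int = 20
    mutation_flip_prob: float = 0.002
    bp_spacing: int = 1500
    cm_per_mb: float = 1.0
    chrom: str = "7"
    sweep_core_index: int | None = None
    sweep_final_freq: float | None = None
    causal_snps: list[tuple[int, float]] = field(default_factory=list)
    baseline_prevalence: float = 0.5
    age_mean: float = 66.0
    age_sd: float = 8.0
    age_log_or: float = 0.03
    cis_pairs: list[tuple[int, int, float, float]] = field(default_factory=list)
    n_probes: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_haplotypes % 2 != 0:
            raise ValueError("n_haplotypes must be even")
        if not (0.0 < self.baseline_prevalence < 1.0):
            raise ValueError("baseline_prevalence must be in (0,1)")
        if not (0.0 <= self.mutation_flip_prob < 0.5):
            raise ValueError("mutation_flip_prob must be in [0, 0.5)")
        for idx, _ in self.causal_snps:
            if not (0 <= idx < self.n_snps):
                raise ValueError(f"causal SNP index {idx} out of range")
        if self.sweep_final_freq is not None and not (0 < self.sweep_final_freq < 1):
            raise ValueError("sweep_final_freq must be in (0,1)")


def _variants(spec: SimulationSpec) -> list[VariantInfo]:
    rate_cm_per_bp = spec.cm_per_mb * 1e-6
    out = []
    for j in range(spec.n_snps):
        pos = (j + 1) * spec.bp_spacing
        out.append(
            VariantInfo(
                id=f"snp{j}", chrom=spec.chrom, pos_bp=pos,
                ref="A", alt="G", ancestral="ref",
                map_cM=pos * rate_cm_per_bp,
            )
        )
    return out


def draw_founders(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Founder haplotypes: per-SNP derived frequency ~ Uniform(0.05, 0.95)."""
    freqs = rng.uniform(0.05, 0.95, size=spec.n_snps)
    return (rng.random((spec.n_founders, spec.n_snps)) < freqs).astype(np.int8)


def simulate_neutral_panel(spec: SimulationSpec) -> HaplotypePanel:
    """Mosaic-copying panel; deterministic under ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    founders = draw_founders(spec, rng)
    n, m = spec.n_haplotypes, spec.n_snps
    n_blocks = -(-m // spec.mosaic_block_len)
    # per-haplotype, per-block founder choice, expanded to SNP resolution
    choice = rng.integers(0, spec.n_founders, size=(n, n_blocks))
    block_of = np.minimum(np.arange(m) // spec.mosaic_block_len, n_blocks - 1)
    H = founders[choice[:, block_of], np.arange(m)]
    if spec.mutation_flip_prob > 0:
        flips = rng.random((n, m)) < spec.mutation_flip_prob
        H = np.where(flips, 1 - H, H)
    samples = [f"s{i}" for i in range(n // 2)]
    meta = {"founder_freq": founders.mean(axis=0), "spec_seed": spec.rng_seed}
    return HaplotypePanel(_variants(spec), H.astype(np.int8), samples, meta)


def simulate_sweep(
    panel: HaplotypePanel,
    core_index: int,
    final_freq: float,
    mutation_flip_prob: float = 0.002,
    recomb_escape_prob: float = 0.01,
    seed: int = 0,
) -> HaplotypePanel:
    """Impose a partial sweep at ``core_index`` by haplotype replication.

    One derived-carrying donor haplotype is copied over randomly chosen
    non-carriers until the derived frequency at the core reaches
    ``final_freq``.  Each copy carries the donor segment only over a
    random extent around the core — per side, the copy "escapes" back to
    its own background with probability ``recomb_escape_prob`` per SNP,
    emulating recombination breaking down the swept haplotype — and picks
    up fresh flips at ``mutation_flip_prob`` per copied site.  Both
    mechanisms make extended haplotype homozygosity (and the
    hitchhiking-induced frequency shift) decay with distance from the
    core, so the sweep's footprint stays local to the core region.
    """
    rng = np.random.default_rng(seed)
    H = panel.H.copy()
    m = H.shape[1]
    core = H[:, core_index]
    carriers = np.nonzero(core == 1)[0]
    if carriers.size == 0 or carriers.size == H.shape[0]:
        raise ValueError("core SNP must be polymorphic")
    target = int(np.ceil(final_freq * H.shape[0]))
    if target < carriers.size:
        raise ValueError(
            f"final_freq {final_freq} below current derived frequency "
            f"{carriers.size / H.shape[0]:.3f}"
        )
    donor = H[rng.choice(carriers)].copy()
    non_carriers = np.nonzero(core == 0)[0]
    n_new = target - carriers.size
    replaced = rng.choice(non_carriers, size=n_new, replace=False)
    for row in replaced:
        if recomb_escape_prob > 0:
            ext_left = int(rng.geometric(recomb_escape_prob))
            ext_right = int(rng.geometric(recomb_escape_prob))
        else:
            ext_left = ext_right = m
        lo = max(0, core_index - ext_left)
        hi = min(m, core_index + ext_right + 1)
        seg = donor[lo:hi].copy()
        if mutation_flip_prob > 0:
            flips = rng.random(hi - lo) < mutation_flip_prob
            flips[core_index - lo] = False
            seg = np.where(flips, 1 - seg, seg)
        H[row, lo:hi] = seg
    variants = [VariantInfo(**vars(v)) for v in panel.variants]
    meta = dict(panel.meta)
    meta.update({"sweep_core": core_index, "sweep_final_freq": final_freq})
    return HaplotypePanel(variants, H, list(panel.samples), meta)


def _solve_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Intercept such that mean(expit(c + eta)) == prevalence."""

    def f(c):
        return expit(c + eta).mean() - prevalence

    lo, hi = -40.0, 40.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"prevalence {prevalence} unattainable for given effects")
    return brentq(f, lo, hi, xtol=1e-10)


def simulate_phenotype(source, spec: SimulationSpec, seed: int | None = None) -> GenotypeStudy:
    """Case/control study under a logistic model with an age covariate.

    ``source`` is a :class:`HaplotypePanel` (samples = consecutive
    haplotype pairs) or an existing dosage study.  The linear predictor is
    ``intercept + sum(log_or * dosage) + age_log_or * (age - age_mean)``;
    the intercept is solved so the marginal prevalence matches
    ``spec.baseline_prevalence`` (within 0.01 by construction of the
    root-finder, to numerical precision in practice).
    """
    import pandas as pd

    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    if isinstance(source, HaplotypePanel):
        D = source.to_dosage()  # derived-allele dosage
        variants = [VariantInfo(**vars(v)) for v in source.variants]
        samples = list(source.samples)
    else:
        D = np.array(source.G, dtype=float)
        variants = [VariantInfo(**vars(v)) for v in source.variants]
        samples = list(source.samples)
    n = D.shape[0]
    age = rng.normal(spec.age_mean, spec.age_sd, size=n)
    eta = spec.age_log_or * (age - spec.age_mean)
    for idx, log_or in spec.causal_snps:
        eta = eta + log_or * D[:, idx]
    intercept = _solve_intercept(eta, spec.baseline_prevalence)
    prob = expit(intercept + eta)
    status = (rng.random(n) < prob).astype(int)
    covariates = pd.DataFrame({"age": age}, index=samples)
    # dosage matrix recoded to sample-minor-allele counts
    G = D.copy()
    for j in range(G.shape[1]):
        if np.nanmean(G[:, j]) / 2.0 > 0.5:
            G[:, j] = 2.0 - G[:, j]
    meta = {
        "causal_snps": list(spec.causal_snps),
        "intercept": intercept,
        "expected_prevalence": float(prob.mean()),
    }
    return GenotypeStudy(variants, G, samples, status, covariates, meta)


def simulate_expression(
    study: GenotypeStudy, spec: SimulationSpec, seed: int | None = None
) -> ExpressionMatrix:
    """Probe expression with designated additive cis effects.

    Paired probes follow ``beta * dosage + N(0, noise_sd)`` and are placed
    within 1 Mb of their SNP; all other probes are unit-variance noise
    placed more than 1 Mb away from every SNP.
    """
    rng = np.random.default_rng(spec.rng_seed + 1 if seed is None else seed)
    n = study.n_samples
    n_probes = max(spec.n_probes, 1 + max((p for _, p, _, _ in spec.cis_pairs), default=0))
    E = rng.normal(0.0, 1.0, size=(n_probes, n))
    max_pos = max(v.pos_bp for v in study.variants)
    probes = [
        ProbeInfo(f"probe{k}", study.variants[0].chrom, max_pos + 2_000_000 + 10_000 * (k + 1))
        for k in range(n_probes)
    ]
    truth = []
    for snp_idx, probe_idx, beta, noise_sd in spec.cis_pairs:
        v = study.variants[snp_idx]
        probes[probe_idx] = ProbeInfo(probes[probe_idx].id, v.chrom, v.pos_bp + 999_999)
        dosage = np.nan_to_num(study.G[:, snp_idx], nan=np.nanmean(study.G[:, snp_idx]))
        E[probe_idx] = beta * dosage + rng.normal(0.0, noise_sd, size=n)
        truth.append((snp_idx, probe_idx, beta, noise_sd))
    return ExpressionMatrix(probes, E, list(study.samples), {"cis_pairs": truth})
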