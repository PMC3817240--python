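# Methods

This note records the statistical models the package implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot establish.

## Association model

Each SNP is tested by logistic regression of case status on additive
minor-allele dosage plus covariates (age by default):
logit P(case) = β₀ + β·g + γ·age.  The fit is iteratively reweighted
least squares, converged when the relative log-likelihood change drops
below 1e-8 (max 50 iterations).  Significance is the two-sided Wald test
z = β̂/SE; the 95% CI is exp(β̂ ± 1.959964·SE).  Additive coding is used
throughout because it is the default of the standard GWAS tooling this
module mirrors, and no alternative genetic model is assumed anywhere in
the chain.  Missing genotypes are handled pairwise-complete: the sample
is dropped for that SNP only, never imputed.  Monomorphic SNPs, SNPs
with fewer than 10 cases or 10 controls among complete observations,
non-converged fits and separated fits (|β̂| > 10) are returned as flagged
records with missing p, not errors, so a scan never aborts on a bad
column.  The threshold convention is strict: "significant at 0.05" means
p < 0.05.

`wald_p_from_or_ci` inverts a printed OR and 95% CI back to the Wald p
via SE = (ln U95 − ln L95)/(2·1.959964).  This is used to verify
published association tables from their own rounding; agreement is
limited by the precision of the printed inputs (the packaged reference
rows reproduce their printed P to well under 1% relative error).

## ARTP gene and pathway test

Per-SNP evidence is combined with the adaptive rank truncated product.
For a gene with per-SNP p-values p₁…p_L and truncation grid K (default
{1,2,3,4,5,10,15,20} capped at L — the conventional software default
family, recorded in the diagnostics since grids are rarely reported):

1. W_b(k) = product of the k smallest p-values of replicate b (log-space
   to avoid underflow), for every replicate b = 0…B (b = 0 observed).
2. p̂_b(k) = #{b′ : W_{b′}(k) ≤ W_b(k)}/(B+1), ties counted on the "≤"
   side (conservative).
3. MinP_b = min_k p̂_b(k); gene p = (1 + #{b ≥ 1 : MinP_b ≤ MinP₀})/(B+1).

This is the single-permutation-layer adjustment: the same ensemble that
estimates each p̂(k) also calibrates the minimum, so no nested resampling
is needed.  The pathway level repeats steps 2–3 with genes in place of
truncated products: each gene's MinP_b column is rank-adjusted into a
per-replicate gene-level p, and the identical layer runs over genes.  All
ensembles share the same phenotype permutations, which keeps gene-level
evidence exchangeable; covariates stay attached to their samples and
only case/control labels are permuted (how covariates behave under
permutation is never stated in the analyses this mirrors, so the simple
label permutation is used and documented).

Inside the ensemble the per-SNP statistic is the efficient score test
against the covariate-only null (one batched Newton fit per replicate,
vectorized across replicates and SNPs).  A full Wald refit per replicate
is available via `method="wald"`; the score route is the default because
ten thousand permutations times thousands of SNPs must run at desk
scale, and the layer only consumes ranks of the statistic within the
ensemble.  For tiny samples the ensemble can be exhaustive
(`B="exhaustive"` enumerates every distinct case assignment), which the
tests compare against brute-force enumeration.

Published workflows sometimes pre-filter to SNPs with observed p < 0.05
before running ARTP.  That filter uses the observed data and biases the
permutation null; it is available as `run_pipeline(prefilter_alpha=...)`
but off by default.

Permutation p-values are floored at 1/(B+1) by construction; no zero
p-value can occur anywhere in the package.

## EHH, iHH and iHS

EHH at distance x from a core SNP is the probability that two random
haplotypes carrying the same core allele are identical over the whole
interval from the core to x.  It is computed by incremental partition
refinement — extending one SNP at a time and splitting carrier groups —
which the tests verify against an explicit all-pairs comparison.  iHH is
the trapezoid integral of EHH over genetic distance (centimorgans, from
the interpolated map — never physical distance), computed separately for
ancestral and derived carriers.  Numerical conventions:

- Each direction integrates up to and including the first point where
  EHH < 0.05 (the customary floor).  If the panel edge arrives first the
  SNP is excluded from the scan as "truncated" rather than scored with a
  biased integral.
- uiHS = ln(iHH_A/iHH_D); negative values mean long derived haplotypes.
- Standardization is within derived-allele-frequency bins of width 0.05;
  bins with fewer than 10 scored SNPs are merged into their lower
  neighbor (upward at the left edge) with a warning.
- Core SNPs need MAF > 0.05 (strict) and a resolved ancestral state.
  When the VCF lacks an AA tag the major allele is taken as ancestral
  and the variant flagged `ancestral_inferred`, so consumers can exclude
  inferred sites.
- Both tails count as signal; candidate rules use |iHS|.

The gene-window caller takes, per gene, the scored SNP nearest the gene
midpoint ("nearest to the midpoint" resolves an ambiguity in how the
index SNP is chosen; the alternative anchor is configurable), a window
of 50 scored SNPs centered there (clipped and flagged "short" at panel
edges), and counts window SNPs with |iHS| above the strong threshold
(2.0).  The count is referred to the distribution of all genome-wide
sliding 50-SNP windows; a gene is a candidate when its count reaches the
upper-10% quantile of that distribution *and* is nonzero (an all-zero
genome must produce no candidates).  The reported per-gene value is the
fraction of windows with a count at least as large — an empirical
exceedance fraction, labeled as such.

## eQTL scan

OLS of normalized expression on dosage with a two-sided t-test on the
slope; empirical significance permutes the expression vector B times,
p = (1 + #{|t_perm| ≥ |t_obs|})/(B+1).  Expression (not genotype) is
permuted — the standard choice for per-pair tests.  Pairs are cis when
SNP and probe share a chromosome within 1 Mb, boundary inclusive.
Testability requires ≥3 distinct dosage values, or 2 with n ≥ 10;
constant dosage or expression is reported as a skipped pair.  No
covariate or latent-factor correction is applied to expression — the
generator produces pre-normalized values, and such pipelines are out of
scope.

## Pipeline

`run_pipeline` chains association → ARTP → iHS scan → candidate join
(p < 0.05 and |iHS| > 1.65) → gene-window scan → eQTL on surviving loci
→ per-locus evidence summary.  Every stage's table is persisted; the
summary is a pure join of those tables (asserted by an idempotence
test), and re-running with the same config and seed produces
byte-identical outputs.  Multiple-testing stance mirrors the
raw-threshold workflow (0.05 / 1.65 / 2 / upper-10%) deliberately;
consumers wanting FDR control can apply it to the persisted per-stage
tables.  Stage failures abort with the stage name; previously persisted
stages remain on disk.

## Synthetic data: what it emulates, and what it does not

The generator exists so each stage has planted truth at desk scale.

- **Haplotypes**: a founder-mosaic model — 40 founders with per-SNP
  derived frequencies ~ Uniform(0.05, 0.95), descendants copying
  founder segments in 20-SNP blocks with a 0.002 per-site flip rate,
  1.5 kb SNP spacing, constant 1 cM/Mb map.  This produces block-wise LD
  (what EHH/iHS consume) at negligible cost.  It does *not* model
  demography, recombination-rate heterogeneity or realistic allele
  frequency spectra, so absolute iHH magnitudes are not comparable to
  human data; only the internal calibration (per-bin mean 0, sd 1, ≈5%
  beyond |1.96|) carries over.
- **Sweep**: a donor haplotype carrying the derived core allele is
  replicated over random non-carriers until the target core frequency.
  Each copy keeps the donor segment only over a geometric random extent
  per side (escape probability 0.01/SNP, emulating recombination onto
  other backgrounds) and picks up fresh flips inside the segment.  Both
  the homozygosity excess and the hitchhiking frequency shift therefore
  decay with distance, keeping the footprint local — necessary because
  the panel itself is the "genome" against which iHS is standardized.
  A full-haplotype replication (no escape) instead distorts every SNP on
  the panel and suppresses the standardized signal.
- **Phenotype**: logit-linear in dosage with an age covariate at a fixed
  small coefficient (0.03 per year — non-trivial but not confounding,
  since age is generated independently of genotype); the intercept is
  solved by root-finding so expected prevalence matches the target
  (default 0.5, the case fraction of a balanced case-control design).
- **Expression**: designated pairs follow β·dosage + N(0, σ); paired
  probes are placed 999,999 bp from their SNP (inside the cis window),
  all other probes are unit noise placed beyond it.

One property worth knowing: within-panel standardization means a
*stronger* sweep (higher final frequency) contaminates its own frequency
bin more, inflating the bin sd and *lowering* standardized |iHS| even as
the physical signal |ln(iHH_A/iHH_D)| grows.  The monotone-response test
therefore asserts monotonicity of the unstandardized score; the
standardized score is asserted only to exceed the detection thresholds.
On genome-scale data, where any sweep is a vanishing fraction of the
standardization set, this artifact is negligible.

## Problem sizes used by the tests

Calibration and power checks run at: 2000 haplotypes × 2000 SNPs for the
neutral iHS calibration and sweep control; 500 genes × B = 200
permutations for the ARTP type-I error; n = 5000 × 200 replicates for CI
coverage; n = 100, B = 999, 50 replicates for eQTL power; 2000 × 1000
for the end-to-end planted run.  These sizes were chosen to make the
binomial/KS tolerances meaningful while keeping the default suite
comfortably runnable on a laptop.

## Known limitations

- Multi-allelic variants are skipped on read; no liftover, no
  imputation, no X-chromosome special-casing.
- The ARTP engine mean-imputes missing dosages inside the permutation
  ensemble (association fits drop them pairwise); with substantial
  missingness the two routes can diverge.
- Cross-population replication is modeled as independent runs over
  multiple expression matrices; no meta-analysis is performed.
- The iHS empirical thresholds (1.65, 2) are conventions, not calibrated
  error rates; the gene-window "upper 10%" is likewise an empirical
  rule, and its exceedance fractions are not p-values.
- One source-table inconsistency is preserved verbatim in the packaged
  reference data: one row prints |iHS| = 1.647 in a table whose caption
  states the 1.65 threshold, and the same source counts "26" loci where
  its table lists 27 rows.  The fixtures transcribe the table; the tests
  document the exceptions rather than correct them.
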