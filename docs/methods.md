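# Methods

This note documents the models, the numerical choices, and what the
simulation harness does and does not emulate.

## Preprocessing

Abundance counts are compositional: only relative information is
meaningful. Counts are converted to per-sample proportions, zeros are
replaced, and the centered log-ratio (CLR) transform is applied
(`skbio.stats.composition.clr`). Zero replacement defaults to the
multiplicative scheme with a count-equivalent mass δ = 0.5 (half a count):
in a row with total n and z zeros, each zero becomes δ/n and the nonzero
proportions are shrunk by 1 − zδ/n, preserving the unit sum. A plain
pseudocount is available. Because δ is a count mass, CLR after replacement
is exactly scale-invariant only for zero-free rows; rows with zeros are
invariant up to the (vanishing) replacement mass. Rows of all zeros are
rejected with the offending sample named.

Genotypes must be complete dosage matrices in {0,1,2}; missing-value
imputation is deliberately out of scope. SNPs are filtered at minor-allele
frequency 0.03 by default (constant columns always go), matching common
association-study practice; near-monomorphic SNPs make r² estimates
unstable.

## Clustering

**Genome.** Dissimilarity is 1 − r², with r the Pearson correlation of
dosage columns (composite LD — phase is not observed). Clustering is
Ward's incremental sum-of-squares restricted to genomically adjacent
cluster pairs, via the Lance–Williams update on the dissimilarity matrix.
Every internal node therefore spans a contiguous SNP interval. Constrained
merging can invert heights; monotone heights are enforced by running
maximum, which the persistence gaps below require. Cost ties break toward
the smaller starting index (determinism). The implementation is a clean
O(D²); no installed package provides adjacency-constrained Ward.

**Metagenome.** Plain Ward linkage (scipy) on Euclidean distances between
taxon columns. The pipeline standardizes columns first (mean 0, unit
variance), making squared distances proportional to 1 − r: the taxon group
structure of interest is a correlation structure, and raw CLR columns
differ mostly by baseline abundance, which would otherwise dominate the
distances. Raw-column clustering remains available
(`ward_tree(..., standardize=False)`, the default of the low-level
function).

**Gap statistic.** An optional chooser of a flat group count over tree
cuts, following Tibshirani's prescription with uniform reference draws
over the data's bounding box; used only where a fixed partition is needed
(it plays no role in the main pipeline, which never cuts the tree).

## Catalog, weights, compression

All 2D − 1 tree nodes become candidate groups. A group is created by the
merge that forms it (leaves at height 0) and destroyed by the merge that
absorbs it; its persistence gap is s = h_destroy − h_create and its Lasso
penalty factor ρ = 1/√s. The paper-level description of the gap is
per-level; persistence realizes the same intent — groups bracketed by
large jumps in the hierarchy get small penalties — and is well defined for
groups spanning several levels. The root is retained with s equal to the
final jump. Groups with s = 0 (tied merges, e.g. duplicated columns) have
infinite penalty and are dropped by default; a capped-weight policy
(ρ = 1/√(1e-8·h_max)) is the alternative.

Compression is the member mean by default; median and first principal
component (sign fixed so the largest-magnitude loading is positive;
singletons return the standardized column) are options. An optional
search-space restriction keeps the `max_groups` largest-gap groups (ties:
larger group, then smaller start index); since the expanded catalog has
only 2D − 1 < 5D groups, the default is no restriction.

## Selection

Each view is screened independently against the shared phenotype. The
weighted Lasso min_β Σ(yᵢ − x̃ᵢβ)² + λ Σ ρ_g|β_g| is solved exactly by
rescaling column g by 1/ρ_g, solving a plain Lasso, and rescaling back
(scikit-learn's coordinate descent; α = λ/2N maps between objective
conventions).

Stability selection is the default: B subsamples of ⌊N/2⌋ without
replacement; per subsample the LARS path of the standardized, rescaled
design runs until q variables have entered, with
q = ⌊√(PFER·(2·cutoff − 1)·p)⌋ from the Meinshausen–Bühlmann bound
E[false selections] ≤ q²/((2·cutoff − 1)p); groups with selection
frequency ≥ cutoff are kept. Defaults per view: genome B = 100,
cutoff = 0.6, PFER = 10; metagenome B = 300, cutoff = 0.7, PFER = 1.
Subsample r draws from seed + r, so runs are reproducible.

With stability off, a single weighted Lasso is fitted at a k-fold
cross-validated penalty chosen by the one-standard-error rule (the largest
penalty within one SE of the CV minimum). The 1-SE rule is used rather
than the CV minimum because the minimum systematically overselects under
pure noise, which defeats the screening purpose of this step.

Reported coefficients come from a least-squares refit of the selected
groups on the original scale; frequencies and the selected flag are the
primary output.

## Interaction testing

Every selected-G × selected-M pair is fitted by OLS on
(1, x̃ᵍ, x̃ᵐ, x̃ᵍ·x̃ᵐ) and θ is tested two-sided on N − 4 df. An intercept is
always included — phenotypes are not assumed centered, and omitting it
would bias θ. Rank-deficient designs (e.g. proportional supervariables)
are flagged untestable and excluded from the multiplicity count.
Correction is Holm by default (simulation setting; FWER), Benjamini–
Hochberg optionally (application setting; FDR). Strong hierarchy holds by
construction: an interaction can only be reported between groups whose
main effects were selected and are in the tested model.

In by-chromosome mode the genome view is clustered and selected per
chromosome, all selected genomic groups are pooled, and a single
correction is applied across all pooled pairs — correction after pooling
keeps the family-wise guarantee over the whole genome.

## Simulation harness

**Genotypes.** Two latent haplotypes per sample are drawn from a
block-diagonal equicorrelated Gaussian (default 16 near-equal blocks over
D_G = 200 SNPs, within-block correlation 0.9 — the canonical value of the
generator's fidelity check); allele j is the indicator latent < Φ⁻¹(MAF_j)
with MAF ~ U(0.1, 0.5); dosage is the haplotype sum. This reproduces the
property the method exploits — contiguous LD blocks along the chromosome —
without external haplotype panels. It does not emulate recombination
hotspots, allele-frequency spectra, or inter-block LD decay of real
genomes.

**Metagenome.** Counts are multivariate Poisson log-normal: Z ~ N(0, Σ)
with Σ block-diagonal, unit variances and within-group correlations drawn
from U(0.5, 0.95) over 6 groups (D_M = 100 taxa);
X_ij ~ Poisson(exp(μ_j + Z_ij)) with μ_j ~ U(log 10, log 100), giving
realistic per-taxon count scales of tens to hundreds. Overdispersion and
positive within-group correlation match real abundance tables; sparsity
(structural zeros), taxonomic tree structure and cross-group correlations
are not emulated.

**Phenotype.** I causal (g, m) pairs are drawn from the generating
partitions (LD blocks × latent groups) — the truth is defined at
generation time, never from an estimated catalog. Pairs are disjoint in
both coordinates while possible; when I exceeds the maximum matching,
extra distinct pairs reuse groups. Every involved group receives a main
effect; all coefficients have magnitude 1 with random signs (magnitudes
are otherwise unidentified in the design); noise is N(0, sd²). The
variable-level truth Δ is the union of members(g) × members(m) blocks.

**Study grid.** Defaults are the full design: N ∈ {50, 100, 200} ×
sd ∈ {0.5, 1, 2} × I ∈ {1, 3, 5, 7, 10}, 30 replicates, with the
gap-weighted (ρ = 1/√s) and unit-weighted (ρ = 1) schemes fitted on the
same datasets and shared trees. Evaluation is at the variable level; an
empty estimate against nonempty truth reports precision as missing (0/0),
not 0, so study averages are not silently deflated. The acceptance script
and tests run a single cell (N = 200, sd = 0.5, I = 3, 10 replicates) —
the regime's easiest corner — which completes in under a minute while
exercising the full pipeline at study scale.

What passing the simulation checks shows: the pipeline recovers planted
block-level interactions and the weighting scheme matters (gap ≫ unit
weights on recall). What it does not show: performance under real LD
decay, compositional sparsity, confounding population structure, or
model misspecification of the phenotype.

## Numerical details and edge cases

- Heights are compared with running-maximum monotonicity; persistence gaps
  are clipped at 0 and negative gaps raise (they indicate an upstream bug).
- Lasso tolerances: coordinate descent tol 1e-10, max_iter 50k; LARS paths
  are capped at max(2q, q+10) steps.
- λ = 0 falls back to least squares; λ ≥ 2·max|x̃ᵀy|/ρ gives the exact null
  solution.
- Degenerate interaction designs return untestable records rather than
  p-values; empty selections yield an empty result table and a success
  exit.
- All stochastic operations take explicit integer seeds; derived seeds use
  `numpy.random.SeedSequence` and stay below 2³¹.

## Known limitations

- The constrained clustering is O(D²) per chromosome; millions of SNPs
  require the by-chromosome mode and patience, not this implementation's
  ambition.
- Precision of the group-level method is intrinsically limited: a
  significant pair slightly "too high" in a tree covers extra variable
  pairs, which the variable-level confusion matrix counts as false
  positives.
- Stability-selection frequencies can split across nested, highly
  correlated groups; the gap weighting mitigates but does not eliminate
  this.
- The t-tests condition on selection; no post-selection correction is
  applied (the multiplicity correction covers the tested family only).
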