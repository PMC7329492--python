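"""Compositional transformation of abundance counts and genotype filtering.

Metagenomic abundances are compositional: only relative information is
meaningful, and raw proportions carry a negative-correlation bias. The
standard remedy is the centered log-ratio (CLR) transform, which requires
strictly positive proportions — zero counts must be replaced first.
Genotypes are filtered on minor-allele frequency (MAF) before clustering,
since near-constant dosage columns make LD estimates unstable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skbio.stats.composition import clr as _skbio_clr


@dataclass
class AbundanceMatrix:
    """Nonnegative integer counts, samples x taxa."""

    values: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("abundance values must be a 2-d matrix")
        if np.any(self.values < 0):
            raise ValueError("abundance counts must be nonnegative")
        if not np.allclose(self.values, np.round(self.values)):
            raise ValueError("abundance counts must be integers")
        n, d = self.values.shape
        if len(self.sample_ids) != n or len(self.taxon_ids) != d:
            raise ValueError("id lengths do not match matrix shape")
        zero_rows = np.flatnonzero(self.values.sum(axis=1) == 0)
        if zero_rows.size:
            raise ValueError(
                f"sample(s) {[self.sample_ids[i] for i in zero_rows]} have all-zero counts"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]


@dataclass
class CompositionMatrix:
    """CLR coordinates, samples x taxa; each row sums to zero."""

    values: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CLR values must be finite")
        tol = 1e-9 * self.values.shape[1]
        if np.any(np.abs(self.values.sum(axis=1)) > tol):
            raise ValueError("CLR rows must sum to zero")


@dataclass
class GenotypeMatrix:
    """SNP dosages in {0,1,2}, samples x SNPs, columns ordered by position."""

    values: np.ndarray
    positions: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str] | None = None
    chromosomes: np.ndarray | None = None  # per-SNP labels; None = single chromosome

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.positions = np.asarray(self.positions)
        if np.any(np.isnan(self.values.astype(float))):
            raise ValueError("genotype matrix contains missing values; imputation is out of scope")
        if not np.isin(self.values, [0, 1, 2]).all():
            raise ValueError("genotype dosages must be in {0, 1, 2}")
        if self.chromosomes is None:
            if np.any(np.diff(self.positions) < 0):
                raise ValueError("SNP positions must be nondecreasing")
        else:
            self.chromosomes = np.asarray(self.chromosomes)
            decreasing = np.diff(self.positions) < 0
            same_chrom = self.chromosomes[1:] == self.chromosomes[:-1]
            if np.any(decreasing & same_chrom):
                raise ValueError("SNP positions must be nondecreasing within a chromosome")
        if len(self.snp_ids) != self.values.shape[1]:
            raise ValueError("snp_ids length does not match matrix")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency f = mean(dosage)/2 per SNP."""
        return self.values.mean(axis=0) / 2.0


def replace_zeros(
    counts: AbundanceMatrix, method: str = "multiplicative", delta: float = 0.5
) -> np.ndarray:
    """Convert counts to strictly positive proportions, replacing zeros.

    Parameters
    ----------
    counts :
        Validated abundance matrix.
    method :
        ``"multiplicative"`` — each zero in a row with total ``n_tot`` becomes
        ``delta / n_tot`` and the nonzero proportions are shrunk by the factor
        ``1 - z * delta / n_tot`` (``z`` zeros in the row), preserving the unit
        row sum. ``"pseudocount"`` — add ``delta`` to every count, renormalize.
    delta :
        Count-equivalent replacement mass (default 0.5, half a count).

    Returns
    -------
    Row-stochastic matrix with all entries strictly positive.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    x = counts.values.astype(float)
    totals = x.sum(axis=1, keepdims=True)
    if method == "pseudocount":
        x = x + delta
        return x / x.sum(axis=1, keepdims=True)
    if method != "multiplicative":
        raise ValueError(f"unknown zero-replacement method {method!r}")
    p = x / totals
    zeros = x == 0
    z = zeros.sum(axis=1, keepdims=True)
    repl = delta / totals
    if np.any(z * repl >= 1):
        bad = int(np.argmax((z * repl >= 1).ravel()))
        raise ValueError(
            f"sample {counts.sample_ids[bad]!r}: replacement mass exceeds total; lower delta"
        )
    out = np.where(zeros, repl, p * (1.0 - z * repl))
    return out


def clr_transform(
    proportions: np.ndarray,
    sample_ids: list[str] | None = None,
    taxon_ids: list[str] | None = None,
    provenance: dict | None = None,
) -> CompositionMatrix:
    """Centered log-ratio transform of strictly positive compositions.

    Each row becomes ``log(p_j) - mean_j log(p_j)``; rows of the result sum
    to zero, mapping the simplex to unconstrained coordinates.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p <= 0):
        raise ValueError("nonpositive entries: call replace_zeros before clr_transform")
    vals = _skbio_clr(p)
    n, d = p.shape
    return CompositionMatrix(
        values=vals,
        sample_ids=sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)],
        taxon_ids=taxon_ids if taxon_ids is not None else [f"t{j}" for j in range(d)],
        provenance=provenance or {},
    )


def clr_from_counts(
    counts: AbundanceMatrix, method: str = "multiplicative", delta: float = 0.5
) -> CompositionMatrix:
    """Counts -> proportions with zero replacement -> CLR, in one call."""
    props = replace_zeros(counts, method=method, delta=delta)
    return clr_transform(
        props,
        sample_ids=counts.sample_ids,
        taxon_ids=counts.taxon_ids,
        provenance={"zero_replacement": method, "delta": delta},
    )


def maf_filter(geno: GenotypeMatrix, threshold: float = 0.03) -> GenotypeMatrix:
    """Drop SNPs with minor-allele frequency below ``threshold``.

    MAF is ``min(f, 1-f)`` with ``f = mean(dosage)/2``. Constant columns
    (MAF 0) are always dropped, even at threshold 0. Column order is
    preserved.
    """
    if not 0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    f = geno.allele_frequencies()
    maf = np.minimum(f, 1.0 - f)
    keep = (maf >= threshold) & (geno.values.std(axis=0) > 0)
    if not keep.any():
        warnings.warn("MAF filter removed every SNP", stacklevel=2)
    return GenotypeMatrix(
        values=geno.values[:, keep],
        positions=geno.positions[keep],
        snp_ids=[s for s, k in zip(geno.snp_ids, keep) if k],
        sample_ids=geno.sample_ids,
        chromosomes=None if geno.chromosomes is None else geno.chromosomes[keep],
    )
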