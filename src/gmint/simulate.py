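"""Synthetic data generators defining the simulation study conditions.

Three generators emulate the study inputs:

* genotypes — a thresholded-Gaussian haplotype model producing contiguous
  LD blocks: each haplotype's latent vector is equicorrelated within a
  block, alleles are the indicator of the latent value falling below the
  allele-frequency quantile, and dosage is the sum of two independent
  haplotypes;
* metagenome counts — a multivariate Poisson log-normal with block-diagonal
  latent covariance, within-group latent correlations drawn from
  [0.5, 0.95] over 6 groups;
* phenotype — a linear model on the generating-partition supervariables
  with I interacting (g, m) pairs, unit-magnitude coefficients with random
  signs, and Gaussian noise.

The generating partitions (LD blocks, latent groups) define the truth;
the estimated catalogs never see them.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .evaluate import precision_recall
from .hierarchy import Group, GroupCatalog, SuperVariableMatrix, compress_groups
from .preprocess import AbundanceMatrix, CompositionMatrix, GenotypeMatrix, clr_from_counts


def _near_equal_blocks(total: int, n_blocks: int) -> list[int]:
    base, extra = divmod(total, n_blocks)
    return [base + (1 if b < extra else 0) for b in range(n_blocks)]


@dataclass
class GenoSimConfig:
    n_samples: int = 200
    n_snps: int = 200
    block_sizes: list[int] | None = None  # default: 16 near-equal LD blocks
    within_block_corr: float = 0.9
    maf_range: tuple[float, float] = (0.1, 0.5)
    seed: int = 0
    n_blocks: int = 16

    def __post_init__(self) -> None:
        if self.block_sizes is None:
            self.block_sizes = _near_equal_blocks(self.n_snps, self.n_blocks)
        if sum(self.block_sizes) != self.n_snps:
            raise ValueError("block sizes must sum to n_snps")
        if not 0 <= self.within_block_corr < 1:
            raise ValueError("within_block_corr must lie in [0, 1)")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must lie in (0, 0.5]")

    @property
    def block_labels(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.block_sizes)), self.block_sizes)


@dataclass
class PLNConfig:
    n_samples: int = 200
    n_taxa: int = 100
    n_groups: int = 6
    rho_range: tuple[float, float] = (0.5, 0.95)
    mu_range: tuple[float, float] = (np.log(10.0), np.log(100.0))
    mu: np.ndarray | None = None
    group_sizes: list[int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.rho_range
        if not 0 < lo <= hi < 1:
            raise ValueError("rho_range must lie inside (0, 1)")
        if self.group_sizes is None:
            self.group_sizes = _near_equal_blocks(self.n_taxa, self.n_groups)
        if sum(self.group_sizes) != self.n_taxa:
            raise ValueError("group sizes must sum to n_taxa")

    @property
    def group_labels(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.group_sizes)), self.group_sizes)


@dataclass
class SimulationTruth:
    """Generating structure of one phenotype draw."""

    pairs: list[tuple[int, int]]  # causal (g, m) group pairs
    S_G: list[int]
    S_M: list[int]
    beta_G: dict[int, float]
    beta_M: dict[int, float]
    theta: dict[tuple[int, int], float]
    Delta_true: np.ndarray  # D_G x D_M binary, variable level
    sd_eps: float
    I: int

    def __post_init__(self) -> None:
        if len(self.pairs) != self.I:
            raise ValueError("number of causal pairs must equal I")


def _block_equicorrelated_normal(
    rng: np.random.Generator, n: int, labels: np.ndarray, corrs: np.ndarray
) -> np.ndarray:
    """Draws N(0, Sigma) rows, Sigma block-diagonal equicorrelated, unit var."""
    d = labels.size
    z = np.empty((n, d))
    for b in np.unique(labels):
        idx = labels == b
        rho = corrs[b]
        shared = rng.standard_normal((n, 1))
        noise = rng.standard_normal((n, int(idx.sum())))
        z[:, idx] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
    return z


def simulate_genotypes(cfg: GenoSimConfig) -> GenotypeMatrix:
    """Block-LD dosage matrix from the thresholded-Gaussian haplotype model."""
    rng = np.random.default_rng(cfg.seed)
    labels = cfg.block_labels
    mafs = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    thresholds = stats.norm.ppf(mafs)
    corrs = np.full(len(cfg.block_sizes), cfg.within_block_corr)
    dosage = np.zeros((cfg.n_samples, cfg.n_snps), dtype=np.int64)
    for _hap in range(2):
        latent = _block_equicorrelated_normal(rng, cfg.n_samples, labels, corrs)
        dosage += (latent < thresholds).astype(np.int64)
    return GenotypeMatrix(
        values=dosage,
        positions=np.arange(1, cfg.n_snps + 1) * 1000,
        snp_ids=[f"snp{j:04d}" for j in range(cfg.n_snps)],
        sample_ids=[f"s{i:04d}" for i in range(cfg.n_samples)],
    )


def simulate_metagenome(
    cfg: PLNConfig, return_params: bool = False
) -> AbundanceMatrix | tuple[AbundanceMatrix, dict]:
    """Poisson log-normal counts with block-correlated latent layer."""
    rng = np.random.default_rng(cfg.seed)
    labels = cfg.group_labels
    corrs = rng.uniform(*cfg.rho_range, size=len(cfg.group_sizes))
    mu = cfg.mu if cfg.mu is not None else rng.uniform(*cfg.mu_range, size=cfg.n_taxa)
    mu = np.asarray(mu, dtype=float)
    z = _block_equicorrelated_normal(rng, cfg.n_samples, labels, corrs)
    counts = rng.poisson(np.exp(mu + z))
    abund = AbundanceMatrix(
        values=counts,
        sample_ids=[f"s{i:04d}" for i in range(cfg.n_samples)],
        taxon_ids=[f"taxon{j:03d}" for j in range(cfg.n_taxa)],
    )
    if return_params:
        return abund, {"mu": mu, "group_corrs": corrs, "group_labels": labels}
    return abund


def partition_catalog(labels: np.ndarray, view: str) -> GroupCatalog:
    """Catalog of a flat partition (one group per label), unit heights."""
    labels = np.asarray(labels)
    groups = []
    for k, b in enumerate(np.unique(labels)):
        members = tuple(int(i) for i in np.flatnonzero(labels == b))
        g = Group(members=members, h_create=0.0, h_destroy=1.0, node_id=k)
        g.rho = 1.0
        groups.append(g)
    return GroupCatalog(groups=groups, view=view, n_variables=labels.size)


def generating_supervariables(
    geno: GenotypeMatrix, comp: CompositionMatrix, geno_labels: np.ndarray, meta_labels: np.ndarray
) -> tuple[SuperVariableMatrix, SuperVariableMatrix]:
    """Mean supervariables over the generating partitions of both views."""
    catG = partition_catalog(geno_labels, "G")
    catM = partition_catalog(meta_labels, "M")
    svG = compress_groups(geno.values.astype(float), catG, fn="mean")
    svM = compress_groups(comp.values, catM, fn="mean")
    return svG, svM


def _draw_pairs(rng: np.random.Generator, n_g: int, n_m: int, I: int) -> list[tuple[int, int]]:
    """I distinct (g, m) pairs, disjoint in both coordinates while possible."""
    if I > n_g * n_m:
        raise ValueError(f"cannot draw {I} distinct pairs from {n_g}x{n_m} groups")
    gs = rng.permutation(n_g)
    ms = rng.permutation(n_m)
    pairs = [(int(g), int(m)) for g, m in zip(gs, ms)][: min(I, n_g, n_m)]
    if len(pairs) < I:
        taken = set(pairs)
        all_pairs = [(g, m) for g in range(n_g) for m in range(n_m) if (g, m) not in taken]
        extra_idx = rng.choice(len(all_pairs), size=I - len(pairs), replace=False)
        pairs += [all_pairs[i] for i in sorted(int(i) for i in extra_idx)]
    return pairs


def simulate_phenotype(
    svG: SuperVariableMatrix,
    svM: SuperVariableMatrix,
    I: int,
    sd_eps: float,
    coef_scheme: str = "unit_signs",
    seed: int = 0,
) -> tuple[np.ndarray, SimulationTruth]:
    """Phenotype from main effects plus I supervariable interactions.

    Every group involved in a causal pair also receives a nonzero main
    effect, so the generated signal satisfies strong dependency. Under
    ``coef_scheme="unit_signs"`` all coefficients have magnitude 1 with
    random signs.
    """
    if sd_eps < 0:
        raise ValueError("noise sd must be nonnegative")
    if coef_scheme != "unit_signs":
        raise ValueError(f"unknown coefficient scheme {coef_scheme!r}")
    rng = np.random.default_rng(seed)
    n_g, n_m = svG.values.shape[1], svM.values.shape[1]
    pairs = _draw_pairs(rng, n_g, n_m, I) if I > 0 else []
    S_G = sorted({g for g, _ in pairs})
    S_M = sorted({m for _, m in pairs})
    sign = lambda: float(rng.choice([-1.0, 1.0]))  # noqa: E731
    beta_G = {g: sign() for g in S_G}
    beta_M = {m: sign() for m in S_M}
    theta = {(g, m): sign() for g, m in pairs}
    n = svG.values.shape[0]
    y = np.zeros(n)
    for g, b in beta_G.items():
        y += b * svG.values[:, g]
    for m, b in beta_M.items():
        y += b * svM.values[:, m]
    for (g, m), t in theta.items():
        y += t * svG.values[:, g] * svM.values[:, m]
    y = y + rng.normal(0.0, sd_eps, size=n)
    d_G, d_M = svG.catalog.n_variables, svM.catalog.n_variables
    delta = np.zeros((d_G, d_M), dtype=bool)
    for g, m in pairs:
        gi = list(svG.catalog.groups[g].members)
        mi = list(svM.catalog.groups[m].members)
        delta[np.ix_(gi, mi)] = True
    truth = SimulationTruth(
        pairs=pairs, S_G=S_G, S_M=S_M, beta_G=beta_G, beta_M=beta_M,
        theta=theta, Delta_true=delta, sd_eps=sd_eps, I=I,
    )
    return y, truth


@dataclass
class Dataset:
    geno: GenotypeMatrix
    abund: AbundanceMatrix
    comp: CompositionMatrix
    y: np.ndarray
    truth: SimulationTruth
    geno_labels: np.ndarray
    meta_labels: np.ndarray


def generate_dataset(
    n_samples: int = 200,
    d_G: int = 200,
    d_M: int = 100,
    I: int = 3,
    sd_eps: float = 0.5,
    seed: int = 0,
    geno_cfg: GenoSimConfig | None = None,
    pln_cfg: PLNConfig | None = None,
) -> Dataset:
    """One complete simulated study input (both views + phenotype + truth)."""
    ss = np.random.SeedSequence([seed, 7])
    s_geno, s_meta, s_pheno = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    if geno_cfg is None:
        geno_cfg = GenoSimConfig(n_samples=n_samples, n_snps=d_G, seed=s_geno)
    if pln_cfg is None:
        pln_cfg = PLNConfig(n_samples=n_samples, n_taxa=d_M, seed=s_meta)
    geno = simulate_genotypes(geno_cfg)
    abund = simulate_metagenome(pln_cfg)
    comp = clr_from_counts(abund)
    svG, svM = generating_supervariables(geno, comp, geno_cfg.block_labels, pln_cfg.group_labels)
    y, truth = simulate_phenotype(svG, svM, I=I, sd_eps=sd_eps, seed=s_pheno)
    return Dataset(
        geno=geno, abund=abund, comp=comp, y=y, truth=truth,
        geno_labels=geno_cfg.block_labels, meta_labels=pln_cfg.group_labels,
    )


@dataclass
class StudyGrid:
    """Factor grid of the simulation study (defaults = the full design)."""

    N: tuple[int, ...] = (50, 100, 200)
    sd_eps: tuple[float, ...] = (0.5, 1.0, 2.0)
    I: tuple[int, ...] = (1, 3, 5, 7, 10)
    n_replicates: int = 30
    d_G: int = 200
    d_M: int = 100
    methods: tuple[str, ...] = ("gap", "unit")  # weighting schemes


def run_study(grid: StudyGrid, seed: int = 0, correction: str = "holm", alpha: float = 0.05) -> pd.DataFrame:
    """Run the simulation study over the grid; tidy precision/recall table.

    Per cell and replicate, one dataset is generated and every weighting
    scheme is fitted on the same dataset (trees and compression shared;
    only the penalty factors differ: "gap" uses rho = 1/sqrt(s), "unit"
    uses rho = 1). Deterministic under ``seed``.
    """
    from .pipeline import fit_views, select_and_test

    rows = []
    cells = [(n, sd, i) for n in grid.N for sd in grid.sd_eps for i in grid.I]
    for ci, (n, sd, i) in enumerate(cells):
        for rep in range(grid.n_replicates):
            rep_seed = int(np.random.SeedSequence([seed, ci, rep]).generate_state(1)[0] % 2**31)
            ds = generate_dataset(
                n_samples=n, d_G=grid.d_G, d_M=grid.d_M, I=i, sd_eps=sd, seed=rep_seed
            )
            views = fit_views(ds.geno, ds.comp)
            for method in grid.methods:
                t0 = time.perf_counter()
                result = select_and_test(
                    views, ds.y, weighting=method, seed=rep_seed,
                    correction=correction, alpha=alpha,
                )
                runtime = time.perf_counter() - t0
                from .evaluate import expand_to_variable_level

                est = expand_to_variable_level(
                    result.records, result.catalog_G, result.catalog_M,
                    ds.geno.n_snps, ds.abund.n_taxa,
                )
                prec, rec, counts = precision_recall(est, ds.truth.Delta_true)
                rows.append(
                    {
                        "method": method, "N": n, "sd_eps": sd, "I": i, "replicate": rep,
                        "TP": counts.TP, "FP": counts.FP, "FN": counts.FN, "TN": counts.TN,
                        "precision": prec, "recall": rec, "runtime_s": round(runtime, 4),
                        "n_selected_G": result.sel_G.n_selected,
                        "n_selected_M": result.sel_M.n_selected,
                    }
                )
    return pd.DataFrame(rows)
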