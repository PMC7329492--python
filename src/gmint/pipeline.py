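"""End-to-end orchestration: preprocess -> cluster -> compress -> select -> test.

The pipeline mirrors the method's four steps: identify the group structure
of each view by hierarchical clustering, compress every candidate group
into a supervariable, select supervariables per view by (stability-)Lasso
with gap weights, then exhaustively test all selected G x M pairs in small
interaction models with a single multiplicity correction.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .clustering import MergeTree, constrained_ward, ld_dissimilarity, ward_tree
from .hierarchy import (
    GroupCatalog,
    SuperVariableMatrix,
    compress_groups,
    compute_weights,
    expand_tree,
    restrict_search_space,
    unit_weights,
)
from .interaction import InteractionRecord, test_all_pairs
from .preprocess import AbundanceMatrix, CompositionMatrix, GenotypeMatrix
from .selection import SelectionConfig, SelectionResult, select_supervariables

logger = logging.getLogger("gmint")


@dataclass
class Views:
    """Per-view structures shared by every weighting scheme."""

    tree_G: MergeTree
    tree_M: MergeTree
    geno: GenotypeMatrix
    comp: CompositionMatrix


@dataclass
class FitResult:
    catalog_G: GroupCatalog
    catalog_M: GroupCatalog
    svG: SuperVariableMatrix
    svM: SuperVariableMatrix
    sel_G: SelectionResult
    sel_M: SelectionResult
    records: list[InteractionRecord]

    @property
    def significant(self) -> list[InteractionRecord]:
        return [r for r in self.records if r.significant]


def fit_views(geno: GenotypeMatrix, comp: CompositionMatrix) -> Views:
    """Build both dendrograms: constrained Ward on LD, plain Ward on CLR.

    The metagenome tree is built on column-standardized CLR profiles, so
    taxa cluster by correlation — matching the correlation-defined group
    structure — instead of by baseline abundance.
    """
    tree_G = constrained_ward(ld_dissimilarity(geno))
    tree_M = ward_tree(comp.values, ids=comp.taxon_ids, standardize=True)
    logger.info("trees built: G %d leaves, M %d leaves", tree_G.n_leaves, tree_M.n_leaves)
    return Views(tree_G=tree_G, tree_M=tree_M, geno=geno, comp=comp)


def _weighted_catalog(tree: MergeTree, weighting: str, max_groups: int | None) -> GroupCatalog:
    cat = compute_weights(expand_tree(tree))
    if weighting == "unit":
        cat = unit_weights(cat)
    elif weighting != "gap":
        raise ValueError(f"unknown weighting {weighting!r} (use 'gap' or 'unit')")
    return restrict_search_space(cat, max_groups)


def select_and_test(
    views: Views,
    y: np.ndarray,
    weighting: str = "gap",
    compression: str = "mean",
    cfg_G: SelectionConfig | None = None,
    cfg_M: SelectionConfig | None = None,
    correction: str = "holm",
    alpha: float = 0.05,
    max_groups: int | None = None,
    seed: int = 0,
) -> FitResult:
    """Weight, compress, select and test on prebuilt trees."""
    if cfg_G is None:
        cfg_G = SelectionConfig.genome_defaults(seed=seed)
    if cfg_M is None:
        cfg_M = SelectionConfig.metagenome_defaults(seed=seed + 1)
    cat_G = _weighted_catalog(views.tree_G, weighting, max_groups)
    cat_M = _weighted_catalog(views.tree_M, weighting, max_groups)
    cat_G.view, cat_M.view = "G", "M"
    svG = compress_groups(views.geno.values.astype(float), cat_G, fn=compression)
    svM = compress_groups(views.comp.values, cat_M, fn=compression)
    logger.info(
        "catalogs: G %d -> %d groups, M %d -> %d groups",
        views.tree_G.n_leaves, len(cat_G), views.tree_M.n_leaves, len(cat_M),
    )
    sel_G = select_supervariables(svG, y, cfg_G, view="G")
    sel_M = select_supervariables(svM, y, cfg_M, view="M")
    logger.info("selected: %d G-groups, %d M-groups", sel_G.n_selected, sel_M.n_selected)
    records = test_all_pairs(sel_G, sel_M, svG, svM, y, correction=correction, alpha=alpha)
    return FitResult(
        catalog_G=cat_G, catalog_M=cat_M, svG=svG, svM=svM,
        sel_G=sel_G, sel_M=sel_M, records=records,
    )


def fit(
    geno: GenotypeMatrix,
    comp: CompositionMatrix,
    y: np.ndarray,
    **kwargs,
) -> FitResult:
    """Full fit from preprocessed inputs (trees built internally)."""
    return select_and_test(fit_views(geno, comp), y, **kwargs)


@dataclass
class RunConfig:
    """File-level configuration of one pipeline run."""

    geno_path: str
    meta_path: str
    pheno_path: str
    out_dir: str
    compression: str = "mean"
    weighting: str = "gap"
    correction: str = "holm"
    alpha: float = 0.05
    maf_threshold: float = 0.03
    zero_replacement: str = "multiplicative"
    delta: float = 0.5
    max_groups: int | None = None
    use_stability: bool = True
    cutoff_g: float = 0.6
    cutoff_m: float = 0.7
    pfer_g: float = 10.0
    pfer_m: float = 1.0
    b_g: int = 100
    b_m: int = 300
    seed: int = 0
    by_chromosome: bool = False
    extras: dict = field(default_factory=dict)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the pipeline from files; write results TSV + manifest JSON.

    Returns the output directory. Outputs: ``interactions.tsv`` (one row
    per tested pair, fixed column order), ``selection.tsv``,
    ``catalog_G.json`` / ``catalog_M.json``, ``tree_G.nwk`` /
    ``tree_M.nwk`` and ``manifest.json`` with the seed, parameters and
    stage counts.
    """
    from . import __version__
    from .io import (
        read_inputs,
        write_catalog_json,
        write_newick,
        write_results_tsv,
        write_selection_tsv,
    )
    from .preprocess import clr_from_counts, maf_filter

    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geno, abund, y, sample_ids = read_inputs(cfg.geno_path, cfg.meta_path, cfg.pheno_path)
    stage_counts = {"samples": len(sample_ids), "snps_raw": geno.n_snps, "taxa": abund.n_taxa}
    geno = maf_filter(geno, cfg.maf_threshold)
    stage_counts["snps_after_maf"] = geno.n_snps
    comp = clr_from_counts(abund, method=cfg.zero_replacement, delta=cfg.delta)

    cfg_G = SelectionConfig(
        use_stability=cfg.use_stability, B=cfg.b_g, cutoff=cfg.cutoff_g,
        PFER=cfg.pfer_g, seed=cfg.seed,
    )
    cfg_M = SelectionConfig(
        use_stability=cfg.use_stability, B=cfg.b_m, cutoff=cfg.cutoff_m,
        PFER=cfg.pfer_m, seed=cfg.seed + 1,
    )
    if cfg.by_chromosome:
        result = _fit_by_chromosome(geno, comp, y, cfg, cfg_G, cfg_M)
    else:
        views = fit_views(geno, comp)
        result = select_and_test(
            views, y, weighting=cfg.weighting, compression=cfg.compression,
            cfg_G=cfg_G, cfg_M=cfg_M, correction=cfg.correction, alpha=cfg.alpha,
            max_groups=cfg.max_groups, seed=cfg.seed,
        )
        write_newick(views.tree_G, geno.snp_ids, out / "tree_G.nwk")
        write_newick(views.tree_M, abund.taxon_ids, out / "tree_M.nwk")

    write_results_tsv(result.records, result.catalog_G, result.catalog_M,
                      geno.snp_ids, abund.taxon_ids, out / "interactions.tsv")
    write_selection_tsv(result.sel_G, result.sel_M, out / "selection.tsv")
    write_catalog_json(result.catalog_G, geno.snp_ids, out / "catalog_G.json")
    write_catalog_json(result.catalog_M, abund.taxon_ids, out / "catalog_M.json")

    n_untestable = sum(1 for r in result.records if not r.testable)
    stage_counts.update(
        {
            "groups_G": len(result.catalog_G),
            "groups_M": len(result.catalog_M),
            "selected_G": result.sel_G.n_selected,
            "selected_M": result.sel_M.n_selected,
            "tested_pairs": len(result.records) - n_untestable,
            "untestable_pairs": n_untestable,
            "significant_pairs": len(result.significant),
        }
    )
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: v for k, v in vars(cfg).items() if k != "extras" and not k.endswith("_path")
        },
        "inputs": {"geno": cfg.geno_path, "meta": cfg.meta_path, "pheno": cfg.pheno_path},
        "stage_counts": stage_counts,
        "elapsed_s": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    if not result.records:
        logger.info("no supervariable selected in at least one view: empty interaction table")
    return out


def _fit_by_chromosome(geno, comp, y, cfg, cfg_G, cfg_M):
    """Cluster/select the genome per chromosome; pool before a single correction.

    Chromosomes are encoded as breaks in the position ordering (positions
    restart between chromosomes). The metagenome view is shared.
    """
    from .hierarchy import GroupCatalog as _GC

    if geno.chromosomes is not None:
        change = np.flatnonzero(geno.chromosomes[1:] != geno.chromosomes[:-1])
    else:
        change = np.flatnonzero(np.diff(geno.positions) < 0)
    starts = [0, *list(change + 1), geno.n_snps]
    tree_M = ward_tree(comp)
    cat_M = _weighted_catalog(tree_M, cfg.weighting, cfg.max_groups)
    cat_M.view = "M"
    svM = compress_groups(comp.values, cat_M, fn=cfg.compression)
    sel_M = select_supervariables(svM, y, cfg_M, view="M")

    pooled_groups, pooled_cols, pooled_sel = [], [], []
    for a, b in zip(starts[:-1], starts[1:]):
        sub = GenotypeMatrix(
            values=geno.values[:, a:b], positions=geno.positions[a:b],
            snp_ids=geno.snp_ids[a:b], sample_ids=geno.sample_ids,
            chromosomes=None if geno.chromosomes is None else geno.chromosomes[a:b],
        )
        if sub.n_snps < 2:
            continue
        tree = constrained_ward(ld_dissimilarity(sub))
        cat = _weighted_catalog(tree, cfg.weighting, cfg.max_groups)
        sv = compress_groups(sub.values.astype(float), cat, fn=cfg.compression)
        sel = select_supervariables(sv, y, cfg_G, view="G")
        for j in sel.selected:
            g = cat.groups[j]
            from .hierarchy import Group

            shifted = Group(
                members=tuple(i + a for i in g.members),
                h_create=g.h_create, h_destroy=g.h_destroy, node_id=len(pooled_groups),
            )
            shifted.rho = g.rho
            pooled_groups.append(shifted)
            pooled_cols.append(sv.values[:, j])
            pooled_sel.append(len(pooled_groups) - 1)
    cat_G = _GC(groups=pooled_groups, view="G", n_variables=geno.n_snps)
    svG = SuperVariableMatrix(
        values=np.column_stack(pooled_cols) if pooled_cols else np.empty((len(y), 0)),
        catalog=cat_G, compression=cfg.compression,
    )
    sel_G = SelectionResult(
        view="G", selected=pooled_sel, frequencies=np.ones(len(pooled_sel)),
        coefficients=np.zeros(len(pooled_sel)), config=cfg_G,
    )
    records = test_all_pairs(sel_G, sel_M, svG, svM, y, correction=cfg.correction, alpha=cfg.alpha)
    return FitResult(
        catalog_G=cat_G, catalog_M=cat_M, svG=svG, svM=svM,
        sel_G=sel_G, sel_M=sel_M, records=records,
    )
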