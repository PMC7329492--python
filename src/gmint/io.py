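"""Readers and writers for the formats the pipeline touches.

TSV matrices follow one convention throughout: samples as rows, a header
row of variable ids, and the sample id in the first column. Genotypes may
alternatively come from a VCF (GT field, biallelic records only).
Dendrograms are serialized to Newick with branch lengths equal to height
differences; catalogs, manifests and simulation truths go to JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import MergeTree
from .hierarchy import GroupCatalog
from .interaction import InteractionRecord
from .preprocess import AbundanceMatrix, GenotypeMatrix
from .selection import SelectionResult
from .simulate import SimulationTruth

logger = logging.getLogger("gmint")


# ---------------------------------------------------------------- TSV matrices

def read_abundance_tsv(path: str | Path) -> AbundanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AbundanceMatrix(
        values=df.to_numpy(),
        sample_ids=[str(s) for s in df.index],
        taxon_ids=[str(c) for c in df.columns],
    )


def write_abundance_tsv(abund: AbundanceMatrix, path: str | Path) -> None:
    pd.DataFrame(abund.values, index=abund.sample_ids, columns=abund.taxon_ids).to_csv(
        path, sep="\t", index_label="sample"
    )


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    """Dosage TSV; columns are assumed ordered by genomic position."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(
        values=df.to_numpy(),
        positions=np.arange(1, df.shape[1] + 1),
        snp_ids=[str(c) for c in df.columns],
        sample_ids=[str(s) for s in df.index],
    )


def write_genotype_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    pd.DataFrame(geno.values, index=geno.sample_ids, columns=geno.snp_ids).to_csv(
        path, sep="\t", index_label="sample"
    )


def read_phenotype_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] != 1:
        raise ValueError("phenotype TSV must have exactly one value column")
    s = df.iloc[:, 0].astype(float)
    s.index = s.index.astype(str)
    return s


def write_phenotype_tsv(y: np.ndarray, sample_ids: list[str], path: str | Path) -> None:
    pd.Series(y, index=sample_ids, name="phenotype").to_csv(
        path, sep="\t", index_label="sample"
    )


# ----------------------------------------------------------------------- VCF

def read_genotype_vcf(path: str | Path) -> GenotypeMatrix:
    """Dosages from a VCF's GT field; multiallelic records are skipped."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, positions, snp_ids, chroms = [], [], [], []
    n_multi = n_missing = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gt = rec.gt_types.astype(float)  # 0/1/2, 3 = unknown under gts012
        if np.any(gt == 3):
            n_missing += 1
            continue
        rows.append(gt.astype(int))
        positions.append(rec.POS)
        snp_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
    if n_multi:
        logger.info("skipped %d multiallelic VCF records", n_multi)
    if n_missing:
        logger.info("skipped %d VCF records with missing genotypes", n_missing)
    if not rows:
        raise ValueError(f"no usable biallelic records in {path}")
    return GenotypeMatrix(
        values=np.array(rows).T,
        positions=np.array(positions),
        snp_ids=snp_ids,
        sample_ids=samples,
        chromosomes=np.array(chroms),
    )


# ------------------------------------------------------------ sample alignment

def read_inputs(
    geno_path: str | Path, meta_path: str | Path, pheno_path: str | Path
) -> tuple[GenotypeMatrix, AbundanceMatrix, np.ndarray, list[str]]:
    """Read the three inputs and align them on the common sample set.

    Samples are matched by id; the intersection is ordered as in the
    genotype file. Samples missing from any input are dropped with a
    logged warning.
    """
    geno_path = str(geno_path)
    if geno_path.endswith((".vcf", ".vcf.gz")):
        geno = read_genotype_vcf(geno_path)
    else:
        geno = read_genotype_tsv(geno_path)
    abund = read_abundance_tsv(meta_path)
    pheno = read_phenotype_tsv(pheno_path)
    for name, ids in (("genotype", geno.sample_ids), ("abundance", abund.sample_ids),
                      ("phenotype", list(pheno.index))):
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate sample ids in {name} input")
    common = [s for s in geno.sample_ids if s in set(abund.sample_ids) & set(pheno.index)]
    if not common:
        raise ValueError("no samples shared by the three inputs")
    dropped = (set(geno.sample_ids) | set(abund.sample_ids) | set(pheno.index)) - set(common)
    if dropped:
        logger.warning("dropping %d sample(s) absent from some input: %s",
                       len(dropped), sorted(dropped))
    g_idx = [geno.sample_ids.index(s) for s in common]
    a_idx = [abund.sample_ids.index(s) for s in common]
    geno = GenotypeMatrix(
        values=geno.values[g_idx], positions=geno.positions, snp_ids=geno.snp_ids,
        sample_ids=common, chromosomes=geno.chromosomes,
    )
    abund = AbundanceMatrix(
        values=abund.values[a_idx], sample_ids=common, taxon_ids=abund.taxon_ids
    )
    y = pheno.loc[common].to_numpy()
    logger.info("aligned %d common samples (genotype order)", len(common))
    return geno, abund, y, common


# --------------------------------------------------------------------- trees

def write_merge_tsv(tree: MergeTree, path: str | Path) -> None:
    pd.DataFrame(tree.merges, columns=["left", "right", "height"]).to_csv(
        path, sep="\t", index_label="merge"
    )


def tree_to_newick(tree: MergeTree, labels: list[str]) -> str:
    """Newick string with branch lengths = parent height - child height."""
    D = tree.n_leaves

    def render(node: int, parent_h: float) -> str:
        if node < D:
            return f"{labels[node]}:{parent_h:.6g}"
        left, right, h = tree.merges[node - D]
        return f"({render(left, h)},{render(right, h)}):{parent_h - h:.6g}"

    left, right, h = tree.merges[-1]
    return f"({render(left, h)},{render(right, h)});"


def write_newick(tree: MergeTree, labels: list[str], path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree, labels) + "\n")


# ------------------------------------------------------------------- catalogs

def write_catalog_json(catalog: GroupCatalog, var_ids: list[str], path: str | Path) -> None:
    payload = [
        {
            "id": g.node_id,
            "view": catalog.view,
            "members": [var_ids[i] for i in g.members],
            "member_indices": list(g.members),
            "h_create": g.h_create,
            "h_destroy": g.h_destroy,
            "s": g.s,
            "rho": g.rho,
        }
        for g in catalog.groups
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


# -------------------------------------------------------------------- results

RESULT_COLUMNS = [
    "g", "m", "members_g", "members_m", "theta_hat", "se", "t", "p", "p_adj", "significant",
]


def write_results_tsv(
    records: list[InteractionRecord],
    catalog_G: GroupCatalog,
    catalog_M: GroupCatalog,
    snp_ids: list[str],
    taxon_ids: list[str],
    path: str | Path,
) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "g": r.g,
                "m": r.m,
                "members_g": ",".join(snp_ids[i] for i in catalog_G.groups[r.g].members),
                "members_m": ",".join(taxon_ids[i] for i in catalog_M.groups[r.m].members),
                "theta_hat": r.theta_hat,
                "se": r.se,
                "t": r.t,
                "p": r.p,
                "p_adj": r.p_adj,
                "significant": r.significant,
            }
        )
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_selection_tsv(sel_G: SelectionResult, sel_M: SelectionResult, path: str | Path) -> None:
    rows = []
    for sel in (sel_G, sel_M):
        for j, f in enumerate(sel.frequencies):
            rows.append(
                {
                    "group": j,
                    "view": sel.view,
                    "frequency": f,
                    "coefficient": sel.coefficients[j],
                    "selected": j in sel.selected,
                }
            )
    pd.DataFrame(rows, columns=["group", "view", "frequency", "coefficient", "selected"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------- truth

def write_truth_json(truth: SimulationTruth, path: str | Path) -> None:
    delta = np.asarray(truth.Delta_true)
    gi, mi = np.nonzero(delta)
    payload = {
        "I": truth.I,
        "sd_eps": truth.sd_eps,
        "pairs": [list(p) for p in truth.pairs],
        "S_G": truth.S_G,
        "S_M": truth.S_M,
        "beta_G": {str(k): v for k, v in truth.beta_G.items()},
        "beta_M": {str(k): v for k, v in truth.beta_M.items()},
        "theta": {f"{g},{m}": v for (g, m), v in truth.theta.items()},
        "delta_shape": list(delta.shape),
        "delta_triplets": [[int(a), int(b), 1] for a, b in zip(gi, mi)],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_truth_json(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    shape = tuple(payload["delta_shape"])
    delta = np.zeros(shape, dtype=bool)
    for a, b, _v in payload["delta_triplets"]:
        delta[a, b] = True
    payload["Delta_true"] = delta
    return payload
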