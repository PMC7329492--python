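"""Dendrogram construction for the two views.

Genomic view: SNPs are clustered with a spatially constrained Ward
agglomeration on the linkage-disequilibrium dissimilarity 1 - r^2, where
only clusters adjacent on the genome may merge — LD is approximately
block-diagonal along the chromosome, so the constraint loses little and
cuts the candidate set to the D-1 adjacent pairs.

Metagenomic view: CLR-transformed abundance profiles are clustered with
ordinary (unconstrained) Ward linkage on Euclidean distances between taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage

from .preprocess import CompositionMatrix, GenotypeMatrix


@dataclass
class DissimilarityMatrix:
    """Symmetric dissimilarities with zero diagonal; kind 'ld' or 'euclidean'."""

    values: np.ndarray
    kind: str = "ld"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        np.fill_diagonal(v, 0.0)
        if self.kind == "ld" and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("LD dissimilarities must lie in [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class MergeTree:
    """Full dendrogram: ordered merges with heights, scipy node convention.

    Leaves are nodes ``0 .. D-1``; the k-th merge (0-based) creates node
    ``D + k``. Heights are nondecreasing after monotonicity enforcement.
    ``constrained`` trees additionally guarantee every internal node covers
    a contiguous interval of leaf indices.
    """

    n_leaves: int
    merges: list[tuple[int, int, float]]
    leaf_order: list[int] = field(default_factory=list)
    constrained: bool = False

    def __post_init__(self) -> None:
        if not self.leaf_order:
            self.leaf_order = list(range(self.n_leaves))
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a tree over D leaves must have D-1 merges")
        seen: set[int] = set()
        for left, right, _h in self.merges:
            if left in seen or right in seen:
                raise ValueError("node used as a child more than once")
            seen.update((left, right))
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be nondecreasing")

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    def node_members(self) -> dict[int, tuple[int, ...]]:
        """Leaf index tuple (sorted) covered by every node, leaves included."""
        members: dict[int, tuple[int, ...]] = {i: (i,) for i in range(self.n_leaves)}
        for k, (left, right, _h) in enumerate(self.merges):
            members[self.n_leaves + k] = tuple(sorted(members[left] + members[right]))
        return members

    def to_linkage(self) -> np.ndarray:
        """Scipy linkage matrix (sizes in column 3) for interop."""
        members = self.node_members()
        Z = np.zeros((self.n_leaves - 1, 4))
        for k, (left, right, h) in enumerate(self.merges):
            Z[k] = [left, right, h, len(members[self.n_leaves + k])]
        return Z

    def cut(self, k: int) -> np.ndarray:
        """Labels of the k-cluster partition obtained by undoing the last merges."""
        if not 1 <= k <= self.n_leaves:
            raise ValueError("k must lie in [1, n_leaves]")
        return cut_tree(self.to_linkage(), n_clusters=k).ravel()


def ld_dissimilarity(geno: GenotypeMatrix) -> DissimilarityMatrix:
    """LD-based dissimilarity 1 - r^2 between dosage columns.

    r is the Pearson correlation of genotype dosages (composite LD), not
    haplotype-phase LD — phase is not observed in dosage data.
    """
    X = geno.values.astype(float)
    if X.shape[0] < 2:
        raise ValueError("need at least two samples to estimate LD")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant dosage column: r^2 undefined (apply maf_filter first)")
    r = np.corrcoef(X, rowvar=False)
    d = 1.0 - r**2
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(values=d, kind="ld")


def _lance_williams_ward(d_ik: float, d_jk: float, d_ij: float, ni: int, nj: int, nk: int) -> float:
    n = ni + nj + nk
    return ((ni + nk) * d_ik + (nj + nk) * d_jk - nk * d_ij) / n


def constrained_ward(d: DissimilarityMatrix) -> MergeTree:
    """Adjacency-constrained Ward agglomeration on a dissimilarity matrix.

    Only clusters adjacent in the column order may merge, so every internal
    node spans a contiguous index interval. The Ward criterion is applied to
    the given dissimilarities via the Lance-Williams update. Constrained
    merging can invert heights; monotone heights are enforced by running
    maximum (downstream gap weights require nondecreasing heights). Ties are
    broken toward the pair with the smallest starting index.
    """
    D = d.n
    if D < 2:
        raise ValueError("need at least two variables to cluster")
    dm = d.values.copy()
    # active clusters kept in genomic order: (node_id, size, start_index)
    clusters: list[list[int]] = [[j, 1, j] for j in range(D)]
    # cost[i] = Ward cost of merging clusters[i] with clusters[i+1]
    cost = [dm[j, j + 1] for j in range(D - 1)]
    # pairwise dissimilarities between active clusters, indexed by position
    merges: list[tuple[int, int, float]] = []
    last_h = 0.0
    next_id = D
    for step in range(D - 1):
        i = int(np.argmin(cost))  # argmin returns first minimum -> leftmost tie-break
        left, right = clusters[i], clusters[i + 1]
        h = max(cost[i], last_h)
        merges.append((left[0], right[0], h))
        last_h = h
        d_ij = cost[i]
        ni, nj = left[1], right[1]
        # Lance-Williams update of the merged cluster's cost to its neighbors
        new = [next_id, ni + nj, left[2]]
        next_id += 1
        # distances from the new cluster to remaining clusters are needed only
        # for its two neighbors, but the update needs d(neighbor, left) and
        # d(neighbor, right): maintain a full condensed matrix over positions.
        n_active = len(clusters)
        row = np.empty(n_active)
        for k in range(n_active):
            if k in (i, i + 1):
                continue
            row[k] = _lance_williams_ward(
                _pairdist(dm, left[0], clusters[k][0]),
                _pairdist(dm, right[0], clusters[k][0]),
                d_ij,
                ni,
                nj,
                clusters[k][1],
            )
        # store new distances under the new node id by growing dm lazily
        dm = _grow(dm, new[0])
        for k in range(n_active):
            if k in (i, i + 1):
                continue
            dm[new[0], clusters[k][0]] = dm[clusters[k][0], new[0]] = row[k]
        clusters[i : i + 2] = [new]
        # rebuild adjacent costs around position i
        cost[i : i + 1] = []
        if i - 1 >= 0:
            cost[i - 1] = dm[clusters[i - 1][0], clusters[i][0]]
        if i + 1 < len(clusters):
            cost[i] = dm[clusters[i][0], clusters[i + 1][0]]
    return MergeTree(n_leaves=D, merges=merges, constrained=True)


def _pairdist(dm: np.ndarray, a: int, b: int) -> float:
    return dm[a, b]


def _grow(dm: np.ndarray, node_id: int) -> np.ndarray:
    if node_id < dm.shape[0]:
        return dm
    new = np.zeros((node_id + 1, node_id + 1))
    new[: dm.shape[0], : dm.shape[1]] = dm
    return new


def ward_tree(
    data: CompositionMatrix | np.ndarray,
    ids: list[str] | None = None,
    standardize: bool = False,
) -> MergeTree:
    """Unconstrained Ward linkage on Euclidean distances between columns.

    With ``standardize=True`` each column is centered and scaled to unit
    variance first, so squared distances become proportional to 1 - r and
    the tree reflects the correlation structure of the taxa rather than
    their baseline-abundance offsets.
    """
    if isinstance(data, CompositionMatrix):
        X = data.values
        ids = data.taxon_ids
    else:
        X = np.asarray(data, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least two columns to cluster")
    if ids is not None and len(set(ids)) != len(ids):
        raise ValueError("duplicate column ids")
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    Z = linkage(X.T, method="ward")
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
    return MergeTree(n_leaves=X.shape[1], merges=merges, constrained=False)


def _within_dispersion(points: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for lab in np.unique(labels):
        pts = points[labels == lab]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return w


def gap_statistic(
    points: np.ndarray,
    tree: MergeTree,
    k_max: int,
    n_ref: int = 10,
    seed: int = 0,
    builder=None,
) -> int:
    """Tibshirani gap-statistic choice of the number of clusters.

    ``points`` holds the clustered items as rows (for column clustering,
    pass the transposed data matrix); ``tree`` is their dendrogram. The
    observed log within-cluster dispersion at each cut k is compared with
    its expectation under ``n_ref`` uniform reference draws over the data's
    bounding box, clustered by ``builder`` (default: unconstrained Ward).
    Returns the smallest k with gap(k) >= gap(k+1) - s_{k+1}.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if tree.n_leaves != n:
        raise ValueError("tree does not match the number of points")
    if k_max < 1 or k_max > n:
        raise ValueError("k_max must lie in [1, n_points]")
    if n_ref < 1:
        raise ValueError("n_ref must be at least 1")
    if builder is None:
        builder = ward_tree  # on columns of points.T == rows of points
    rng = np.random.default_rng(seed)
    ks = np.arange(1, k_max + 1)
    log_w = np.array([np.log(max(_within_dispersion(pts, tree.cut(int(k))), 1e-300)) for k in ks])
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    ref_log_w = np.empty((n_ref, len(ks)))
    for b in range(n_ref):
        ref = rng.uniform(lo, hi, size=pts.shape)
        ref_tree = builder(ref.T)
        ref_log_w[b] = [
            np.log(max(_within_dispersion(ref, ref_tree.cut(int(k))), 1e-300)) for k in ks
        ]
    gap = ref_log_w.mean(axis=0) - log_w
    s = ref_log_w.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / n_ref)
    for idx in range(len(ks) - 1):
        if gap[idx] >= gap[idx + 1] - s[idx + 1]:
            return int(ks[idx])
    return int(ks[-1])
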