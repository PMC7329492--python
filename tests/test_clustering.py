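"""Dendrogram construction: LD dissimilarity, constrained and plain Ward."""

import numpy as np
import pytest

from gmint.clustering import (
    DissimilarityMatrix,
    constrained_ward,
    gap_statistic,
    ld_dissimilarity,
    ward_tree,
)
from gmint.preprocess import GenotypeMatrix


def _geno_from(values):
    v = np.asarray(values)
    return GenotypeMatrix(
        values=v, positions=np.arange(v.shape[1]), snp_ids=[f"x{j}" for j in range(v.shape[1])]
    )


# ------------------------------------------------------------- ward oracles


def _ess(pts):
    return float(((pts - pts.mean(axis=0)) ** 2).sum())


def _naive_ward_merge_cost(pts, A, B):
    """Incremental sum-of-squares of merging clusters A and B (leaf lists)."""
    return _ess(pts[A + B]) - _ess(pts[A]) - _ess(pts[B])


def _naive_constrained_ward(pts):
    """Greedy adjacent-pair Ward computed directly from cluster ESS."""
    clusters = [[j] for j in range(pts.shape[0])]
    merges = []
    while len(clusters) > 1:
        costs = [
            _naive_ward_merge_cost(pts, clusters[i], clusters[i + 1])
            for i in range(len(clusters) - 1)
        ]
        i = int(np.argmin(costs))
        merges.append((tuple(clusters[i]), tuple(clusters[i + 1]), 2 * costs[i]))
        clusters[i : i + 2] = [clusters[i] + clusters[i + 1]]
    return merges


def _naive_unconstrained_ward(pts):
    clusters = [[j] for j in range(pts.shape[0])]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                c = _naive_ward_merge_cost(pts, clusters[a], clusters[b])
                if best is None or c < best[0]:
                    best = (c, a, b)
        c, a, b = best
        merges.append((frozenset(clusters[a]), frozenset(clusters[b]), np.sqrt(2 * c)))
        merged = clusters[a] + clusters[b]
        clusters = [cl for i, cl in enumerate(clusters) if i not in (a, b)] + [merged]
    return merges


def _sq_euclidean_dissim(pts):
    d = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    return DissimilarityMatrix(values=d, kind="euclidean")


class TestLdDissimilarity:
    def test_diagonal_zero_and_duplicate_columns(self, rng):
        col = rng.integers(0, 3, size=50)
        col[:2] = [0, 2]
        g = _geno_from(np.column_stack([col, col, rng.integers(0, 3, size=50)]))
        d = ld_dissimilarity(g)
        assert d.values[0, 0] == 0
        assert d.values[0, 1] == pytest.approx(0, abs=1e-12)

    def test_independent_columns_near_one(self):
        rng = np.random.default_rng(7)
        g = _geno_from(rng.integers(0, 3, size=(10_000, 2)))
        d = ld_dissimilarity(g)
        assert d.values[0, 1] == pytest.approx(1.0, abs=0.02)

    def test_constant_column_rejected(self):
        v = np.column_stack([np.zeros(20, dtype=int), np.tile([0, 1], 10)])
        with pytest.raises(ValueError, match="constant"):
            ld_dissimilarity(_geno_from(v))


class TestConstrainedWard:
    def test_block_structure_merged_first(self):
        d = np.full((4, 4), 0.9)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.1
        np.fill_diagonal(d, 0.0)
        tree = constrained_ward(DissimilarityMatrix(values=d, kind="ld"))
        first_two = {frozenset(tree.merges[0][:2]), frozenset(tree.merges[1][:2])}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_two_leaves(self):
        d = DissimilarityMatrix(values=np.array([[0.0, 0.4], [0.4, 0.0]]), kind="ld")
        tree = constrained_ward(d)
        assert tree.merges == [(0, 1, 0.4)]

    def test_contiguity_of_internal_nodes(self, rng):
        pts = rng.normal(size=(9, 4))
        tree = constrained_ward(_sq_euclidean_dissim(pts))
        for members in tree.node_members().values():
            assert list(members) == list(range(min(members), max(members) + 1))

    @pytest.mark.parametrize("n_points", [4, 6, 8])
    def test_matches_ess_oracle(self, n_points):
        """Greedy adjacent Ward from explicit ESS equals the LW implementation."""
        rng = np.random.default_rng(n_points)
        pts = rng.normal(size=(n_points, 3))
        tree = constrained_ward(_sq_euclidean_dissim(pts))
        oracle = _naive_constrained_ward(pts)
        members = tree.node_members()
        for k, (left, right, h) in enumerate(tree.merges):
            o_left, o_right, o_cost = oracle[k]
            assert {members[left], members[right]} == {tuple(sorted(o_left)), tuple(sorted(o_right))}
            # heights agree up to the running-maximum monotonicity fix
            expected = max(o_cost, max(c for _, _, c in oracle[: k + 1]))
            assert h == pytest.approx(expected, rel=1e-9)

    def test_equals_unconstrained_when_optimal_merges_adjacent(self):
        # ordered points on a line: unconstrained Ward merges are all adjacent
        pts = np.array([[0.0], [0.1], [3.0], [3.2], [9.0], [9.5]])
        tree = constrained_ward(_sq_euclidean_dissim(pts))
        oracle = _naive_unconstrained_ward(pts)
        members = tree.node_members()
        for k, (left, right, _h) in enumerate(tree.merges):
            assert {frozenset(members[left]), frozenset(members[right])} == set(oracle[k][:2])

    def test_single_variable_rejected(self):
        with pytest.raises(ValueError):
            constrained_ward(DissimilarityMatrix(values=np.zeros((1, 1)), kind="ld"))


class TestWardTree:
    def test_identical_columns_merge_first_at_zero(self, rng):
        X = rng.normal(size=(20, 5))
        X[:, 3] = X[:, 1]
        tree = ward_tree(X)
        left, right, h = tree.merges[0]
        assert {left, right} == {1, 3}
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_ward_oracle(self, rng):
        X = rng.normal(size=(15, 6))
        tree = ward_tree(X)
        oracle = _naive_unconstrained_ward(X.T)
        members = tree.node_members()
        for k, (left, right, h) in enumerate(tree.merges):
            assert {frozenset(members[left]), frozenset(members[right])} == set(oracle[k][:2])
            assert h == pytest.approx(oracle[k][2], rel=1e-9)

    def test_column_permutation_invariance(self, rng):
        X = rng.normal(size=(25, 7))
        perm = np.array([3, 0, 6, 1, 5, 2, 4])
        t1 = ward_tree(X)
        t2 = ward_tree(X[:, perm])
        sets1 = {frozenset(m) for m in t1.node_members().values()}
        sets2 = {frozenset(int(perm[i]) for i in m) for m in t2.node_members().values()}
        assert sets1 == sets2

    def test_duplicate_ids_rejected(self, rng):
        with pytest.raises(ValueError, match="duplicate"):
            ward_tree(rng.normal(size=(10, 3)), ids=["a", "a", "b"])


class TestGapStatistic:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(3)
        pts = np.vstack(
            [rng.normal(0, 0.3, size=(12, 2)), rng.normal(20, 0.3, size=(12, 2))]
        )
        tree = ward_tree(pts.T)
        k = gap_statistic(pts, tree, k_max=6, n_ref=10, seed=0)
        assert k == 2

    def test_zero_reference_draws_rejected(self, rng):
        pts = rng.normal(size=(8, 2))
        tree = ward_tree(pts.T)
        with pytest.raises(ValueError):
            gap_statistic(pts, tree, k_max=4, n_ref=0)

    def test_deterministic_under_seed(self, rng):
        pts = rng.normal(size=(15, 3))
        tree = ward_tree(pts.T)
        ks = {gap_statistic(pts, tree, k_max=5, n_ref=5, seed=11) for _ in range(3)}
        assert len(ks) == 1
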