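"""Flatten a dendrogram into a weighted group catalog and compress groups.

Rather than choosing one cut of the tree, every node (leaf and internal,
root included — 2D-1 groups in all) becomes a candidate group. Each group
lives over a height interval of the dendrogram: it is created by the merge
that forms it and destroyed by the merge that absorbs it. The length s of
that interval — the persistence gap — measures how strongly the data
support the group; the Lasso penalty factor rho = 1/sqrt(s) makes
long-lived groups cheap to select and ephemeral ones expensive.

Each group is then compressed to a single supervariable (mean, median or
first principal component of its member columns), giving the samples x
groups design matrix used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .clustering import MergeTree


@dataclass
class Group:
    """One candidate group: member columns plus its life span in the tree."""

    members: tuple[int, ...]
    h_create: float
    h_destroy: float
    node_id: int
    s: float = field(init=False)
    rho: float = field(init=False, default=np.nan)

    def __post_init__(self) -> None:
        self.s = self.h_destroy - self.h_create
        if self.s < -1e-12:
            raise ValueError("negative persistence gap: heights not monotone upstream")
        self.s = max(self.s, 0.0)

    @property
    def start(self) -> int:
        return min(self.members)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class GroupCatalog:
    groups: list[Group]
    view: str  # "G" or "M"
    n_variables: int

    def __len__(self) -> int:
        return len(self.groups)

    def member_sets(self) -> list[tuple[int, ...]]:
        return [g.members for g in self.groups]

    def is_laminar(self) -> bool:
        """Every pair of groups is nested or disjoint."""
        sets = [frozenset(g.members) for g in self.groups]
        for i, a in enumerate(sets):
            for b in sets[i + 1 :]:
                if not (a <= b or b <= a or not (a & b)):
                    return False
        return True


@dataclass
class SuperVariableMatrix:
    """Samples x groups compressed design; one column per retained group."""

    values: np.ndarray
    catalog: GroupCatalog
    compression: str

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.catalog):
            raise ValueError("column count must match catalog size")

    @property
    def rho(self) -> np.ndarray:
        return np.array([g.rho for g in self.catalog.groups])


def expand_tree(tree: MergeTree) -> GroupCatalog:
    """All 2D-1 groups of a dendrogram with creation/destruction heights.

    Leaves are created at height 0. A node is destroyed by the merge whose
    child it is; the root is never absorbed and is assigned a destruction
    height of ``final height + (final - penultimate height)`` so that its
    persistence equals the last jump of the hierarchy.
    """
    D = tree.n_leaves
    members = tree.node_members()
    created = {i: 0.0 for i in range(D)}
    destroyed: dict[int, float] = {}
    for k, (left, right, h) in enumerate(tree.merges):
        destroyed[left] = h
        destroyed[right] = h
        created[D + k] = h
    final = tree.merges[-1][2] if tree.merges else 0.0
    penult = tree.merges[-2][2] if len(tree.merges) >= 2 else 0.0
    root = 2 * D - 2
    destroyed[root] = final + (final - penult)
    groups = [
        Group(members=members[n], h_create=created[n], h_destroy=destroyed[n], node_id=n)
        for n in range(2 * D - 1)
    ]
    return GroupCatalog(groups=groups, view="", n_variables=D)


def compute_weights(
    catalog: GroupCatalog, zero_gap_policy: str = "drop", eps: float = 1e-8
) -> GroupCatalog:
    """Attach rho = 1/sqrt(s) to every group; resolve zero-gap groups.

    Groups destroyed at the height they were created (tied merges) have
    s = 0 and an infinite penalty: they are dropped by default, or kept
    with rho capped at ``1/sqrt(eps * h_max)`` under the "cap" policy.
    """
    h_max = max((g.h_destroy for g in catalog.groups), default=1.0) or 1.0
    out: list[Group] = []
    for g in catalog.groups:
        if g.s <= 0:
            if zero_gap_policy == "drop":
                continue
            elif zero_gap_policy == "cap":
                g = replace(g, h_create=g.h_create, h_destroy=g.h_create)
                g.s = 0.0
                g.rho = 1.0 / np.sqrt(eps * h_max)
                out.append(g)
                continue
            else:
                raise ValueError(f"unknown zero_gap_policy {zero_gap_policy!r}")
        g.rho = 1.0 / np.sqrt(g.s)
        out.append(g)
    return GroupCatalog(groups=out, view=catalog.view, n_variables=catalog.n_variables)


def unit_weights(catalog: GroupCatalog) -> GroupCatalog:
    """Set rho = 1 on every retained group (unweighted scheme)."""
    out = []
    for g in catalog.groups:
        g2 = Group(members=g.members, h_create=g.h_create, h_destroy=g.h_destroy, node_id=g.node_id)
        g2.rho = 1.0
        out.append(g2)
    return GroupCatalog(groups=out, view=catalog.view, n_variables=catalog.n_variables)


def compress_groups(
    data: np.ndarray, catalog: GroupCatalog, fn: str = "mean"
) -> SuperVariableMatrix:
    """Compress each group's member columns to one supervariable per sample.

    ``fn`` is "mean", "median" or "pc1". For pc1 the member columns are
    standardized, projected on the leading principal component, and the
    sign is fixed so the largest-magnitude loading is positive; a singleton
    group returns its standardized column.
    """
    X = np.asarray(data, dtype=float)
    cols = np.empty((X.shape[0], len(catalog)))
    for j, g in enumerate(catalog.groups):
        sub = X[:, list(g.members)]
        if fn == "mean":
            cols[:, j] = sub.mean(axis=1)
        elif fn == "median":
            cols[:, j] = np.median(sub, axis=1)
        elif fn == "pc1":
            cols[:, j] = _pc1(sub)
        else:
            raise ValueError(f"unknown compression {fn!r}")
    return SuperVariableMatrix(values=cols, catalog=catalog, compression=fn)


def _pc1(sub: np.ndarray) -> np.ndarray:
    sd = sub.std(axis=0)
    sd[sd == 0] = 1.0
    z = (sub - sub.mean(axis=0)) / sd
    if z.shape[1] == 1:
        return z[:, 0]
    _u, _s, vt = np.linalg.svd(z, full_matrices=False)
    load = vt[0]
    if load[np.argmax(np.abs(load))] < 0:
        load = -load
    return z @ load


def restrict_search_space(catalog: GroupCatalog, max_groups: int | None = None) -> GroupCatalog:
    """Keep the ``max_groups`` groups with the largest persistence gaps.

    Ties are resolved toward the larger group, then the smaller starting
    index. ``None`` keeps everything.
    """
    if max_groups is None or max_groups >= len(catalog):
        return catalog
    if max_groups < 1:
        raise ValueError("max_groups must be at least 1")
    order = sorted(
        range(len(catalog.groups)),
        key=lambda i: (
            -catalog.groups[i].s,
            -catalog.groups[i].size,
            catalog.groups[i].start,
        ),
    )
    keep = sorted(order[:max_groups])
    return GroupCatalog(
        groups=[catalog.groups[i] for i in keep],
        view=catalog.view,
        n_variables=catalog.n_variables,
    )
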