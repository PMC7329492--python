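"""Variable-level scoring of detected interactions against simulated truth.

A significant group pair (g, m) asserts an interaction between every SNP in
g and every taxon in m; the estimated variable-level interaction matrix is
the union of those blocks. It is compared entrywise with the generating
truth over all D_G x D_M variable pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hierarchy import GroupCatalog
from .interaction import InteractionRecord


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def expand_to_variable_level(
    records: list[InteractionRecord],
    catalog_G: GroupCatalog,
    catalog_M: GroupCatalog,
    d_G: int,
    d_M: int,
) -> np.ndarray:
    """Binary D_G x D_M matrix: 1 where a significant pair covers (j, j')."""
    est = np.zeros((d_G, d_M), dtype=bool)
    for rec in records:
        if not rec.significant:
            continue
        gi = list(catalog_G.groups[rec.g].members)
        mi = list(catalog_M.groups[rec.m].members)
        est[np.ix_(gi, mi)] = True
    return est


def precision_recall(
    est: np.ndarray, truth: np.ndarray
) -> tuple[float, float, ConfusionCounts]:
    """Precision TP/(FP+TP) and recall TP/(FN+TP) over all variable pairs.

    An empty estimate against a nonempty truth has undefined precision
    (0/0), reported as NaN rather than 0 so that study averages are not
    silently deflated.
    """
    est = np.asarray(est, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if est.shape != truth.shape:
        raise ValueError("estimated and true interaction matrices differ in shape")
    tp = int(np.sum(est & truth))
    fp = int(np.sum(est & ~truth))
    fn = int(np.sum(~est & truth))
    tn = int(np.sum(~est & ~truth))
    counts = ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)
    precision = tp / (fp + tp) if (fp + tp) > 0 else float("nan")
    recall = tp / (fn + tp) if (fn + tp) > 0 else float("nan")
    return precision, recall, counts
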