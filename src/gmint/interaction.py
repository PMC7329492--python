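"""Exhaustive pairwise interaction testing between selected supervariables.

Every selected genomic group g is paired with every selected metagenomic
group m in the 3-term linear model

    y_i = b0 + xg_i * beta_g + xm_i * beta_m + (xg_i * xm_i) * theta_gm + eps_i

and the interaction coefficient theta_gm is tested with a two-sided t-test
on N-4 degrees of freedom. Because both main effects sit in every tested
model and only selected groups are paired, the procedure satisfies the
strong-dependency (strong-hierarchy) hypothesis by construction. P-values
are adjusted across all testable pairs with Holm (FWER) or
Benjamini-Hochberg (FDR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .hierarchy import SuperVariableMatrix
from .selection import SelectionResult


@dataclass
class InteractionRecord:
    g: int  # catalog index, view G
    m: int  # catalog index, view M
    theta_hat: float
    se: float
    t: float
    p: float
    beta_g: float
    beta_m: float
    p_adj: float = np.nan
    significant: bool = False
    testable: bool = True


def fit_interaction_model(
    xg: np.ndarray, xm: np.ndarray, y: np.ndarray, g: int = -1, m: int = -1
) -> InteractionRecord:
    """OLS fit of one supervariable pair with interaction; t-test on theta."""
    xg = np.asarray(xg, dtype=float).ravel()
    xm = np.asarray(xm, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if xg.size != n or xm.size != n:
        raise ValueError("xg, xm and y must have equal lengths")
    if n < 5:
        raise ValueError("need at least 5 samples for the 4-parameter model")
    X = np.column_stack([np.ones(n), xg, xm, xg * xm])
    if np.linalg.matrix_rank(X) < 4:
        return InteractionRecord(
            g=g, m=m, theta_hat=np.nan, se=np.nan, t=np.nan, p=np.nan,
            beta_g=np.nan, beta_m=np.nan, testable=False,
        )
    coef, _res, _rank, _sv = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - 4
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[3, 3]))
    if se == 0:
        t = np.inf if coef[3] != 0 else 0.0
        p = 0.0 if coef[3] != 0 else 1.0
    else:
        t = float(coef[3] / se)
        p = float(2.0 * stats.t.sf(abs(t), dof))
    return InteractionRecord(
        g=g, m=m, theta_hat=float(coef[3]), se=se, t=t, p=p,
        beta_g=float(coef[1]), beta_m=float(coef[2]),
    )


def adjust_pvalues(p: np.ndarray, method: str = "holm") -> np.ndarray:
    """Holm step-down or Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"holm": "holm", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown correction {method!r}")
    return multipletests(p, method=key)[1]


def test_all_pairs(
    sel_G: SelectionResult,
    sel_M: SelectionResult,
    svG: SuperVariableMatrix,
    svM: SuperVariableMatrix,
    y: np.ndarray,
    correction: str = "holm",
    alpha: float = 0.05,
) -> list[InteractionRecord]:
    """Test every selected-G x selected-M pair; adjust across testable pairs.

    Returns |sel_G| x |sel_M| records. Rank-deficient pairs are flagged
    untestable and excluded from the multiplicity count.
    """
    records: list[InteractionRecord] = []
    for g in sel_G.selected:
        for m in sel_M.selected:
            rec = fit_interaction_model(svG.values[:, g], svM.values[:, m], y, g=g, m=m)
            records.append(rec)
    testable = [r for r in records if r.testable]
    if testable:
        adj = adjust_pvalues(np.array([r.p for r in testable]), method=correction)
        for r, a in zip(testable, adj):
            r.p_adj = float(a)
            r.significant = bool(a <= alpha)
    return records


def significant_records(records: list[InteractionRecord]) -> list[InteractionRecord]:
    return [r for r in records if r.significant]
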