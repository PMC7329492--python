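"""Per-view supervariable selection: weighted Lasso + stability selection.

Each view (genome G, metagenome M) is screened independently against the
shared phenotype y with the penalized problem

    min_beta  sum_i (y_i - xtil_i beta)^2  +  lam * sum_g rho_g |beta_g|,

where rho_g = 1/sqrt(s_g) penalizes short-lived dendrogram groups. The
weighted problem is solved exactly by rescaling column g by 1/rho_g,
solving a plain Lasso, and rescaling the coefficients back.

Stability selection wraps the Lasso path: on B half-subsamples the path is
run until q variables have entered, q = floor(sqrt(PFER * (2*cutoff-1) * p))
from the Meinshausen-Buhlmann per-family-error bound; groups whose
selection frequency reaches the cutoff are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso, LassoCV, lars_path

from .hierarchy import SuperVariableMatrix


@dataclass
class SelectionConfig:
    use_stability: bool = True
    B: int = 100
    cutoff: float = 0.6
    PFER: float = 10.0
    seed: int = 0
    k_folds: int = 5  # CV folds when stability is off

    def __post_init__(self) -> None:
        if not 0.5 < self.cutoff <= 1.0:
            raise ValueError("cutoff must lie in (0.5, 1]")
        if self.B < 2:
            raise ValueError("B must be at least 2")
        if self.PFER <= 0:
            raise ValueError("PFER must be positive")

    @classmethod
    def genome_defaults(cls, seed: int = 0) -> "SelectionConfig":
        return cls(B=100, cutoff=0.6, PFER=10.0, seed=seed)

    @classmethod
    def metagenome_defaults(cls, seed: int = 0) -> "SelectionConfig":
        return cls(B=300, cutoff=0.7, PFER=1.0, seed=seed)

    def q(self, p: int) -> int:
        """Path length bounding E[false selections] by PFER at this cutoff."""
        q = int(np.floor(np.sqrt(self.PFER * (2.0 * self.cutoff - 1.0) * p)))
        if q < 1:
            raise ValueError(
                f"PFER={self.PFER} too small for p={p} at cutoff={self.cutoff}: "
                f"computed path length q={q} < 1"
            )
        return min(q, p)


@dataclass
class SelectionResult:
    view: str
    selected: list[int]  # indices into the catalog
    frequencies: np.ndarray
    coefficients: np.ndarray
    config: SelectionConfig | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.size and (f.min() < 0 or f.max() > 1):
            raise ValueError("selection frequencies must lie in [0, 1]")
        self.frequencies = f

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def weighted_lasso(X: np.ndarray, y: np.ndarray, rho: np.ndarray, lam: float) -> np.ndarray:
    """Exact solution of the rho-weighted Lasso by column rescaling.

    At lam = 0 the (least-squares) solution is returned. The objective is
    the plain residual sum of squares plus ``lam * sum rho_g |beta_g|`` —
    no intercept; center y and the columns beforehand if one is needed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rho = np.asarray(rho, dtype=float).ravel()
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    if np.any(rho <= 0):
        raise ValueError("weights rho must be strictly positive")
    if X.shape[0] != y.size or X.shape[1] != rho.size:
        raise ValueError("shape mismatch between X, y and rho")
    if lam == 0:
        return np.linalg.lstsq(X, y, rcond=None)[0]
    Xs = X / rho
    n = X.shape[0]
    # sklearn's Lasso minimizes (1/2n)||y - Xb||^2 + alpha*||b||_1
    model = Lasso(alpha=lam / (2.0 * n), fit_intercept=False, max_iter=50_000, tol=1e-10)
    model.fit(Xs, y)
    return model.coef_ / rho


def lambda_max(X: np.ndarray, y: np.ndarray, rho: np.ndarray) -> float:
    """Smallest penalty at which the weighted-Lasso solution is all-zero."""
    X = np.asarray(X, dtype=float)
    return float(2.0 * np.max(np.abs(X.T @ np.asarray(y, float)) / np.asarray(rho, float)))


def _entry_order(X: np.ndarray, y: np.ndarray, q: int) -> np.ndarray:
    """Indices of the first q variables to enter the Lasso (LARS) path."""
    _alphas, _active, coefs = lars_path(
        X, y, method="lasso", max_iter=max(2 * q, q + 10), alpha_min=0.0
    )
    nonzero = coefs != 0
    entered = np.flatnonzero(nonzero.any(axis=1))
    first_step = np.array([int(np.argmax(nonzero[j])) for j in entered])
    order = entered[np.argsort(first_step, kind="stable")]
    return order[:q]


def stability_select(
    sv: SuperVariableMatrix | np.ndarray,
    y: np.ndarray,
    rho: np.ndarray | None = None,
    cfg: SelectionConfig | None = None,
    view: str = "",
) -> SelectionResult:
    """Stability selection over the weighted Lasso path.

    B subsamples of floor(N/2) samples without replacement; on each, the
    path of the rescaled design is run until q variables have entered.
    A group is selected when its selection frequency reaches cfg.cutoff.
    Columns are standardized internally; reported coefficients come from a
    least-squares refit of the selected groups on the original scale.
    Replicate r draws its subsample from seed + r.
    """
    if cfg is None:
        cfg = SelectionConfig()
    X = sv.values if isinstance(sv, SuperVariableMatrix) else np.asarray(sv, dtype=float)
    if rho is None:
        rho = sv.rho if isinstance(sv, SuperVariableMatrix) else np.ones(X.shape[1])
    rho = np.asarray(rho, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    q = cfg.q(p)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = ((X - mu) / sd) / rho
    yc = y - y.mean()
    half = n // 2
    hits = np.zeros(p)
    for r in range(cfg.B):
        rng = np.random.default_rng(cfg.seed + r)
        idx = rng.choice(n, size=half, replace=False)
        sel = _entry_order(Z[idx], yc[idx], q)
        hits[sel] += 1
    freq = hits / cfg.B
    selected = [int(j) for j in np.flatnonzero(freq >= cfg.cutoff)]
    coefs = np.zeros(p)
    if selected:
        beta = np.linalg.lstsq(X[:, selected] - X[:, selected].mean(axis=0), yc, rcond=None)[0]
        coefs[selected] = beta
    return SelectionResult(
        view=view, selected=selected, frequencies=freq, coefficients=coefs, config=cfg
    )


def choose_lambda_cv(
    X: np.ndarray, y: np.ndarray, rho: np.ndarray, k_folds: int = 5, seed: int = 0
) -> float:
    """One-standard-error cross-validation choice of the Lasso penalty.

    Fallback selector used when stability selection is disabled. The
    k-fold CV curve is computed on LassoCV's automatic logarithmic grid of
    the rescaled design, and the largest penalty whose mean CV error is
    within one standard error of the minimum is returned (the sparser,
    more conservative end of the plateau). The value is on the scale of
    the unnormalized objective (RSS + lam * sum rho|beta|).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if k_folds < 2:
        raise ValueError("k_folds must be at least 2")
    if X.shape[0] < k_folds:
        raise ValueError("fewer samples than folds")
    from sklearn.model_selection import KFold

    cv = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    model = LassoCV(cv=cv, fit_intercept=False, max_iter=20_000, tol=1e-8)
    model.fit(X / np.asarray(rho, float), y)
    mean_err = model.mse_path_.mean(axis=1)
    se_err = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(model.mse_path_.shape[1])
    best = int(np.argmin(mean_err))
    threshold = mean_err[best] + se_err[best]
    # alphas_ is decreasing: the first grid point under the threshold is the
    # largest penalty within one SE of the minimum
    idx = int(np.flatnonzero(mean_err <= threshold)[0])
    return float(model.alphas_[idx] * 2.0 * X.shape[0])


def lasso_select(
    sv: SuperVariableMatrix | np.ndarray,
    y: np.ndarray,
    rho: np.ndarray | None = None,
    cfg: SelectionConfig | None = None,
    view: str = "",
) -> SelectionResult:
    """Single weighted-Lasso fit at a cross-validated penalty (no stability)."""
    if cfg is None:
        cfg = SelectionConfig()
    X = sv.values if isinstance(sv, SuperVariableMatrix) else np.asarray(sv, dtype=float)
    if rho is None:
        rho = sv.rho if isinstance(sv, SuperVariableMatrix) else np.ones(X.shape[1])
    rho = np.asarray(rho, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    yc = y - y.mean()
    lam = choose_lambda_cv(Z, yc, rho, k_folds=cfg.k_folds, seed=cfg.seed)
    beta_std = weighted_lasso(Z, yc, rho, lam)
    selected = [int(j) for j in np.flatnonzero(beta_std != 0)]
    freq = (beta_std != 0).astype(float)
    coefs = beta_std / sd
    return SelectionResult(
        view=view, selected=selected, frequencies=freq, coefficients=coefs, config=cfg
    )


def select_supervariables(
    sv: SuperVariableMatrix, y: np.ndarray, cfg: SelectionConfig, view: str
) -> SelectionResult:
    """Dispatch to stability selection (default) or the CV Lasso fallback."""
    if cfg.use_stability:
        return stability_select(sv, y, cfg=cfg, view=view)
    return lasso_select(sv, y, cfg=cfg, view=view)
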