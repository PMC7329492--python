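"""Weighted Lasso and stability selection."""

import numpy as np
import pytest

from gmint.selection import (
    SelectionConfig,
    choose_lambda_cv,
    lambda_max,
    stability_select,
    weighted_lasso,
)


def _cd_weighted_lasso(X, y, rho, lam, n_iter=5000, tol=1e-12):
    """Direct cyclic coordinate descent on RSS + lam * sum rho|beta|."""
    n, p = X.shape
    beta = np.zeros(p)
    col_sq = (X**2).sum(axis=0)
    r = y - X @ beta
    for _ in range(n_iter):
        delta = 0.0
        for j in range(p):
            r += X[:, j] * beta[j]
            z = X[:, j] @ r
            thr = lam * rho[j] / 2.0
            new = np.sign(z) * max(abs(z) - thr, 0.0) / col_sq[j]
            delta = max(delta, abs(new - beta[j]))
            beta[j] = new
            r -= X[:, j] * beta[j]
        if delta < tol:
            break
    return beta


class TestWeightedLasso:
    def test_zero_penalty_is_least_squares(self, rng):
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        np.testing.assert_allclose(
            weighted_lasso(X, y, np.ones(4), 0.0),
            np.linalg.lstsq(X, y, rcond=None)[0],
            atol=1e-10,
        )

    def test_all_zero_at_lambda_max(self, rng):
        X = rng.normal(size=(60, 5))
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        y = rng.normal(size=60)
        y -= y.mean()
        rho = np.array([0.5, 1.0, 1.5, 2.0, 0.8])
        lam = lambda_max(X, y, rho)
        assert np.all(weighted_lasso(X, y, rho, lam * 1.0001) == 0)
        assert np.any(weighted_lasso(X, y, rho, lam * 0.9) != 0)

    def test_orthonormal_soft_thresholding(self, rng):
        # orthonormal design: beta_j = soft(x_j^T y, lam/2)
        A = rng.normal(size=(30, 5))
        Q, _ = np.linalg.qr(A)
        y = rng.normal(size=30)
        lam = 0.8
        z = Q.T @ y
        expected = np.sign(z) * np.maximum(np.abs(z) - lam / 2.0, 0.0)
        np.testing.assert_allclose(
            weighted_lasso(Q, y, np.ones(5), lam), expected, atol=1e-8
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_coordinate_descent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 40, 8
        X = rng.normal(size=(n, p))
        y = X[:, 0] - 2 * X[:, 3] + rng.normal(size=n)
        rho = rng.uniform(0.3, 3.0, size=p)
        for lam in (0.5, 2.0, 10.0):
            ours = weighted_lasso(X, y, rho, lam)
            oracle = _cd_weighted_lasso(X, y, rho, lam)
            np.testing.assert_allclose(ours, oracle, atol=1e-6)

    def test_rescaling_identity(self, rng):
        """Scaling columns and weights together leaves frequencies unchanged."""
        X = rng.normal(size=(40, 6))
        y = X[:, 1] + rng.normal(size=40)
        rho = np.ones(6)
        scale = rng.uniform(0.5, 2.0, size=6)
        b1 = weighted_lasso(X, y, rho, 3.0)
        b2 = weighted_lasso(X * scale, y, rho * scale, 3.0)
        np.testing.assert_allclose(b1, b2 * scale, atol=1e-8)

    def test_negative_penalty_rejected(self, rng):
        with pytest.raises(ValueError):
            weighted_lasso(rng.normal(size=(10, 2)), rng.normal(size=10), np.ones(2), -1.0)


class TestStabilitySelection:
    def test_view_defaults_match_published_settings(self):
        m = SelectionConfig.metagenome_defaults()
        assert (m.B, m.cutoff, m.PFER) == (300, 0.7, 1.0)
        g = SelectionConfig.genome_defaults()
        assert (g.B, g.cutoff, g.PFER) == (100, 0.6, 10.0)

    def test_planted_strong_group_is_selected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(200, 51))
            y = 5.0 * X[:, 17] + rng.normal(size=200)  # signal-to-noise 5
            cfg = SelectionConfig(B=50, cutoff=0.7, PFER=1.0, seed=seed)
            res = stability_select(X, y, cfg=cfg)
            if res.frequencies[17] >= 0.9 and 17 in res.selected:
                hits += 1
        assert hits == 10

    def test_pure_noise_respects_pfer_bound(self):
        total = 0
        for run in range(50):
            rng = np.random.default_rng(500 + run)
            X = rng.normal(size=(100, 50))
            y = rng.normal(size=100)
            cfg = SelectionConfig(B=50, cutoff=0.7, PFER=1.0, seed=run)
            total += stability_select(X, y, cfg=cfg).n_selected
        assert total / 50 <= 1.0

    def test_q_formula_and_too_small_pfer(self):
        cfg = SelectionConfig(B=10, cutoff=0.7, PFER=1.0)
        assert cfg.q(199) == int(np.floor(np.sqrt(1.0 * 0.4 * 199)))
        with pytest.raises(ValueError, match="q"):
            SelectionConfig(B=10, cutoff=0.51, PFER=0.01).q(5)

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(80, 20))
        y = X[:, 2] + rng.normal(size=80)
        cfg = SelectionConfig(B=20, cutoff=0.6, PFER=2.0, seed=9)
        r1 = stability_select(X, y, cfg=cfg)
        r2 = stability_select(X, y, cfg=cfg)
        np.testing.assert_array_equal(r1.frequencies, r2.frequencies)
        assert r1.selected == r2.selected

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SelectionConfig(cutoff=0.4)
        with pytest.raises(ValueError):
            SelectionConfig(B=1)
        with pytest.raises(ValueError):
            SelectionConfig(PFER=0.0)


class TestChooseLambdaCV:
    def test_strong_predictor_survives(self, rng):
        X = rng.normal(size=(100, 10))
        y = 4.0 * X[:, 3] + rng.normal(size=100)
        lam = choose_lambda_cv(X, y, np.ones(10), seed=0)
        beta = weighted_lasso(X, y, np.ones(10), lam)
        assert beta[3] != 0

    def test_pure_noise_yields_sparse_fits(self):
        sparse_runs = 0
        for seed in range(20):
            rng = np.random.default_rng(700 + seed)
            X = rng.normal(size=(60, 15))
            y = rng.normal(size=60)
            lam = choose_lambda_cv(X, y, np.ones(15), seed=seed)
            beta = weighted_lasso(X, y, np.ones(15), lam)
            if np.count_nonzero(beta) <= 2:
                sparse_runs += 1
        assert sparse_runs >= 16  # >= 80% of runs

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(50, 8))
        y = rng.normal(size=50)
        assert choose_lambda_cv(X, y, np.ones(8), seed=4) == choose_lambda_cv(
            X, y, np.ones(8), seed=4
        )

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            choose_lambda_cv(rng.normal(size=(3, 2)), rng.normal(size=3), np.ones(2), k_folds=5)
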