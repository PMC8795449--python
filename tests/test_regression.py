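"""Design-matrix building, standardization, and ridge estimation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Ridge

from famvae import (
    build_design,
    coefficient_quadrants,
    loo_cv_lambda,
    ridge_fit,
    standardize,
)


def toy_design(seed=0, n=20, p=3):
    rng = np.random.default_rng(seed)
    muts = [f"A{i + 2}S" for i in range(p - 1)]
    per_variant = {
        f"v{i}": [m for m in muts if rng.random() < 0.5] for i in range(n)
    }
    labels = {f"v{i}": int(i % 2) for i in range(n)}
    return build_design(per_variant, labels), rng


class TestBuildDesign:
    def test_shared_mutation_column(self):
        d = build_design(
            {"a": ["S60A"], "b": ["S60A", "ΔK70"], "c": []},
            {"a": 0, "b": 0, "c": 1},
        )
        frame = d.to_frame()
        assert list(frame.columns) == ["S60A", "ΔK70", "library"]
        assert frame["S60A"].sum() == 2
        assert frame.loc["c"].tolist() == [0, 0, 1]  # target-like variant

    def test_predictors_sorted_by_position(self):
        d = build_design({"a": ["T150L", "S60A", "ΔK70"]}, {"a": 0})
        assert d.predictor_names == ["S60A", "ΔK70", "T150L", "library"]

    def test_duplicate_ids_rejected(self):
        class Dup(dict):
            def __iter__(self):
                return iter(["a", "a"])

        with pytest.raises(ValueError, match="duplicate"):
            build_design(Dup({"a": []}), {"a": 0})

    def test_missing_library_label_rejected(self):
        with pytest.raises(ValueError, match="library label"):
            build_design({"a": []}, {})


class TestStandardize:
    def test_hand_computed(self):
        z = standardize(np.array([1.0, 2.0, 3.0]))
        assert np.allclose(z, [-1.0, 0.0, 1.0])

    def test_replicates_averaged_first(self):
        table = pd.DataFrame({"r1": [0.0, 2.0, 4.0], "r2": [2.0, 2.0, 2.0]})
        z = standardize(table)
        assert np.allclose(z, [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        y = np.array([3.0, -1.0, 0.5, 2.0])
        z = standardize(y)
        assert np.allclose(standardize(z), z)
        assert abs(z.mean()) < 1e-10 and abs(z.std(ddof=1) - 1) < 1e-10

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            standardize(np.ones(5))


class TestRidgeFit:
    def test_lambda_zero_matches_ols_normal_equations(self):
        d, rng = toy_design()
        z = standardize(rng.standard_normal(d.n))
        res = ridge_fit(d, z, lam=0.0)
        # independent oracle: OLS with explicit intercept column
        Xi = np.column_stack([np.ones(d.n), d.X])
        beta = np.linalg.solve(Xi.T @ Xi, Xi.T @ z)
        assert np.allclose(res.coefficients.values, beta[1:], atol=1e-8)
        assert res.intercept == pytest.approx(beta[0], abs=1e-8)

    def test_matches_sklearn_ridge(self):
        d, rng = toy_design(seed=3, n=40, p=6)
        z = standardize(rng.standard_normal(d.n))
        for lam in (0.1, 1.0, 10.0):
            res = ridge_fit(d, z, lam=lam)
            sk = Ridge(alpha=lam, fit_intercept=True).fit(d.X, z)
            assert np.allclose(res.coefficients.values, sk.coef_, atol=1e-8)
            assert res.intercept == pytest.approx(sk.intercept_, abs=1e-8)

    def test_huge_lambda_crushes_coefficients(self):
        d, rng = toy_design(seed=4)
        z = standardize(rng.standard_normal(d.n))
        b0 = np.linalg.norm(ridge_fit(d, z, lam=1e-9).coefficients.values)
        b_inf = np.linalg.norm(ridge_fit(d, z, lam=1e6).coefficients.values)
        assert b_inf < 1e-3 * b0

    def test_monotone_shrinkage(self):
        d, rng = toy_design(seed=5, n=30, p=5)
        z = standardize(rng.standard_normal(d.n))
        norms = [
            np.linalg.norm(ridge_fit(d, z, lam=lam).coefficients.values)
            for lam in (0.01, 0.1, 1.0, 10.0, 100.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_zero_response_zero_coefficients(self):
        d, _ = toy_design(seed=6)
        res = ridge_fit(d, np.zeros(d.n), lam=1.0)
        assert np.allclose(res.coefficients.values, 0.0)

    def test_collinear_at_lambda_zero_raises(self):
        per_variant = {f"v{i}": ["A2S", "C3W"] if i % 2 else []
                       for i in range(10)}
        labels = {f"v{i}": 0 if i % 2 else 1 for i in range(10)}
        d = build_design(per_variant, labels)
        z = standardize(np.arange(10.0))
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            ridge_fit(d, z, lam=0.0)

    def test_gradient_of_objective_vanishes_at_solution(self):
        d, rng = toy_design(seed=7, n=25, p=4)
        z = standardize(rng.standard_normal(d.n))
        res = ridge_fit(d, z, lam=2.5)
        beta = res.coefficients.values
        grad = (
            -2 * d.X.T @ (z - d.X @ beta - res.intercept) + 2 * 2.5 * beta
        )
        assert np.max(np.abs(grad)) < 1e-8


class TestLooCV:
    def test_returns_grid_member_and_tracks_noise(self):
        d, rng = toy_design(seed=8, n=60, p=8)
        beta_true = rng.standard_normal(d.p)
        z = d.X @ beta_true + 0.1 * rng.standard_normal(d.n)
        z = standardize(z)
        grid = (0.01, 1.0, 100.0)
        lam = loo_cv_lambda(d, z, grid=grid)
        assert lam in grid
        # near-noiseless data prefers light regularization
        assert lam < 100.0


class TestQuadrants:
    def make_results(self, betas_a, betas_t):
        d = build_design(
            {f"v{i}": [] for i in range(4)}, {f"v{i}": 0 for i in range(4)}
        )
        from famvae.regression import RegressionResult

        names = list(betas_a)
        return (
            RegressionResult(pd.Series(betas_a), 0.0, 1.0,
                             np.zeros(4), np.zeros(4)),
            RegressionResult(pd.Series(betas_t), 0.0, 1.0,
                             np.zeros(4), np.zeros(4)),
        )

    def test_sign_classification(self):
        ra, rt = self.make_results(
            {"A217I": 0.5, "A217T": -0.3, "G83A": 0.0, "library": -0.2},
            {"A217I": 0.4, "A217T": -0.1, "G83A": 0.0, "library": -0.1},
        )
        table = coefficient_quadrants(ra, rt).set_index("mutation")
        assert table.loc["A217I", "quadrant"] == "++"
        assert table.loc["A217T", "quadrant"] == "--"
        assert table.loc["G83A", "quadrant"] == "neutral"
        assert table.loc["library", "quadrant"] == "--"

    def test_sign_flip_flips_axis(self):
        ra, rt = self.make_results(
            {"X1Y": 0.5, "library": 0.1}, {"X1Y": 0.4, "library": 0.1}
        )
        ra_neg, _ = self.make_results(
            {"X1Y": -0.5, "library": 0.1}, {"X1Y": 0.4, "library": 0.1}
        )
        q = coefficient_quadrants(ra, rt).set_index("mutation")
        q_neg = coefficient_quadrants(ra_neg, rt).set_index("mutation")
        assert q.loc["X1Y", "quadrant"] == "++"
        assert q_neg.loc["X1Y", "quadrant"] == "-+"

    def test_mismatched_predictors_rejected(self):
        ra, _ = self.make_results({"X1Y": 0.5, "library": 0.1},
                                  {"X1Y": 0.4, "library": 0.1})
        _, rt = self.make_results({"Z2W": 0.4, "library": 0.1},
                                  {"Z2W": 0.4, "library": 0.1})
        with pytest.raises(ValueError, match="predictor"):
            coefficient_quadrants(ra, rt)
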