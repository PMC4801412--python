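"""VIF, semipartial regression, AICc model selection and Pearson r."""

import numpy as np
import pytest

import betascape as bs
from betascape.exceptions import InvalidSpecError, UndefinedStatisticError
from betascape.stats import PredictorSet


def lstsq_r2(X, y):
    """Independent QR-based R^2 oracle (intercept added here)."""
    X1 = np.column_stack([np.ones(len(y)), X])
    Q, R = np.linalg.qr(X1)
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X1 @ beta
    tss = ((y - y.mean()) ** 2).sum()
    return 1 - (resid @ resid) / tss


class TestVif:
    def test_orthogonal_predictors_give_one(self):
        n = 64
        t = np.arange(n)
        X = np.column_stack(
            [np.cos(2 * np.pi * t / n), np.sin(2 * np.pi * t / n), np.cos(4 * np.pi * t / n)]
        )
        out = bs.vif(PredictorSet(names=["a", "b", "c"], values=X))
        assert all(v == pytest.approx(1.0, abs=1e-10) for v in out.values())

    def test_duplicated_column_flags_infinite(self, rng):
        x = rng.normal(size=40)
        X = np.column_stack([x, x, rng.normal(size=40)])
        with pytest.warns(UserWarning, match="collinear"):
            out = bs.vif(PredictorSet(names=["x1", "x2", "y"], values=X))
        assert np.isinf(out["x1"]) and np.isinf(out["x2"])

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as smapi

        X = rng.normal(size=(200, 4))
        X[:, 1] += 0.8 * X[:, 0]
        X[:, 3] += 0.5 * X[:, 2] - 0.3 * X[:, 0]
        ours = bs.vif(PredictorSet(names=list("abcd"), values=X))
        Xc = smapi.add_constant(X)
        for j, name in enumerate("abcd"):
            expect = variance_inflation_factor(Xc, j + 1)
            assert ours[name] == pytest.approx(expect, rel=1e-8)


class TestPartialRegression:
    def test_filters_only_signal_gives_null_semipartials(self, rng):
        n = 500
        F = rng.normal(size=(n, 2))
        y = F @ np.array([2.0, -1.0]) + rng.normal(0, 0.1, n)
        X = rng.normal(size=(n, 3))
        res = bs.partial_regression(y, PredictorSet(names=list("abc"), values=X, filters=F))
        assert all(v < 0.01 for v in res.semipartial_r2.values())

    def test_orthogonal_closed_form(self, rng):
        """y = beta * x1 + noise with orthogonal predictors: the semipartial
        R2 of x1 approaches beta^2 var(x1) / var(y)."""
        n = 2000
        beta = 1.5
        X = rng.normal(size=(n, 3))
        y = beta * X[:, 0] + rng.normal(0, 1.0, n)
        res = bs.partial_regression(y, PredictorSet(names=["x1", "x2", "x3"], values=X))
        expect = beta**2 * X[:, 0].var() / y.var()
        assert res.semipartial_r2["x1"] == pytest.approx(expect, abs=0.03)
        assert res.semipartial_r2["x2"] < 0.01
        assert res.semipartial_r2["x3"] < 0.01

    def test_semipartial_equals_two_fit_difference(self, rng):
        n = 300
        X = rng.normal(size=(n, 4))
        X[:, 1] += 0.5 * X[:, 0]
        F = rng.normal(size=(n, 2))
        y = X @ np.array([1.0, 0.5, 0.0, -0.8]) + F[:, 0] + rng.normal(size=n)
        res = bs.partial_regression(y, PredictorSet(names=list("abcd"), values=X, filters=F))
        full_cols = np.column_stack([F, X])
        r2_full = lstsq_r2(full_cols, y)
        assert res.global_r2 == pytest.approx(r2_full, abs=1e-10)
        for j, name in enumerate("abcd"):
            reduced = np.column_stack([F, np.delete(X, j, axis=1)])
            expect = r2_full - lstsq_r2(reduced, y)
            assert res.semipartial_r2[name] == pytest.approx(expect, abs=1e-10)
            assert 0 <= res.semipartial_r2[name] <= res.global_r2 + 1e-12
            assert res.f_values[name] >= 0

    def test_nesting_monotonicity(self, rng):
        n = 200
        X = rng.normal(size=(n, 3))
        y = X[:, 0] + rng.normal(size=n)
        r2s = []
        for p in (1, 2, 3):
            res = bs.partial_regression(
                y, PredictorSet(names=[f"x{j}" for j in range(p)], values=X[:, :p])
            )
            r2s.append(res.global_r2)
        assert r2s[0] <= r2s[1] + 1e-12 <= r2s[2] + 2e-12

    def test_rank_deficiency_rejected(self, rng):
        x = rng.normal(size=50)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(InvalidSpecError):
            bs.partial_regression(rng.normal(size=50), PredictorSet(names=["a", "b"], values=X))


class TestModelSelection:
    def test_weights_sum_to_one_and_best_has_zero_delta(self, rng):
        n = 120
        X = rng.normal(size=(n, 3))
        y = X[:, 0] + rng.normal(size=n)
        rows = bs.model_selection(y, PredictorSet(names=list("abc"), values=X))
        assert len(rows) == 7  # 2^3 - 1 subsets
        assert sum(r.weight for r in rows) == pytest.approx(1.0, abs=1e-12)
        assert rows[0].delta_aicc == 0.0
        assert all(r.delta_aicc >= 0 for r in rows)

    def test_duplicated_predictors_tie(self, rng):
        x = rng.normal(size=100)
        z = rng.normal(size=100)
        y = x + rng.normal(0, 0.5, 100)
        X = np.column_stack([x, x.copy(), z])
        rows = bs.model_selection(y, PredictorSet(names=["x1", "x2", "z"], values=X))
        by_subset = {r.predictors: r.aicc for r in rows}
        assert abs(by_subset[("x1",)] - by_subset[("x2",)]) < 0.01
        assert abs(by_subset[("x1", "z")] - by_subset[("x2", "z")]) < 0.01

    def test_strong_single_predictor_dominates(self, rng):
        """With one strong true predictor, the best-AICc model contains it
        and carries most of the Akaike weight, across seeded replicates."""
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            n = 2000
            X = r.normal(size=(n, 4))
            y = 1.23 * X[:, 0] + r.normal(0, 1.0, n)  # R^2 ~ 0.6
            rows = bs.model_selection(y, PredictorSet(names=list("abcd"), values=X))
            best = rows[0]
            share = sum(rr.weight for rr in rows if "a" in rr.predictors)
            hits += ("a" in best.predictors) and share > 0.9
        assert hits == 20

    def test_single_predictor_coefficient_matches_correlation(self, rng):
        """With filters conditioning, the standardized coefficient of a lone
        predictor equals the correlation of the filter-residualized
        response and predictor, up to the scaling of the z-scores."""
        n = 400
        F = rng.normal(size=(n, 2))
        x = rng.normal(size=n)
        y = 0.8 * x + F[:, 0] + rng.normal(size=n)
        rows = bs.model_selection(y, PredictorSet(names=["x"], values=x[:, None], filters=F))
        coef = rows[0].coefficients["x"]

        def residualize(v):
            X1 = np.column_stack([np.ones(n), F])
            b, *_ = np.linalg.lstsq(X1, v, rcond=None)
            return v - X1 @ b

        ry, rx = residualize((y - y.mean()) / y.std(ddof=1)), residualize(
            (x - x.mean()) / x.std(ddof=1)
        )
        expect = (ry @ rx) / (rx @ rx)
        assert coef == pytest.approx(expect, rel=1e-8)

    def test_aicc_formula(self, rng):
        n = 80
        x = rng.normal(size=n)
        y = x + rng.normal(size=n)
        rows = bs.model_selection(y, PredictorSet(names=["x"], values=x[:, None]))
        yz = (y - y.mean()) / y.std(ddof=1)
        xz = (x - x.mean()) / x.std(ddof=1)
        X1 = np.column_stack([np.ones(n), xz])
        b, *_ = np.linalg.lstsq(X1, yz, rcond=None)
        rss = float(((yz - X1 @ b) ** 2).sum())
        K = 2
        expect = n * np.log(rss / n) + 2 * K + 2 * K * (K + 1) / (n - K - 1)
        assert rows[0].aicc == pytest.approx(expect, rel=1e-12)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert bs.pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert bs.pearson(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self, rng):
        x, y = rng.normal(size=100), rng.normal(size=100)
        expect = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert bs.pearson(x, y) == pytest.approx(expect, abs=1e-12)

    def test_joint_missing_handling(self, small_grid, rng):
        vals = rng.normal(size=small_grid.n_land)
        miss = np.zeros(small_grid.n_land, bool)
        miss[:3] = True
        f = bs.CellField(small_grid, vals, missing=miss)
        other = rng.normal(size=small_grid.n_land)
        assert bs.pearson(f, other) == pytest.approx(
            np.corrcoef(vals[~miss], other[~miss])[0, 1]
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            bs.pearson(np.ones(5), np.arange(5.0))
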