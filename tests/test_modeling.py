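"""Feature assembly, normalisation, splitting and ridge regression."""

import json

import numpy as np
import pytest
from scipy import optimize

import fruitcast as fc
from fruitcast.errors import (
    DegenerateDataError,
    DomainError,
    InsufficientDataError,
    SchemaError,
    SolverError,
)
from fruitcast.growth_curve import E500
from fruitcast.modeling import (
    FeatureRow,
    Normalizer,
    RidgeModel,
    SplitSpec,
    _solve_ridge,
    build_feature_table,
    cv_select_lambda,
    fit_ridge,
    predict,
    split_train_test,
)
from fruitcast.pipeline import AnchorRecord


def make_record(i, qc=True, harvest=150.0, scheme="E500", temp=19.0):
    return AnchorRecord(
        fruit_id=f"f-{i:03d}", cultivar="Zayda", scheme=scheme,
        anchor_taus=(200.0, 300.0, 500.0),
        anchor_values=(10.0 + i, 30.0 + i, 80.0 + i),
        r2=0.99, qc_pass=qc, extrapolated=False, suspect=False,
        harvest_mass=harvest, mean_temp=temp,
    )


def linear_rows(n=40, k=3, seed=0, noise=0.0, slope=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(100, 20, size=(n, k))
    w = np.arange(1, k + 1) if slope is None else np.asarray(slope)
    y = X @ w + 10 + noise * rng.normal(size=n)
    y = np.maximum(y, 1.0)
    return [FeatureRow(f"f-{i:03d}", tuple(X[i]), float(y[i])) for i in range(n)]


class TestFeatureTable:
    def test_shape_contract(self):
        rows = build_feature_table([make_record(i) for i in range(10)], E500)
        assert len(rows) == 10 and all(len(r.features) == 3 for r in rows)

    def test_mean_temp_adds_column(self):
        rows = build_feature_table(
            [make_record(i) for i in range(10)], E500, include_mean_temp=True
        )
        assert all(len(r.features) == 4 for r in rows)
        assert rows[0].features[-1] == pytest.approx(19.0)

    def test_qc_failures_excluded(self):
        recs = [make_record(i, qc=(i != 3)) for i in range(10)]
        assert len(build_feature_table(recs, E500)) == 9

    def test_missing_harvest_excluded(self):
        recs = [make_record(i, harvest=None if i == 0 else 150.0) for i in range(6)]
        assert len(build_feature_table(recs, E500)) == 5

    def test_mixed_schemes_rejected(self):
        recs = [make_record(0), make_record(1, scheme="E800")]
        with pytest.raises(SchemaError):
            build_feature_table(recs, E500)

    def test_rows_sorted_by_fruit_id(self):
        recs = [make_record(i) for i in (5, 1, 3)]
        rows = build_feature_table(recs, E500)
        assert [r.fruit_id for r in rows] == sorted(r.fruit_id for r in rows)


class TestNormalizer:
    def test_two_point_symmetry_sample_sd(self):
        norm = Normalizer.fit(np.array([[1.0], [3.0]]))
        # sample sd (ddof=1) of [1, 3] is sqrt(2)
        np.testing.assert_allclose(
            norm.transform(np.array([[1.0], [3.0]])).ravel(),
            [-1 / np.sqrt(2), 1 / np.sqrt(2)],
        )

    def test_training_features_standardised(self):
        rng = np.random.default_rng(2)
        X = rng.normal(50, 7, size=(30, 4))
        Z = Normalizer.fit(X).transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1, rtol=1e-12)

    def test_test_rows_use_training_stats(self):
        train = np.array([[0.0], [2.0]])
        norm = Normalizer.fit(train)
        # a value far outside training data is scaled by *training* stats
        assert norm.transform(np.array([[10.0]]))[0, 0] == pytest.approx(9 / np.sqrt(2))

    def test_zero_variance_feature_named(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.raises(DegenerateDataError, match="1"):
            Normalizer.fit(X)


class TestSplit:
    def test_80_20(self):
        rows = linear_rows(100)
        train, test = split_train_test(rows, SplitSpec(0.8, 1))
        assert len(train) == 80 and len(test) == 20

    def test_deterministic(self):
        rows = linear_rows(50)
        a = split_train_test(rows, SplitSpec(0.8, 9))
        b = split_train_test(rows, SplitSpec(0.8, 9))
        assert [r.fruit_id for r in a[0]] == [r.fruit_id for r in b[0]]

    def test_rounding_and_partition(self):
        rows = linear_rows(10)
        train, test = split_train_test(rows, SplitSpec(0.8, 0))
        assert len(train) == 8 and len(test) == 2
        ids = {r.fruit_id for r in train} | {r.fruit_id for r in test}
        assert ids == {r.fruit_id for r in rows}

    def test_too_few_rows(self):
        with pytest.raises(InsufficientDataError):
            split_train_test(linear_rows(4), SplitSpec(0.8, 0))


def ridge_objective(w, Xn, yc, lam):
    r = yc - Xn @ w
    return float(r @ r + lam * w @ w)


class TestRidge:
    def test_exact_line_lambda_zero(self):
        rows = [FeatureRow(f"f{i}", (float(x),), 2.0 * x) for i, x in enumerate([1, 2, 3, 4], 1)]
        model = fit_ridge(rows, 0.0)
        np.testing.assert_allclose(predict(model, rows), [r.target for r in rows], rtol=1e-10)

    def test_one_dimensional_closed_form_by_hand(self):
        # centred x = [1, -1], y = [2, -2], lambda = 2: w = sum(xy)/(sum(x^2)+lam) = 1
        w, b = _solve_ridge(np.array([[1.0], [-1.0]]), np.array([2.0, -2.0]), 2.0)
        assert w[0] == pytest.approx(1.0)
        assert b == pytest.approx(0.0)

    @pytest.mark.parametrize("lam", [0.0, 0.5, 3.0, 50.0])
    def test_matches_iterative_optimizer(self, lam):
        rng = np.random.default_rng(int(lam * 10) + 1)
        Xn = rng.normal(size=(30, 4))
        yc = rng.normal(size=30)
        yc -= yc.mean()
        w, _ = _solve_ridge(Xn, yc - 0, lam)
        res = optimize.minimize(
            ridge_objective, np.zeros(4), args=(Xn, yc, lam), method="BFGS",
            options={"gtol": 1e-12},
        )
        np.testing.assert_allclose(w, res.x, atol=1e-6)

    def test_lambda_zero_equals_ols(self):
        rows = linear_rows(25, noise=3.0, seed=5)
        model = fit_ridge(rows, 0.0)
        X = np.array([r.features for r in rows])
        y = np.array([r.target for r in rows])
        Xd = np.column_stack([np.ones(len(rows)), model.normalizer.transform(X)])
        beta = np.linalg.lstsq(Xd, y, rcond=None)[0]
        np.testing.assert_allclose(model.weights, beta[1:], rtol=1e-8)
        assert model.intercept == pytest.approx(beta[0], rel=1e-8)

    def test_shrinkage_monotone_in_lambda(self):
        rows = linear_rows(30, noise=5.0, seed=8)
        norms = [
            np.linalg.norm(fit_ridge(rows, lam).weights)
            for lam in [0.0, 0.1, 1.0, 10.0, 100.0, 1000.0]
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_collinear_at_lambda_zero_advises_regularisation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        rows = [
            FeatureRow(f"f{i}", (float(v), float(2 * v)), float(abs(v) + 1))
            for i, v in enumerate(x)
        ]
        with pytest.raises(SolverError, match="lambda"):
            fit_ridge(rows, 0.0)

    def test_negative_lambda_rejected(self):
        with pytest.raises(DomainError):
            fit_ridge(linear_rows(10), -1.0)


class TestPredict:
    def test_mean_feature_row_predicts_intercept(self):
        rows = linear_rows(20, noise=2.0, seed=3)
        model = fit_ridge(rows, 1.0)
        mean_row = FeatureRow("mean", tuple(model.normalizer.means), 100.0)
        assert predict(model, [mean_row])[0] == pytest.approx(model.intercept)

    def test_hand_matrix_arithmetic_three_rows(self):
        rows = [
            FeatureRow("a", (1.0, 0.0), 10.0),
            FeatureRow("b", (0.0, 1.0), 20.0),
            FeatureRow("c", (1.0, 1.0), 30.0),
        ]
        model = fit_ridge(rows, 0.5)
        X = np.array([r.features for r in rows])
        y = np.array([r.target for r in rows])
        Xn = model.normalizer.transform(X)
        w = np.linalg.solve(Xn.T @ Xn + 0.5 * np.eye(2), Xn.T @ (y - y.mean()))
        np.testing.assert_allclose(predict(model, rows), Xn @ w + y.mean(), rtol=1e-12)

    def test_schema_mismatch(self):
        model = fit_ridge(linear_rows(10, k=3), 1.0)
        with pytest.raises(SchemaError):
            predict(model, linear_rows(5, k=2))

    def test_leakage_guard_test_stats_never_refit(self):
        """Shifting/scaling the test rows must shift predictions exactly as the
        fixed training normaliser dictates — i.e. test statistics are unused."""
        rows = linear_rows(40, noise=2.0, seed=4)
        model = fit_ridge(rows[:30], 1.0)
        test = rows[30:]
        X = np.array([r.features for r in test])
        base = predict(model, test)
        shifted = [
            FeatureRow(r.fruit_id, tuple(np.asarray(r.features) + 5.0), r.target)
            for r in test
        ]
        delta = (5.0 / np.asarray(model.normalizer.sds)) @ np.asarray(model.weights)
        np.testing.assert_allclose(predict(model, shifted), base + delta, rtol=1e-10)


class TestCVSelection:
    def test_single_grid_value(self):
        rows = linear_rows(30, noise=1.0)
        assert cv_select_lambda(rows, [7.5], k_folds=5) == 7.5

    def test_noiseless_linear_selects_smallest_lambda(self):
        rows = linear_rows(60, noise=0.0, seed=6)
        lam = cv_select_lambda(rows, [0.01, 0.1, 1, 10, 100], k_folds=10, repeats=2, seed=1)
        assert lam == 0.01

    def test_row_order_invariance(self):
        rows = linear_rows(40, noise=4.0, seed=2)
        lam1 = cv_select_lambda(rows, [0.01, 1, 100], seed=3)
        lam2 = cv_select_lambda(rows[::-1], [0.01, 1, 100], seed=3)
        assert lam1 == lam2

    def test_fewer_rows_than_folds(self):
        with pytest.raises(InsufficientDataError):
            cv_select_lambda(linear_rows(8), [1.0], k_folds=10)


class TestPersistence:
    def test_json_round_trip(self):
        model = fit_ridge(linear_rows(20, noise=1.0), 2.0)
        back = RidgeModel.from_json(model.to_json())
        assert back == model

    def test_wrong_kind_rejected(self):
        with pytest.raises(SchemaError):
            RidgeModel.from_json(json.dumps({"model": "catboost"}))
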