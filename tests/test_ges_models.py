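import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from baltind import ges_models as gm


def _zmat(n, cols, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.standard_normal((n, len(cols))), columns=list(cols))


def _logistic_labels(zmat, beta, intercept=0.0, seed=0):
    rng = np.random.default_rng(seed)
    eta = intercept + zmat.to_numpy() @ np.asarray(beta)
    p = 1.0 / (1.0 + np.exp(-eta))
    return pd.Series((rng.random(len(p)) < p).astype(int), index=zmat.index)


def loglik_oracle(y, X):
    """Direct likelihood maximisation, independent of the IRLS path."""

    def nll(b):
        eta = X @ b
        return -np.sum(y * eta - np.logaddexp(0.0, eta))

    b0 = np.zeros(X.shape[1])
    res = minimize(nll, b0, method="BFGS", options={"gtol": 1e-10})
    return res.x


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        z = _zmat(10, ["A"])
        y = pd.Series([1] * 7 + [0] * 3, index=z.index)
        m = gm.fit_logistic(y, z, [])
        assert m.beta["const"] == pytest.approx(np.log(7 / 3), abs=1e-6)

    def test_matches_direct_likelihood_oracle(self):
        for seed in range(10):
            z = _zmat(120, ["A", "B"], seed=seed)
            y = _logistic_labels(z, [1.0, -0.5], 0.3, seed=seed)
            m = gm.fit_logistic(y, z, ["A", "B"])
            X = np.column_stack([np.ones(len(z)), z["A"], z["B"]])
            oracle = loglik_oracle(y.to_numpy(), X)
            np.testing.assert_allclose(
                m.beta[["const", "A", "B"]], oracle, atol=1e-4
            )

    def test_flipped_labels_negate_coefficients(self):
        z = _zmat(80, ["A"], seed=1)
        y = _logistic_labels(z, [1.2], seed=1)
        m1 = gm.fit_logistic(y, z, ["A"])
        m2 = gm.fit_logistic(1 - y, z, ["A"])
        np.testing.assert_allclose(m1.beta, -m2.beta, atol=1e-8)

    def test_aic_and_wald_identities(self):
        z = _zmat(60, ["A", "B"], seed=2)
        y = _logistic_labels(z, [0.8, 0.0], seed=2)
        m = gm.fit_logistic(y, z, ["A", "B"])
        assert m.aic == pytest.approx(2 * m.n_params - 2 * m.loglik, abs=1e-6)
        np.testing.assert_allclose(m.wald, (m.beta / m.se) ** 2, atol=1e-6)

    def test_complete_separation_flagged(self):
        z = _zmat(40, ["A"], seed=3)
        y = (z["A"] > 0).astype(int)
        m = gm.fit_logistic(y, z, ["A"])
        assert m.separation

    def test_small_class_rejected(self):
        z = _zmat(10, ["A"])
        y = pd.Series([1] * 9 + [0], index=z.index)
        with pytest.raises(ValueError, match="per class"):
            gm.fit_logistic(y, z, ["A"])

    def test_dataset_dummy_added(self):
        z = _zmat(60, ["A"], seed=4)
        y = _logistic_labels(z, [1.0], seed=4)
        ds = pd.Series(["north"] * 30 + ["south"] * 30, index=z.index)
        m = gm.fit_logistic(y, z, ["A"], dataset=ds)
        assert any(name.startswith("dataset_") for name in m.beta.index)


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        # exactly orthogonal, mean-zero columns
        a = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0, 1.0, -1.0])
        b = b - b @ a / (a @ a) * a
        z = pd.DataFrame({"A": a, "B": b})
        v = gm.vif_scores(z, ["A", "B"])
        np.testing.assert_allclose(v, [1.0, 1.0], atol=1e-12)

    def test_duplicated_predictor_infinite(self):
        z = _zmat(30, ["A"], seed=5)
        z["B"] = z["A"]
        v = gm.vif_scores(z, ["A", "B"])
        assert np.isinf(v).all()

    def test_correlation_point_eight_formula(self):
        # construct sample correlation exactly 0.8 via Gram-Schmidt
        rng = np.random.default_rng(6)
        x = rng.standard_normal(50)
        e = rng.standard_normal(50)
        x = (x - x.mean()) / x.std()
        e = e - e.mean()
        e = e - (e @ x) / (x @ x) * x
        e = e / e.std()
        y = 0.8 * x + np.sqrt(1 - 0.64) * e
        z = pd.DataFrame({"A": x, "B": y})
        v = gm.vif_scores(z, ["A", "B"])
        np.testing.assert_allclose(v, 1 / (1 - 0.64), atol=1e-9)

    def test_single_predictor_rejected(self):
        with pytest.raises(ValueError):
            gm.vif_scores(_zmat(10, ["A"]), ["A"])


class TestModelSearch:
    def test_recovers_strong_single_predictor(self):
        hits = 0
        for seed in range(40):
            z = _zmat(40, ["MeanSize", "a", "b", "c"], seed=seed)
            y = _logistic_labels(z, [1.5, 0, 0, 0], seed=seed)
            try:
                res = gm.aic_model_search(y, z, list(z.columns))
            except ValueError:
                continue  # degenerate class split
            hits += "MeanSize" in res.winner.predictors
        assert hits >= 32

    def test_parsimony_prefers_simpler_nested_model(self):
        # a useless orthogonal predictor: complex model has ~same loglik,
        # AIC two higher, LRT p ~ 1 -> intercept-only wins
        z = pd.DataFrame({"noise": [1.0, -1.0] * 10})
        y = pd.Series([1, 1, 0, 0] * 5, index=z.index)  # balanced within noise
        res = gm.aic_model_search(y, z, ["noise"], max_terms=1)
        assert res.winner.predictors == []

    def test_vif_screening_drops_collinear_subsets(self):
        z = _zmat(50, ["A"], seed=7)
        z["B"] = z["A"] * 1.0000001
        y = _logistic_labels(z[["A"]], [1.0], seed=7)
        res = gm.aic_model_search(y, z, ["A", "B"], max_terms=2)
        assert all(set(m.predictors) != {"A", "B"} for m in res.ranked)

    def test_search_is_deterministic(self):
        z = _zmat(40, ["A", "B"], seed=8)
        y = _logistic_labels(z, [1.0, 0.0], seed=8)
        r1 = gm.aic_model_search(y, z, ["A", "B"])
        r2 = gm.aic_model_search(y, z, ["A", "B"])
        assert r1.winner.predictors == r2.winner.predictors
        assert r1.winner.aic == r2.winner.aic

    def test_noise_predictor_raises_aic_on_average(self):
        deltas = []
        for seed in range(60):
            z = _zmat(50, ["A", "noise"], seed=seed)
            y = _logistic_labels(z, [1.0, 0.0], seed=seed)
            try:
                m1 = gm.fit_logistic(y, z, ["A"])
                m2 = gm.fit_logistic(y, z, ["A", "noise"])
            except ValueError:
                continue
            deltas.append(m2.aic - m1.aic)
        assert np.mean(deltas) > 0


class TestClassificationMetrics:
    def test_perfect_separation_fixture(self):
        z = pd.DataFrame({"A": [-2.0, -1.5, -1.0, 1.0, 1.5, 2.0]})
        y = pd.Series([0, 0, 0, 1, 1, 1], index=z.index)
        m = gm.fit_logistic(y, z, ["A"])
        met = gm.classification_metrics(m, y, z)
        assert met.sensitivity == met.specificity == met.overall == 100.0

    def test_intercept_only_predicts_majority(self):
        z = _zmat(10, ["A"], seed=9)
        y = pd.Series([1] * 7 + [0] * 3, index=z.index)
        m = gm.fit_logistic(y, z, [])
        met = gm.classification_metrics(m, y, z)
        assert met.overall == 70.0
        assert met.sensitivity == 100.0
        assert met.specificity == 0.0

    def test_matches_brute_force_confusion(self):
        z = _zmat(100, ["A", "B"], seed=10)
        y = _logistic_labels(z, [1.0, -0.7], seed=10)
        m = gm.fit_logistic(y, z, ["A", "B"])
        met = gm.classification_metrics(m, y, z)
        p = m.predict(z)
        pred = (p >= 0.5).astype(int)
        tp = ((pred == 1) & (y == 1)).sum()
        tn = ((pred == 0) & (y == 0)).sum()
        assert met.overall == pytest.approx(100 * (tp + tn) / len(y))
        assert met.sensitivity == pytest.approx(100 * tp / (y == 1).sum())
        assert met.specificity == pytest.approx(100 * tn / (y == 0).sum())


class TestMSTS:
    @pytest.mark.parametrize(
        "z_size,z_stock,expected",
        [
            (1.0, 1.0, "green"),
            (0.0, 0.0, "green"),  # threshold itself counts as adequate
            (1.0, -1.0, "orange_size_only"),
            (-1.0, 1.0, "orange_stock_only"),
            (-1.0, -2.0, "red"),
        ],
    )
    def test_quadrants(self, z_size, z_stock, expected):
        assert gm.msts_classify(z_size, z_stock).status == expected

    def test_missing_component_undetermined(self):
        assert gm.msts_classify(np.nan, 1.0).status == "undetermined"

    def test_monotone_in_size(self):
        order = {"red": 0, "orange_stock_only": 1, "green": 2}
        for z_stock in (-1.0, 1.0):
            statuses = [
                gm.msts_classify(z, z_stock).status for z in (-2.0, -0.5, 0.5, 2.0)
            ]
            ranks = [
                order.get(s, 1 if "orange" in s else None) for s in statuses
            ]
            assert ranks == sorted(ranks)

    def test_threshold_override(self):
        assert gm.msts_classify(0.5, 0.5, threshold=1.0).status == "red"

    def test_bad_stock_metric_rejected(self):
        with pytest.raises(ValueError):
            gm.msts_classify(0, 0, stock_metric="CB")
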