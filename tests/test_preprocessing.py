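import numpy as np
import pandas as pd
import pytest

import baltind
from baltind import preprocessing as prep
from baltind.io import RefConKind, RefConWindow
from baltind.synthetic_data import GeneratorConfig, default_traits, generate_dataset


def _series(values, start=2000):
    return pd.Series(values, index=range(start, start + len(values)), dtype=float)


class TestBoxCox:
    def test_fixed_lambda_one_is_shift_by_one(self):
        s = _series([1.0, 2.5, 4.0, 7.0, 9.0])
        tr = prep.boxcox_fit_transform(s, lmbda=1.0)
        np.testing.assert_allclose(tr.transformed, s - 1.0)

    def test_fixed_lambda_zero_is_log(self):
        s = _series([1.0, 2.5, 4.0, 7.0, 9.0])
        tr = prep.boxcox_fit_transform(s, lmbda=0.0)
        np.testing.assert_allclose(tr.transformed, np.log(s))

    def test_mle_recovers_log_for_lognormal_data(self):
        rng = np.random.default_rng(42)
        s = _series(np.exp(rng.standard_normal(200)), start=0)
        tr = prep.boxcox_fit_transform(s)
        assert -0.3 < tr.lmbda < 0.3

    def test_inverse_roundtrip(self):
        rng = np.random.default_rng(1)
        s = _series(np.exp(rng.standard_normal(50) * 0.5 + 2), start=0)
        tr = prep.boxcox_fit_transform(s)
        back = tr.inverse(tr.transformed.to_numpy())
        np.testing.assert_allclose(back, s.to_numpy(), rtol=1e-8)

    def test_zeros_handled_by_half_min_positive_shift(self):
        s = _series([0.0, 0.4, 1.0, 2.0, 3.0])
        tr = prep.boxcox_fit_transform(s, lmbda=0.0)
        assert tr.shift == 0.2
        assert np.isfinite(tr.transformed).all()

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            prep.boxcox_fit_transform(_series([3.0] * 8))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            prep.boxcox_fit_transform(_series([1.0, 2.0, 3.0]))


class TestKSNormality:
    def test_short_series_not_eligible(self):
        res = prep.ks_normality(_series([1, 2, 3, 4, 5, 6]))
        assert not res.eligible
        assert res.pvalue is None

    def test_normal_samples_rarely_rejected(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(2000)
            if prep.ks_normality(pd.Series(x)).pvalue > 0.05:
                hits += 1
        assert hits >= 90

    def test_exponential_samples_always_rejected(self):
        for seed in range(100):
            x = np.random.default_rng(seed).exponential(size=2000)
            assert prep.ks_normality(pd.Series(x)).pvalue < 0.01


class TestEvfImpute:
    def test_gap_free_matrix_returned_unchanged(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(10, 3)))
        res = prep.evf_impute(m)
        pd.testing.assert_frame_equal(res.completed, m)
        assert res.n_iter == 0

    def test_rank_one_gap_restored_exactly(self):
        col1 = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        m = pd.DataFrame({"a": col1, "b": 2 * col1})
        truth = m.loc[4, "b"]
        m.loc[4, "b"] = np.nan
        res = prep.evf_impute(m)
        assert res.completed.loc[4, "b"] == pytest.approx(truth, abs=1e-4)
        assert res.imputed.loc[4, "b"]
        # observed cells untouched
        obs = ~res.imputed
        pd.testing.assert_frame_equal(res.completed[obs], m[obs])

    def test_matches_regression_oracle_on_correlated_data(self):
        # single gap in rho=0.9 bivariate data: EVF should track the OLS
        # prediction from the other column, and beat mean imputation about
        # as often as that optimal predictor does.  With prediction-error
        # SD ~= sqrt(2(1-rho)) = 0.45 and a N(0,1) gap value, the win
        # probability is (2/pi) arctan(1/0.45) ~= 0.74; assert above its
        # 2-SE lower bound over 200 seeds.
        wins, err_evf_sum, err_ols_sum = 0, 0.0, 0.0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(20)
            y = 0.9 * x + np.sqrt(1 - 0.81) * rng.standard_normal(20)
            m = pd.DataFrame({"x": x, "y": y})
            truth = m.loc[7, "y"]
            m.loc[7, "y"] = np.nan
            res = prep.evf_impute(m)
            obs = m.dropna()
            ols = np.polyval(np.polyfit(obs["x"], obs["y"], 1), x[7])
            err_evf = abs(res.completed.loc[7, "y"] - truth)
            err_evf_sum += err_evf
            err_ols_sum += abs(ols - truth)
            wins += err_evf < abs(obs["y"].mean() - truth)
        assert err_evf_sum <= 1.1 * err_ols_sum
        assert wins >= 0.67 * 200

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(15, 4)))
        m.iloc[2, 1] = np.nan
        m.iloc[9, 3] = np.nan
        once = prep.evf_impute(m).completed
        twice = prep.evf_impute(once).completed
        np.testing.assert_allclose(once, twice, atol=1e-6)

    def test_too_sparse_column_rejected(self):
        m = pd.DataFrame(np.ones((10, 2)))
        m.iloc[:5, 0] = np.nan
        with pytest.raises(ValueError, match="observed"):
            prep.evf_impute(m)

    def test_single_column_rejected(self):
        with pytest.raises(ValueError, match="two"):
            prep.evf_impute(pd.DataFrame({"a": [1.0, 2, 3]}))


class TestStandardize:
    def _baseline(self):
        return prep.Baseline(
            mu=10.0, sigma=2.0, kind=RefConKind.entire, window=None, n_years=10
        )

    def test_mean_maps_to_zero_and_two_sigma_to_two(self):
        z = prep.standardize(_series([10.0, 14.0]), self._baseline())
        assert z.values.tolist() == [0.0, 2.0]

    def test_whole_series_baseline_gives_mean_zero_sd_one(self):
        rng = np.random.default_rng(5)
        s = _series(rng.normal(3, 2, 30), start=1980)
        b = prep.make_baseline(s)
        z = prep.standardize(s, b).values
        assert z.mean() == pytest.approx(0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1, abs=1e-9)

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        s = _series(rng.normal(size=20), start=1980)
        za = prep.standardize(s, prep.make_baseline(s)).values
        t = 3.5 * s + 7.0
        zb = prep.standardize(t, prep.make_baseline(t)).values
        np.testing.assert_allclose(za, zb, atol=1e-10)

    def test_refcon_window_restricts_baseline_years(self):
        s = _series(np.r_[np.ones(10), 5 * np.ones(10)], start=1980)
        s += np.linspace(0, 0.1, 20)  # avoid constant window
        w = RefConWindow("D", RefConKind.refcon_chl, 1980, 1989)
        b = prep.make_baseline(s, window=w)
        assert b.n_years == 10
        assert b.mu == pytest.approx(s.iloc[:10].mean())

    def test_short_window_rejected(self):
        s = _series([1.0, 2, 3, 4], start=1980)
        with pytest.raises(ValueError, match="years"):
            prep.make_baseline(s)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            prep.Baseline(0.0, 0.0, RefConKind.entire, None, 10)


class TestCvPercent:
    def test_constant_series_zero(self):
        assert prep.cv_percent([10, 10, 10]) == 0.0

    def test_two_point_formula(self):
        assert prep.cv_percent([8, 12]) == pytest.approx(28.2843, abs=1e-3)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            prep.cv_percent([-1.0, 1.0])


class TestPipelineProperties:
    def test_zscores_of_generated_indicators_pass_normality(self):
        # after Box-Cox + whole-series z-scoring the lognormal-like series
        # should look normal (p > 0.2) in the majority of seeds
        hits = 0
        for seed in range(10):
            cfg = GeneratorConfig(seed=seed, n_years=30)
            samples, _ = generate_dataset(cfg)
            wide = baltind.compute_indicators(
                samples, default_traits(cfg)
            ).droplevel("dataset")
            z, _, _, _ = prep.zscore_matrix(wide)
            res = prep.ks_normality(z["TZB"])
            hits += res.pvalue > 0.2
        assert hits >= 6

    def test_zscore_matrix_imputes_missing_years(self):
        cfg = GeneratorConfig(seed=11, n_years=30, missing_year_prob=0.1)
        samples, truth = generate_dataset(cfg)
        wide = baltind.compute_indicators(samples, default_traits(cfg)).droplevel(
            "dataset"
        )
        wide = wide.reindex(range(cfg.start_year, cfg.start_year + cfg.n_years))
        assert len(truth.missing_years) > 0
        z, _, _, imputed = prep.zscore_matrix(wide)
        assert not z.isna().any().any()
        assert imputed.loc[list(truth.missing_years)].all().all()
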