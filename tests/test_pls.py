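"""PLS core: factor extraction, VIP, block CV, diagnostics, metrics, splitting."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ramanqc as rq
from ramanqc import pls
from ramanqc.synth import API_PEAK_CENTERS


def _random_xy(seed, n=20, p=8, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


def _simpls(X, y, n_lv):
    """Independent SIMPLS-style oracle (covariance deflation, single response)."""
    X = X - X.mean(axis=0)
    y = y - y.mean()
    s = X.T @ y
    n, p = X.shape
    R = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    V = np.zeros((p, n_lv))
    for a in range(n_lv):
        r = s.copy()
        t = X @ r
        t -= t.mean()
        tn = np.linalg.norm(t)
        t /= tn
        r /= tn
        pvec = X.T @ t
        qa = float(y @ t)
        v = pvec.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pvec)
        v /= np.linalg.norm(v)
        s -= v * (v @ s)
        R[:, a], T[:, a], P[:, a], q[a], V[:, a] = r, t, pvec, qa, v
    coef = R @ q
    return coef, T


class TestFitPLS:
    def test_single_factor_exact_when_y_is_one_column(self):
        # orthogonal columns: the informative one is uncontaminated, so a
        # single latent variable reproduces the response exactly
        rng = np.random.default_rng(0)
        raw = rng.normal(size=(15, 6))
        Q, _ = np.linalg.qr(raw - raw.mean(axis=0))  # centered, orthonormal columns
        X = Q
        y = 2.5 * X[:, 3]
        fit = pls.fit_pls(X, y, 1)
        np.testing.assert_allclose(pls.predict(fit, X), y, atol=1e-8)
        r2, _, _ = pls.regression_metrics(y, pls.predict(fit, X))
        assert r2 == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_full_rank_equals_least_squares(self, seed):
        X, y = _random_xy(seed, n=20, p=8, noise=0.3)
        fit = pls.fit_pls(X, y, 8)
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        np.testing.assert_allclose(fit.coef, beta, atol=1e-6)

    @pytest.mark.parametrize("seed", [4, 5])
    def test_matches_simpls_oracle_predictions(self, seed):
        X, y = _random_xy(seed, n=20, p=8, noise=0.5)
        for a in (1, 2, 3):
            fit = pls.fit_pls(X, y, a)
            coef, T = _simpls(X, y, a)
            pred_simpls = (X - X.mean(axis=0)) @ coef + y.mean()
            np.testing.assert_allclose(pls.predict(fit, X), pred_simpls, atol=1e-6)
            # scores span the same subspace (columns match up to sign/scale)
            Tn = fit.scores / np.linalg.norm(fit.scores, axis=0)
            for k in range(a):
                assert abs(abs(Tn[:, k] @ T[:, k]) - 1.0) < 1e-6

    def test_matches_sklearn_reference(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = _random_xy(11, n=30, p=10, noise=0.4)
        fit = pls.fit_pls(X, y, 3)
        ref = sklearn.PLSRegression(n_components=3, scale=False).fit(X, y)
        np.testing.assert_allclose(
            pls.predict(fit, X), ref.predict(X).ravel(), atol=1e-6
        )

    def test_scores_orthogonal_and_weights_normalised(self):
        X, y = _random_xy(6, n=25, p=12, noise=0.2)
        fit = pls.fit_pls(X, y, 5)
        G = fit.scores.T @ fit.scores
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)
        np.testing.assert_allclose(np.linalg.norm(fit.weights, axis=0), 1.0, atol=1e-10)

    def test_zero_variance_x_raises(self):
        with pytest.raises(pls.NumericalDegeneracyError):
            pls.fit_pls(np.ones((10, 5)), np.arange(10.0), 1)

    def test_n_lv_beyond_rank_limit_rejected(self):
        X, y = _random_xy(7, n=6, p=3)
        with pytest.raises(ValueError):
            pls.fit_pls(X, y, 6)


class TestPredict:
    def test_training_rows_reproduce_fitted_values(self):
        X, y = _random_xy(8, noise=0.3)
        fit = pls.fit_pls(X, y, 3)
        np.testing.assert_allclose(
            pls.predict(fit, X), (X - fit.x_mean) @ fit.coef + fit.y_mean, atol=1e-12
        )

    def test_mean_row_predicts_mean_response(self):
        X, y = _random_xy(9, noise=0.3)
        fit = pls.fit_pls(X, y, 2)
        assert pls.predict(fit, X.mean(axis=0)[None, :])[0] == pytest.approx(
            y.mean(), abs=1e-10
        )

    def test_variable_count_mismatch_raises(self):
        X, y = _random_xy(10)
        fit = pls.fit_pls(X, y, 2)
        with pytest.raises(ValueError):
            pls.predict(fit, X[:, :5])


class TestVIP:
    @pytest.mark.parametrize("seed,n_lv", [(0, 1), (1, 3), (2, 5)])
    def test_squared_vip_sums_to_variable_count(self, seed, n_lv):
        X, y = _random_xy(seed, n=25, p=12, noise=0.5)
        fit = pls.fit_pls(X, y, n_lv)
        vip = pls.vip_scores(fit)
        assert np.sum(vip**2) == pytest.approx(12.0, abs=1e-8)

    def test_single_lv_closed_form(self):
        X, y = _random_xy(3, n=20, p=6, noise=0.5)
        fit = pls.fit_pls(X, y, 1)
        vip = pls.vip_scores(fit)
        w = fit.weights[:, 0]
        expected = np.abs(w) * np.sqrt(6.0) / np.linalg.norm(w)
        np.testing.assert_allclose(vip, expected, atol=1e-10)

    def test_top_vip_channels_coincide_with_api_peaks(self):
        # only API channels carry response information in a low-noise study
        cfg = rq.SyntheticBatchConfig(
            seed=0, noise_sd=0.1, baseline_amplitude=0.0, excipient_rsd_pct=0.0,
            api_sampling_rsd_pct=0.0, high_dose_extra_cv=0.0, assay_rsd_pct=0.0,
        )
        study = rq.generate_calibration_study(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = rq.RamanContentModel.from_study(
                study, n_lv=2, vip_threshold=0.0
            ).fit()
        vip = res.vip
        top = study.wavenumbers[np.argsort(vip)[-30:]]
        # every strong channel lies within one band-width of a configured API peak
        assert all(min(abs(t - c) for c in API_PEAK_CENTERS) <= 16.0 for t in top)

    def test_threshold_zero_keeps_everything(self):
        vip = np.array([0.1, 0.9, 1.5])
        assert pls.select_variables(vip, 0.0).all()

    def test_uniform_vip_is_one_and_nothing_dropped(self):
        # sum VIP^2 = p forces VIP = 1 everywhere when all are equal
        vip = np.ones(40)
        assert pls.select_variables(vip, 0.8).all()

    def test_dropping_all_variables_raises(self):
        with pytest.raises(ValueError):
            pls.select_variables(np.full(5, 0.1), 0.8)

    def test_selection_improves_cv_on_planted_signal(self):
        # 20 informative channels + 280 noise channels: VIP pruning helps
        rng = np.random.default_rng(12)
        n = 60
        y = np.tile([2.0, 4.0, 6.0, 8.0, 10.0], 12) + rng.normal(size=n) * 0.1
        loading = rng.uniform(0.5, 1.5, size=20)
        X = np.hstack([np.outer(y, loading) + rng.normal(size=(n, 20)) * 0.2,
                       rng.normal(size=(n, 280)) * 3.0])
        cv_pre = pls.block_cv(X, y, 3, 10)
        fit = pls.fit_pls(X, y, 2)
        keep = pls.select_variables(pls.vip_scores(fit), 0.8)
        cv_post = pls.block_cv(X[:, keep], y, 3, 10)
        assert cv_post.rmsecv.min() <= cv_pre.rmsecv.min()


class TestBlockCV:
    def test_50_samples_block_10_gives_5_folds_each_once(self):
        X, y = _random_xy(13, n=50, p=6, noise=0.5)
        cv = pls.block_cv(X, y, 3, 10)
        assert cv.fold_bounds == [(0, 10), (10, 20), (20, 30), (30, 40), (40, 50)]
        assert np.all(np.isfinite(cv.predictions))

    def test_block_size_equal_n_rejected(self):
        X, y = _random_xy(14, n=20, p=5)
        with pytest.raises(ValueError):
            pls.block_cv(X, y, 2, 20)

    def test_noiseless_linear_set_has_tiny_rmsecv_at_one_lv(self):
        rng = np.random.default_rng(15)
        y = np.repeat([2.0, 4.0, 6.0, 8.0, 10.0], 10)
        spectrum = rng.uniform(0.5, 2.0, size=40)
        X = np.outer(y, spectrum)
        cv = pls.block_cv(X, y, 1, 10)
        assert cv.rmsecv[0] < 1e-6


class TestChooseNLV:
    def test_v_curve_picks_argmin(self):
        assert pls.choose_n_lv(np.array([5.0, 2.0, 1.0, 1.5, 2.0])) == 3

    def test_flat_curve_picks_one(self):
        assert pls.choose_n_lv(np.ones(6)) == 1

    def test_tie_breaks_toward_fewer(self):
        assert pls.choose_n_lv(np.array([1.0, 1.0, 0.999]), rel_tol=0.02) == 1

    def test_one_se_rule_tolerates_noisy_tail(self):
        rmsecv = np.array([5.0, 2.0, 1.00, 0.97, 0.99])
        se = np.full(5, 0.05)
        assert pls.choose_n_lv(rmsecv, se=se) == 3


class TestOutlierDiagnostics:
    def test_centroid_sample_has_zero_t2(self):
        X, y = _random_xy(16, n=30, p=10, noise=0.3)
        fit = pls.fit_pls(X, y, 3)
        d = pls.outlier_diagnostics(fit, fit.x_mean[None, :])
        assert d.t2[0] == pytest.approx(0.0, abs=1e-16)

    def test_row_in_model_plane_has_zero_q(self):
        X, y = _random_xy(17, n=30, p=10, noise=0.3)
        fit = pls.fit_pls(X, y, 3)
        # a synthetic row built inside the span of the loadings
        row = fit.x_mean + fit.loadings @ np.array([1.0, -2.0, 0.5])
        d = pls.outlier_diagnostics(fit, row[None, :])
        assert d.q[0] == pytest.approx(0.0, abs=1e-16)

    def test_planted_noisy_test_spectrum_has_max_q_and_is_flagged(self, fitted_default):
        study, train, test, results = fitted_default
        Xte = study.spectra[test].copy()
        rng = np.random.default_rng(99)
        # ten times the generator's replicate noise, after 5-replicate averaging
        Xte[7] += rng.normal(size=Xte.shape[1]) * (10 * 2.0 / np.sqrt(5))
        d = results.diagnostics(Xte)
        assert int(np.argmax(d.q)) == 7
        assert bool(d.flagged[7])

    def test_flag_consistency(self, fitted_default):
        _, _, _, results = fitted_default
        d = results.train_diagnostics
        np.testing.assert_array_equal(
            d.flagged, (d.t2 > d.t2_limit) | (d.q > d.q_limit)
        )
        assert np.all(d.t2 >= 0) and np.all(d.q >= 0)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.arange(10.0)
        r2, rmse, bias = pls.regression_metrics(y, y)
        assert (r2, rmse, bias) == (pytest.approx(1.0), 0.0, 0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(c=st.floats(-10, 10), seed=st.integers(0, 100))
    def test_constant_offset_closed_form(self, c, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=12)
        _, rmse, bias = pls.regression_metrics(y, y + c)
        assert rmse == pytest.approx(abs(c), abs=1e-12)
        assert bias == pytest.approx(c, abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 500))
    def test_rmse_bounds_bias_and_decomposes(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=10)
        yhat = y + rng.normal(size=10)
        _, rmse, bias = pls.regression_metrics(y, yhat)
        assert rmse >= abs(bias) - 1e-12
        resid = yhat - y
        assert rmse**2 == pytest.approx(bias**2 + resid.var(), abs=1e-10)

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            pls.regression_metrics(np.array([]), np.array([]))


class TestSplit:
    def test_default_study_split_is_50_15_with_quota(self, default_study):
        train, test = pls.split_train_test(
            default_study.dose_mg, rng=np.random.default_rng(0)
        )
        assert (train.size, test.size) == (50, 15)
        assert np.intersect1d(train, test).size == 0
        assert np.union1d(train, test).size == 65
        for d in (2.0, 4.0, 6.0, 8.0, 10.0):
            n_d = np.count_nonzero(default_study.dose_mg[test] == d)
            assert 2 <= n_d <= 4

    def test_zero_test_size_rejected(self, default_study):
        with pytest.raises(ValueError):
            pls.split_train_test(default_study.dose_mg, n_test=0)

    def test_infeasible_quota_rejected(self, default_study):
        with pytest.raises(ValueError):
            pls.split_train_test(default_study.dose_mg, n_test=30, per_dose_quota=(2, 4))

    def test_same_seed_same_split(self, default_study):
        a = pls.split_train_test(default_study.dose_mg, rng=7)
        b = pls.split_train_test(default_study.dose_mg, rng=7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestStudyLevelProperties:
    def test_report_rmse_bounds_bias_on_every_split(self, seed_sweep):
        for run in seed_sweep:
            rep = run["report"]
            assert rep.rmsec >= abs(rep.bias_cal) - 1e-9
            assert rep.rmsecv >= abs(rep.bias_cv) - 1e-9
            assert rep.rmsep >= abs(rep.bias_pred) - 1e-9

    def test_calibration_fits_better_than_validation_in_expectation(self, seed_sweep):
        rmsec = np.mean([r["report"].rmsec for r in seed_sweep])
        rmsecv = np.mean([r["report"].rmsecv for r in seed_sweep])
        assert rmsec < rmsecv
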