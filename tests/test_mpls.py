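import json

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from nirseed.io import GridError
from nirseed.mpls import MPLS, CVPlan, MPLSResults
from nirseed.preprocess import MathTreatment
from nirseed.synthetic import BandModel, SyntheticConfig, generate_spectrum


def rank_one_instance(n=30, seed=0):
    """Spectra whose only variation is one analyte band: y is exactly
    linear in the band height and one PLS factor fits it perfectly."""
    cfg = SyntheticConfig(tmq_bands=(BandModel(1500.0, 10.0, 0.01),),
                          grid=np.arange(1100.0, 2500.0, 2.0))
    rng = np.random.default_rng(seed)
    tmq = rng.uniform(1, 15, size=n)
    X = np.vstack([
        generate_spectrum(t, cfg, rng, noise=False, scatter=False,
                          matrix=False)
        for t in tmq
    ])
    j = int(np.argmin(np.abs(cfg.grid - 1500.0)))
    y = 3.0 * X[:, j] + 7.0
    return X, y


class TestOracleEquivalence:
    @pytest.mark.parametrize("n_factors", [1, 3, 6])
    def test_unmodified_equals_pls1(self, n_factors):
        rng = np.random.default_rng(42)
        for _ in range(15):
            X = rng.normal(size=(20, 50))
            y = X @ rng.normal(size=50) * 0.2 + rng.normal(size=20)
            ours = MPLS(y, X, modified=False).fit(n_factors)
            sk = PLSRegression(n_components=n_factors, scale=False).fit(X, y)
            np.testing.assert_allclose(ours.params, sk.coef_.ravel(),
                                       atol=1e-8)
            np.testing.assert_allclose(ours.fittedvalues,
                                       sk.predict(X).ravel(), atol=1e-8)


class TestExactFit:
    @pytest.mark.parametrize("modified", [False, True])
    def test_noiseless_linear_one_factor(self, modified):
        X, y = rank_one_instance()
        res = MPLS(y, X, modified=modified).fit(1)
        ss_res = np.sum(res.resid**2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 1 - 1e-9
        assert res.training_report().se <= 1e-8 * np.std(y)

    def test_cv_chooses_one_factor_on_noiseless_data(self):
        X, y = rank_one_instance(n=40, seed=3)
        cv = MPLS(y, X, modified=True).fit_cv(max_factors=5, n_groups=5,
                                              seed=0)
        assert cv.n_factors_selected == 1
        assert cv.secv_curve[0] < 1e-6


class TestPrediction:
    def test_training_mean_maps_to_y_center(self, rng):
        X = rng.normal(size=(25, 40))
        y = rng.uniform(1, 10, size=25)
        res = MPLS(y, X).fit(3)
        pred = res.predict(X.mean(axis=0)[None, :])
        assert pred[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_factorwise_agrees_with_collapsed(self, rng):
        X = rng.normal(size=(30, 60))
        y = X @ rng.normal(size=60) * 0.1 + rng.normal(size=30)
        res = MPLS(y, X, modified=True).fit(6)
        Xnew = rng.normal(size=(10, 60))
        np.testing.assert_allclose(res.predict_factorwise(Xnew)[:, -1],
                                   res.predict(Xnew), rtol=1e-8, atol=1e-10)

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(20, 30))
        y = rng.normal(size=20)
        res = MPLS(y, X).fit(2)
        perm = rng.permutation(20)
        np.testing.assert_allclose(res.predict(X[perm]),
                                   res.predict(X)[perm], atol=1e-12)

    def test_grid_mismatch(self, rng):
        res = MPLS(rng.normal(size=10), rng.normal(size=(10, 30))).fit(2)
        with pytest.raises(GridError):
            res.predict(rng.normal(size=(3, 29)))


class TestEquivariance:
    def test_y_translation_and_scale(self, rng):
        X = rng.normal(size=(25, 40))
        y = X @ rng.normal(size=40) * 0.3 + rng.normal(size=25)
        Xn = rng.normal(size=(5, 40))
        base = MPLS(y, X, modified=True).fit(4).predict(Xn)
        shifted = MPLS(y + 11.0, X, modified=True).fit(4).predict(Xn)
        scaled = MPLS(y * 2.5, X, modified=True).fit(4).predict(Xn)
        np.testing.assert_allclose(shifted, base + 11.0, atol=1e-8)
        np.testing.assert_allclose(scaled, base * 2.5, rtol=1e-8)

    def test_training_sec_monotone_in_factors(self, rng):
        X = rng.normal(size=(40, 30))
        y = X @ rng.normal(size=30) * 0.2 + rng.normal(size=40)
        model = MPLS(y, X, modified=True)
        rss = [np.sum(model.fit(f).resid ** 2) for f in range(1, 8)]
        assert all(a >= b - 1e-10 for a, b in zip(rss, rss[1:]))


class TestCrossValidation:
    def test_plan_partitions_evenly(self):
        plan = CVPlan(23, n_groups=5, seed=1)
        sizes = np.bincount(plan.assignment, minlength=5)
        assert sizes.sum() == 23
        assert sizes.max() - sizes.min() <= 1

    def test_same_seed_same_curve(self, rng):
        X = rng.normal(size=(40, 30))
        y = X @ rng.normal(size=30) * 0.2 + rng.normal(size=40)
        model = MPLS(y, X)
        a = model.fit_cv(max_factors=6, n_groups=5, seed=9)
        b = model.fit_cv(max_factors=6, n_groups=5, seed=9)
        np.testing.assert_array_equal(a.plan.assignment, b.plan.assignment)
        np.testing.assert_array_equal(a.secv_curve, b.secv_curve)
        assert a.n_factors_selected == b.n_factors_selected

    def test_null_data_one_minus_vr_small(self):
        # y independent of X: factor selection must not manufacture signal
        vrs = []
        for s in range(20):
            rng = np.random.default_rng(s)
            X = rng.normal(size=(60, 100))
            y = rng.normal(size=60)
            cv = MPLS(y, X).fit_cv(max_factors=16, n_groups=5, seed=s)
            vrs.append(cv.one_minus_vr)
        assert np.mean(vrs) <= 0.1

    def test_max_factors_clipped_with_warning(self, rng):
        X = rng.normal(size=(8, 30))
        y = rng.normal(size=8)
        with pytest.warns(UserWarning, match="clipped"):
            res = MPLS(y, X).fit(20)
        assert res.n_factors == 7

    def test_outlier_mask_flags_planted_outlier(self, rng):
        X, y = rank_one_instance(n=40, seed=5)
        y = y + rng.normal(0, 0.05, size=40)
        y[3] += 8.0  # gross reference error
        cv = MPLS(y, X).fit_cv(max_factors=4, n_groups=5, seed=0)
        mask = cv.outlier_mask()
        assert mask[3]
        assert mask.sum() <= 3


class TestSerialization:
    def test_round_trip_predictions(self, tmp_path, rng):
        X = rng.normal(size=(25, 40))
        y = X @ rng.normal(size=40) * 0.3 + rng.normal(size=25)
        res = MPLS(y, X, modified=True).fit(4)
        path = tmp_path / "model.json"
        res.to_json(path)
        predict, doc = MPLSResults.predictor_from_json(path)
        assert doc["n_factors"] == 4
        Xn = rng.normal(size=(6, 40))
        np.testing.assert_allclose(predict(Xn), res.predict(Xn), atol=1e-10)

    def test_degenerate_target_rejected(self, rng):
        with pytest.raises(ValueError, match="degenerate"):
            MPLS(np.full(10, 3.0), rng.normal(size=(10, 5)))


def test_prediction_plot_smoke(rng):
    import matplotlib
    matplotlib.use("Agg")
    X = rng.normal(size=(20, 30))
    y = X @ rng.normal(size=30) * 0.3 + rng.normal(size=20)
    ax = MPLS(y, X).fit(2).plot_predictions()
    assert "predicted" in ax.get_ylabel()
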