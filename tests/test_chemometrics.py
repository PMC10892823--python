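"""PCA, PCA-LDA and NIPALS PLSR against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from nirpowder.chemometrics import (
    cross_validate_plsr,
    fit_pca,
    fit_plsr,
    lda_classify,
    optimize_model,
)
from nirpowder.chemometrics import test_set_predict as predict_test_set
from nirpowder.preprocess import parse_chain
from nirpowder.simulate import SpectralDataset


def _dataset(X, y, reps, response="conc_melamine", wl=None):
    n = X.shape[0]
    meta = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "protein": ["whey"] * n,
            "combo": ["M"] * n,
            "level": (np.asarray(y) > np.median(y)).astype(int),
            "replicate": reps,
        }
    )
    return SpectralDataset(
        X=np.asarray(X, float),
        wavelengths=np.arange(X.shape[1], dtype=float) if wl is None else wl,
        meta=meta,
        Y=pd.DataFrame({response: np.asarray(y, float)}),
    )


class TestPCA:
    def test_rank_one_explains_everything(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.outer([1.0, 2.0, 3.0, -1.0, 0.5], v)
        model = fit_pca(X, 1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_full_rank_reconstruction(self, rng):
        X = rng.normal(size=(8, 5))
        model = fit_pca(X, 5)
        recon = model.mean + model.scores @ model.loadings.T
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_matches_sklearn_oracle_on_small_matrix(self, rng):
        X = rng.normal(size=(6, 4))
        model = fit_pca(X, 3)
        from sklearn.decomposition import PCA

        sk = PCA(n_components=3).fit(X)
        # compare up to per-component sign
        for k in range(3):
            ours, theirs = model.loadings[:, k], sk.components_[k]
            sign = np.sign(ours @ theirs)
            np.testing.assert_allclose(ours, sign * theirs, atol=1e-8)
        np.testing.assert_allclose(
            model.explained_variance_ratio, sk.explained_variance_ratio_, atol=1e-10
        )

    def test_loadings_orthonormal(self, rng):
        X = rng.normal(size=(10, 6))
        model = fit_pca(X, 4)
        np.testing.assert_allclose(
            model.loadings.T @ model.loadings, np.eye(4), atol=1e-8
        )

    def test_rank_request_errors(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.normal(size=(4, 10)), 5)


class TestLDA:
    def _separated(self, rng, gap=30.0):
        n_per = 18
        X0 = rng.normal(0.0, 1.0, size=(n_per, 8))
        X1 = rng.normal(gap, 1.0, size=(n_per, 8))
        X = np.vstack([X0, X1])
        labels = np.array([0] * n_per + [1] * n_per)
        reps = np.tile([1, 2, 3], 2 * n_per // 3)
        return _dataset(X, labels.astype(float), reps), labels

    def test_separated_classes_perfect_prediction(self, rng):
        ds, labels = self._separated(rng)
        res = lda_classify(ds, labels=labels, n_pcs=3)
        assert res.prediction_pct == 100.0
        assert res.recognition_pct == 100.0

    def test_shuffled_labels_near_chance(self, rng):
        ds, labels = self._separated(rng)
        accs = []
        for s in range(20):
            shuffled = np.random.default_rng(s).permutation(labels)
            accs.append(lda_classify(ds, labels=shuffled, n_pcs=3).prediction_pct)
        assert abs(np.mean(accs) - 50.0) < 10.0

    def test_confusion_trace_is_recognition(self, rng):
        ds, labels = self._separated(rng, gap=2.0)
        res = lda_classify(ds, labels=labels, n_pcs=3)
        assert res.recognition_pct == pytest.approx(
            100.0 * np.trace(res.confusion_calibration) / len(labels)
        )
        assert res.confusion_cv.sum() == len(labels)
        np.testing.assert_array_equal(
            res.confusion_calibration.sum(axis=1),
            [np.sum(labels == c) for c in res.classes],
        )

    def test_too_many_pcs_raises(self, rng):
        ds, labels = self._separated(rng)
        with pytest.raises(ValueError):
            lda_classify(ds, labels=labels, n_pcs=30)


class TestNIPALS:
    def test_exact_linear_response_zero_rmsec(self, rng):
        X = rng.normal(size=(12, 6))
        beta = rng.normal(size=6)
        y = X @ beta + 2.0
        model = fit_plsr(X, y, n_lv=6)
        assert model.rmsec == pytest.approx(0.0, abs=1e-8)
        assert model.r2c == pytest.approx(1.0, abs=1e-10)

    def test_mean_spectrum_predicts_mean_response(self, rng):
        X = rng.normal(size=(15, 7))
        y = rng.normal(size=15)
        model = fit_plsr(X, y, n_lv=3)
        assert model.predict(X.mean(axis=0)[None, :])[0] == pytest.approx(
            y.mean(), abs=1e-10
        )

    def test_full_rank_equals_min_norm_least_squares(self, rng):
        # 10×6 instance: at n_lv = rank the PLS solution is the OLS solution
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        model = fit_plsr(X, y, n_lv=6)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        b_oracle = np.linalg.pinv(Xc) @ yc
        np.testing.assert_allclose(model.b, b_oracle, atol=1e-8)

    def test_one_lv_weight_is_normalised_covariance(self, rng):
        X = rng.normal(size=(20, 9))
        y = rng.normal(size=20)
        model = fit_plsr(X, y, n_lv=1)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w_oracle = Xc.T @ yc
        w_oracle /= np.linalg.norm(w_oracle)
        np.testing.assert_allclose(model.W[:, 0], w_oracle, atol=1e-8)

    def test_scores_orthogonal(self, rng):
        X = rng.normal(size=(25, 12))
        y = rng.normal(size=25)
        T = fit_plsr(X, y, n_lv=5).T
        G = T.T @ T
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)

    def test_rmsec_monotone_in_lv(self, rng):
        X = rng.normal(size=(30, 15))
        y = X @ rng.normal(size=15) + rng.normal(0, 0.5, size=30)
        rmsecs = [fit_plsr(X, y, k).rmsec for k in range(1, 9)]
        assert all(a >= b - 1e-12 for a, b in zip(rmsecs, rmsecs[1:]))

    def test_matches_sklearn_predictions(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(24, 10))
        y = X @ rng.normal(size=10) + rng.normal(0, 0.3, size=24)
        ours = fit_plsr(X, y, n_lv=4).predict(X)
        sk = PLSRegression(n_components=4, scale=False).fit(X, y)
        np.testing.assert_allclose(ours, sk.predict(X).ravel(), atol=1e-6)

    def test_degenerate_inputs(self, rng):
        X = rng.normal(size=(8, 4))
        with pytest.raises(ValueError):
            fit_plsr(X, np.ones(8), n_lv=2)
        with pytest.raises(ValueError):
            fit_plsr(X, rng.normal(size=8), n_lv=6)  # beyond rank


class TestReplicateCV:
    def _linear_dataset(self, rng, n=30, p=8, noise=0.0):
        X = rng.normal(size=(n, p))
        beta = rng.normal(size=p)
        y = X @ beta + noise * rng.normal(size=n)
        reps = np.tile([1, 2, 3], n // 3)
        return _dataset(X, y, reps)

    def test_noiseless_signal_recovered(self, rng):
        ds = self._linear_dataset(rng)
        rmsecv, r2cv = cross_validate_plsr(ds, "conc_melamine", n_lv=8)
        assert r2cv >= 0.999

    def test_rmsecv_matches_hand_pooled_folds(self, rng):
        ds = self._linear_dataset(rng, n=9, p=4, noise=0.5)
        rmsecv, r2cv = cross_validate_plsr(ds, "conc_melamine", n_lv=2)
        y = ds.Y["conc_melamine"].to_numpy()
        reps = ds.meta["replicate"].to_numpy()
        sse = 0.0
        for rep in (1, 2, 3):
            test = reps == rep
            model = fit_plsr(ds.X[~test], y[~test], 2)
            sse += np.sum((model.predict(ds.X[test]) - y[test]) ** 2)
        assert rmsecv == pytest.approx(np.sqrt(sse / len(y)), rel=1e-10)
        assert r2cv == pytest.approx(1 - sse / np.sum((y - y.mean()) ** 2), rel=1e-10)

    def test_constant_response_errors(self, rng):
        ds = self._linear_dataset(rng)
        ds.Y["conc_melamine"] = 1.0
        with pytest.raises(ValueError):
            cross_validate_plsr(ds, "conc_melamine", n_lv=2)


class TestTestSetPredict:
    def test_row_order_invariance(self, rng):
        X = rng.normal(size=(18, 6))
        y = X @ rng.normal(size=6) + rng.normal(0, 0.2, size=18)
        reps = np.tile([1, 2, 3], 6)
        ds = _dataset(X, y, reps)
        out1 = predict_test_set(ds, "conc_melamine", n_lv=3)
        perm = rng.permutation(18)
        out2 = predict_test_set(ds.subset(perm), "conc_melamine", n_lv=3)
        assert out1["rmsep"] == pytest.approx(out2["rmsep"], rel=1e-10)

    def test_rmsep_definition(self, rng):
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        reps = np.tile([1, 2, 3], 4)
        ds = _dataset(X, y, reps)
        out = predict_test_set(ds, "conc_melamine", n_lv=2)
        direct = np.sqrt(np.mean((out["y_predicted"] - out["y_observed"]) ** 2))
        assert out["rmsep"] == pytest.approx(direct, rel=1e-12)

    def test_repeat_simulation_r2p_close_to_r2cv(self, rng):
        X = rng.normal(size=(60, 10))
        y = X @ rng.normal(size=10) + rng.normal(0, 0.05, size=60)
        reps = np.tile([1, 2, 3], 20)
        ds = _dataset(X, y, reps)
        _, r2cv = cross_validate_plsr(ds, "conc_melamine", n_lv=8)
        r2p = predict_test_set(ds, "conc_melamine", n_lv=8)["r2p"]
        assert abs(r2p - r2cv) < 0.01


class TestOptimizeModel:
    def _ds(self, rng):
        lam = np.arange(1000.0, 1100.0, 2.0)
        X = np.exp(-0.5 * ((lam - 1050.0) / 20.0) ** 2)[None, :] * rng.uniform(
            0.5, 2.0, size=(24, 1)
        ) + rng.normal(0, 0.01, size=(24, len(lam)))
        y = X[:, 25] * 3.0 + rng.normal(0, 0.02, size=24)
        reps = np.tile([1, 2, 3], 8)
        return _dataset(X, y, reps, wl=lam)

    def test_single_candidate_returned(self, rng):
        ds = self._ds(rng)
        model = optimize_model(ds, "conc_melamine", ["SG(5,2,0)"], [2])
        assert model.pretreatment == "SG(5,2,0)"
        assert model.n_lv == 2

    def test_tie_break_prefers_first_candidate(self, rng):
        ds = self._ds(rng)
        model = optimize_model(ds, "conc_melamine", ["SNV", "SNV"], [1, 2])
        assert model.pretreatment == "SNV"

    def test_argmin_matches_brute_force(self, rng):
        ds = self._ds(rng)
        chains = ["SG(5,2,0)", "SNV", "SG(7,2,1)"]
        lvs = range(1, 5)
        model = optimize_model(ds, "conc_melamine", chains, lvs)
        grid = {
            (c, lv): cross_validate_plsr(ds, "conc_melamine", lv, parse_chain(c))[0]
            for c in chains
            for lv in lvs
        }
        best = min(grid.items(), key=lambda kv: (kv[1], kv[0][1], chains.index(kv[0][0])))
        assert (model.pretreatment, model.n_lv) == best[0]
        assert model.rmsecv == pytest.approx(best[1], rel=1e-10)
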