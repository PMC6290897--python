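"""NIPALS PLS, LV selection, VIP, rotation, permutation significance."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irsigflow.pls import (
    PLSError,
    confidence_ellipse,
    fit_pls,
    orthogonal_rotate,
    permutation_significance,
    select_n_lv,
    vip_scores,
    zscore_apply,
    zscore_fit,
    zscore_invert,
)


class TestZscore:
    def test_closed_form(self):
        z, params = zscore_fit(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(z["a"], [-1.0, 0.0, 1.0])  # sample SD

    def test_apply_idempotent_and_invertible(self, rng):
        df = pd.DataFrame(rng.normal(2, 3, size=(20, 4)), columns=list("abcd"))
        z, params = zscore_fit(df)
        pd.testing.assert_frame_equal(zscore_apply(df, params), z)
        np.testing.assert_allclose(zscore_invert(z, params).to_numpy(),
                                   df.to_numpy(), atol=1e-9)

    def test_zero_variance_names_column(self):
        df = pd.DataFrame({"ok": [1.0, 2.0], "flat": [5.0, 5.0]})
        with pytest.raises(PLSError, match="flat"):
            zscore_fit(df)


class TestFit:
    def test_single_predictor_equals_ols(self, rng):
        x = rng.normal(size=40)
        y = 1.7 * x + rng.normal(0, 0.3, 40)
        X = pd.DataFrame({"x": x})
        model = fit_pls(X, pd.DataFrame({"y": y}), 1)
        slope, intercept = np.polyfit(x, y, 1)
        np.testing.assert_allclose(
            model.predict_response(X)["y"], intercept + slope * x, atol=1e-8)

    def test_noiseless_full_rank_perfect_fit(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        Y = pd.DataFrame({"y": X.to_numpy() @ np.array([1.0, -2.0, 0.5, 3.0])})
        model = fit_pls(X, Y, 4)
        resid = model.predict_response(X)["y"] - Y["y"]
        ss_res = float((resid ** 2).sum())
        ss_tot = float(((Y["y"] - Y["y"].mean()) ** 2).sum())
        assert 1 - ss_res / ss_tot == pytest.approx(1.0, abs=1e-8)

    def test_scores_orthogonal(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 8)))
        Y = pd.DataFrame({"y": rng.normal(size=50)})
        model = fit_pls(X, Y, 4)
        TtT = model.T.T @ model.T
        off = TtT - np.diag(np.diag(TtT))
        assert np.abs(off).max() < 1e-6

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = pd.DataFrame(rng.normal(size=(40, 6)))
        Y = pd.DataFrame({"y": X.iloc[:, 0] * 1.5 - X.iloc[:, 3] + rng.normal(0, 0.2, 40)})
        model = fit_pls(X, Y, 3)
        sk = PLSRegression(n_components=3, scale=True).fit(X, Y)
        np.testing.assert_allclose(
            model.predict_response(X).to_numpy().ravel(),
            sk.predict(X).ravel(), atol=1e-8)

    def test_excess_components_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)))
        Y = pd.DataFrame({"y": rng.normal(size=10)})
        with pytest.raises(PLSError):
            fit_pls(X, Y, 5)

    def test_nan_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [1, 2, 4.0]})
        with pytest.raises(PLSError, match="NaN"):
            fit_pls(X, pd.DataFrame({"y": [1.0, 2.0, 3.0]}), 1)


class TestVIP:
    def test_single_predictor_vip_is_one(self, rng):
        x = rng.normal(size=20)
        model = fit_pls(pd.DataFrame({"x": x}),
                        pd.DataFrame({"y": 2 * x + rng.normal(0, .1, 20)}), 1)
        assert vip_scores(model)["x"] == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_mean_square_is_one(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 25, int(rng.integers(2, 10))
        a = int(rng.integers(1, min(4, p + 1)))
        X = pd.DataFrame(rng.normal(size=(n, p)))
        Y = pd.DataFrame({"y": rng.normal(size=n)})
        vip = vip_scores(fit_pls(X, Y, a))
        assert (vip ** 2).mean() == pytest.approx(1.0, abs=1e-9)

    def test_informative_predictor_flagged(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 10)),
                         columns=[f"v{i}" for i in range(10)])
        Y = pd.DataFrame({"y": 2.0 * X["v0"] + rng.normal(0, 0.2, 60)})
        vip = vip_scores(fit_pls(X, Y, 2))
        assert vip["v0"] > 1.0 > vip.drop("v0").median()


class TestRotation:
    def _model(self, rng, sep_axis="lv2"):
        labels = np.array(["a"] * 25 + ["b"] * 25)
        X = pd.DataFrame(rng.normal(size=(50, 6)), columns=list("uvwxyz"))
        # strong variance along u (captured by LV1), class separation along w
        X["u"] = rng.normal(scale=4.0, size=50)
        X.loc[labels == "b", "w"] += 3.0
        return fit_pls(X, labels, 2, mode="discriminant"), X, labels

    @staticmethod
    def _between_frac(t, labels):
        grand = t.mean()
        between = sum((t[labels == c].mean() - grand) ** 2 * (labels == c).sum()
                      for c in np.unique(labels))
        return between / ((t - grand) ** 2).sum()

    def test_rotation_orthogonal_and_prediction_invariant(self, rng):
        model, X, labels = self._model(rng)
        before = model.predict_response(X).to_numpy()
        rotated = orthogonal_rotate(model)
        R = rotated.rotation
        assert np.abs(R @ R.T - np.eye(2)).max() < 1e-9
        np.testing.assert_allclose(
            rotated.predict_response(X).to_numpy(), before, atol=1e-9)

    def test_axis1_carries_max_separation(self, rng):
        model, X, labels = self._model(rng)
        rotated = orthogonal_rotate(model)
        f1 = self._between_frac(rotated.T[:, 0], labels)
        f2 = self._between_frac(rotated.T[:, 1], labels)
        assert f1 >= f2
        assert f1 >= self._between_frac(model.T[:, 0], labels) - 1e-12

    def test_matches_dense_angle_grid_oracle(self, rng):
        model, X, labels = self._model(rng)
        rotated = orthogonal_rotate(model)
        achieved = self._between_frac(rotated.T[:, 0], labels)
        best = max(
            self._between_frac(
                model.T @ np.array([np.cos(t), np.sin(t)]), labels)
            for t in np.linspace(0, np.pi, 3600, endpoint=False)
        )
        assert achieved >= best - 1e-6

    def test_single_component_identity(self, rng):
        x = rng.normal(size=20)
        model = fit_pls(pd.DataFrame({"x": x}),
                        pd.DataFrame({"y": x + rng.normal(0, .1, 20)}), 1)
        rotated = orthogonal_rotate(model, criterion="y_covariance")
        np.testing.assert_allclose(rotated.rotation, np.eye(1))


class TestSelectNLV:
    def test_curve_covers_grid(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 5)))
        Y = pd.DataFrame({"y": rng.normal(size=30)})
        _, curve = select_n_lv(X, Y, [1, 2, 3], seed=0)
        assert sorted(curve) == [1, 2, 3]

    def test_pure_noise_prefers_one_lv(self):
        picks = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(30, 8)))
            Y = pd.DataFrame({"y": rng.normal(size=30)})
            a, _ = select_n_lv(X, Y, [1, 2, 3, 4], seed=seed)
            picks.append(a)
        assert np.mean(np.array(picks) == 1) > 0.5

    def test_two_lv_structure_recovered(self):
        """X driven by two latent factors, one response per factor: CV picks
        two latent variables in the vast majority of seeds."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            Z = rng.normal(size=(40, 2))
            L = np.linalg.qr(rng.normal(size=(30, 2)))[0]
            X = pd.DataFrame(3 * Z @ L.T + rng.normal(size=(40, 30)))
            Y = pd.DataFrame({"y1": Z[:, 0] + 0.5 * rng.normal(size=40),
                              "y2": Z[:, 1] + 0.5 * rng.normal(size=40)})
            a, _ = select_n_lv(X, Y, [1, 2, 3, 4], seed=seed)
            hits += a == 2
        assert hits >= 0.8 * 50


class TestPermutationSignificance:
    def test_seed_determinism(self, rng):
        X = pd.DataFrame(rng.normal(size=(24, 5)))
        Y = pd.DataFrame({"y": X.iloc[:, 0] + rng.normal(0, .3, 24)})
        p1, _ = permutation_significance(X, Y, [1, 2], n_perm=20, seed=3)
        p2, _ = permutation_significance(X, Y, [1, 2], n_perm=20, seed=3)
        assert p1 == p2

    def test_strong_signal_detected(self):
        detections = 0
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            X = pd.DataFrame(rng.normal(size=(30, 5)))
            y = X.iloc[:, 0] * 3 + rng.normal(0, 0.3, 30)  # R^2 ~ 0.9
            p, _ = permutation_significance(
                X, pd.DataFrame({"y": y}), [1, 2], n_perm=30, seed=rep)
            detections += p < 0.05
        assert detections >= 0.95 * 20

    def test_low_n_perm_refused(self, rng):
        X = pd.DataFrame(rng.normal(size=(24, 4)))
        Y = pd.DataFrame({"y": rng.normal(size=24)})
        with pytest.raises(PLSError, match="20"):
            permutation_significance(X, Y, [1], n_perm=10, seed=0)


class TestConfidenceEllipse:
    def test_isotropic_radius_closed_form(self, rng):
        scores = rng.normal(size=(10_000, 2))
        e = confidence_ellipse(scores, 0.95)
        expected = np.sqrt(5.991464547107979)  # chi2.ppf(0.95, 2)
        np.testing.assert_allclose(e.radii, expected, rtol=0.05)

    def test_level_zero_degenerate(self, rng):
        e = confidence_ellipse(rng.normal(size=(100, 2)), 0.0)
        np.testing.assert_allclose(e.radii, 0.0)

    def test_large_sample_containment(self, rng):
        scores = rng.multivariate_normal([1, -2], [[2, 0.7], [0.7, 1]], size=10_000)
        e = confidence_ellipse(scores, 0.95)
        cov = np.cov(scores, rowvar=False)
        inv = np.linalg.inv(cov)
        d = scores - scores.mean(axis=0)
        inside = (np.einsum("ij,jk,ik->i", d, inv, d)
                  <= 5.991464547107979).mean()
        assert inside == pytest.approx(0.95, abs=0.02)

    def test_singular_covariance_rejected(self, rng):
        x = rng.normal(size=50)
        with pytest.raises(PLSError, match="singular"):
            confidence_ellipse(np.column_stack([x, 2 * x]), 0.95)
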