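import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from radepi.selection import (
    FeatureTable,
    LassoConfig,
    SignatureModel,
    _fit_l1,
    build_lambda_grid,
    compute_signature,
    fit_lasso_loocv,
    signature_probability,
    univariate_screen,
    zscore_fit_apply,
)

# The four published signature coefficients (zone percentage, NGTDM contrast,
# GLCM maximum probability, Chebyshev distance) used as worked-example input.
PUBLISHED_COEFS = [
    0.445876806974411,
    0.135681539773941,
    0.336605042219162,
    0.281620532274246,
]


def _table(x, y, cohort="train"):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    cols = [f"f{i}" for i in range(x.shape[1])]
    return FeatureTable(
        [f"p{i}" for i in range(len(x))], pd.DataFrame(x, columns=cols),
        np.asarray(y), cohort,
    )


class TestZscore:
    def test_one_two_three(self):
        t = _table([[1.0], [2.0], [3.0]], [0, 1, 0])
        (tn,), params = zscore_fit_apply(t)
        np.testing.assert_allclose(tn.features["f0"], [-1.0, 0.0, 1.0])

    def test_constant_feature_excluded(self):
        x = np.column_stack([np.ones(4), np.arange(4.0)])
        (tn,), params = zscore_fit_apply(_table(x, [0, 1, 0, 1]))
        assert params.dropped_constant == ("f0",)
        assert list(tn.features.columns) == ["f1"]

    def test_validation_value_at_train_mean_is_zero(self):
        train = _table([[1.0], [3.0]], [0, 1])
        valid = _table([[2.0]], [1], "validation")
        (tn, vn), _ = zscore_fit_apply(train, valid)
        assert vn.features["f0"].iloc[0] == pytest.approx(0.0)

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            zscore_fit_apply(_table([[1.0]], [1]))


class TestScreen:
    def test_feature_equal_to_label_kept(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 40)
        x = np.column_stack([y.astype(float), rng.normal(size=40)])
        res = univariate_screen(_table(x, y))
        row = res.table.set_index("feature").loc["f0"]
        assert row["auc"] == pytest.approx(1.0)
        assert row["pearson_p"] < 1e-6
        assert bool(row["kept"])

    def test_inverse_feature_oriented_and_kept(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 40)
        res = univariate_screen(_table(-y.astype(float)[:, None] * 2.0, y))
        row = res.table.iloc[0]
        assert row["auc"] == pytest.approx(1.0)  # max(AUC, 1-AUC)
        assert bool(row["kept"])

    def test_type_one_control_small(self):
        # scaled-down version of the acceptance simulation
        rng = np.random.default_rng(2)
        kept = total = 0
        for _ in range(100):
            y = np.array([0, 1] * 50)
            x = rng.normal(size=(100, 20))
            res = univariate_screen(_table(x, y))
            kept += int(res.table["kept"].sum())
            total += 20
        assert kept / total <= 0.06

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 60)
        x = rng.normal(size=(60, 30)) + 0.5 * y[:, None] * rng.random(30)
        t = _table(x, y)
        strict = set(univariate_screen(t, 0.05, 0.6).kept)
        loose = set(univariate_screen(t, 0.10, 0.55).kept)
        assert strict <= loose

    def test_pearson_matches_scipy(self):
        from scipy.stats import pearsonr

        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 50)
        x = rng.normal(size=(50, 5))
        res = univariate_screen(_table(x, y))
        for j in range(5):
            expected = pearsonr(x[:, j], y).pvalue
            assert res.table["pearson_p"].iloc[j] == pytest.approx(expected, rel=1e-9)


def _planted_cohort(seed=0, n=200, n_noise=0, beta=2.0, n_plant=3):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, n_plant + n_noise))
    coefs = np.zeros(n_plant + n_noise)
    coefs[:n_plant] = beta
    y = (rng.random(n) < expit(x @ coefs)).astype(int)
    return _table(x, y)


class TestLasso:
    def test_full_shrinkage_at_grid_top(self):
        t = _planted_cohort()
        x = t.features.to_numpy()
        grid = build_lambda_grid(x, t.labels, LassoConfig())
        m = _fit_l1(x, t.labels, grid[0], LassoConfig())
        assert np.all(m.coef_ == 0.0)

    def test_near_zero_lambda_matches_unpenalized(self):
        t = _planted_cohort(n=200)
        x = t.features.to_numpy()
        from sklearn.linear_model import LogisticRegression

        oracle = LogisticRegression(C=1e8, tol=1e-10, max_iter=20000).fit(x, t.labels)
        cfg = LassoConfig(solver_tol=1e-10, max_iter=50000)
        m = _fit_l1(x, t.labels, 1e-7, cfg)
        np.testing.assert_allclose(m.coef_, oracle.coef_, atol=1e-3)

    def test_support_shrinks_along_path(self):
        t = _planted_cohort(seed=5, n=150, n_noise=10, beta=1.2)
        x = t.features.to_numpy()
        cfg = LassoConfig()
        grid = build_lambda_grid(x, t.labels, cfg)
        sizes = [
            int(np.sum(_fit_l1(x, t.labels, lam, cfg).coef_ != 0))
            for lam in grid[:: len(grid) // 10]
        ]
        # grid is decreasing, so supports grow (weakly) along the list
        for a, b in zip(sizes, sizes[1:]):
            assert b >= a - 1  # liblinear wiggle tolerance of one feature

    def test_loocv_selects_planted_features(self):
        t = _planted_cohort(seed=1, n=80, n_noise=5, beta=2.0)
        model = fit_lasso_loocv(t, LassoConfig(n_lambdas=40))
        assert set(model.feature_names) >= {"f0", "f1"}
        assert np.all(model.coefficients != 0)
        assert model.lambda_star in model.lambda_grid

    def test_one_class_rejected(self):
        t = _table(np.random.default_rng(0).normal(size=(20, 3)), np.ones(20, dtype=int))
        with pytest.raises(ValueError, match="one class"):
            fit_lasso_loocv(t)

    def test_too_few_patients_rejected(self):
        t = _planted_cohort(n=8)
        with pytest.raises(ValueError, match="10"):
            fit_lasso_loocv(t)


class TestSignature:
    def _published_model(self):
        names = ["zone_percentage", "ngtdm_contrast", "glcm_max_probability",
                 "chebyshev"]
        from radepi.selection import NormalizationParams

        return SignatureModel(
            feature_names=names,
            coefficients=np.array(PUBLISHED_COEFS),
            intercept=0.0,
            lambda_star=0.067,
            lambda_grid=np.array([0.067]),
            cv_error=np.array([0.0]),
            normalization=NormalizationParams(
                mean=pd.Series(0.0, index=names), std=pd.Series(1.0, index=names)
            ),
        )

    def test_zero_vector_gives_zero(self):
        model = self._published_model()
        x = pd.DataFrame([[0.0, 0.0, 0.0, 0.0]], columns=model.feature_names)
        assert compute_signature(model, x)[0] == 0.0

    def test_published_unit_vector(self):
        model = self._published_model()
        x = pd.DataFrame([[1.0, 0.0, 0.0, 0.0]], columns=model.feature_names)
        assert compute_signature(model, x)[0] == pytest.approx(0.445876806974411, abs=1e-15)

    def test_published_sum_vector(self):
        model = self._published_model()
        x = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], columns=model.feature_names)
        assert compute_signature(model, x)[0] == pytest.approx(1.199783921241760, abs=1e-12)

    def test_missing_feature_named_in_error(self):
        model = self._published_model()
        x = pd.DataFrame([[1.0]], columns=["zone_percentage"])
        with pytest.raises(ValueError, match="chebyshev"):
            compute_signature(model, x)

    def test_json_roundtrip(self):
        model = self._published_model()
        back = SignatureModel.from_json(model.to_json())
        np.testing.assert_allclose(back.coefficients, model.coefficients)
        assert back.feature_names == model.feature_names

    def test_probability_uses_intercept(self):
        model = self._published_model()
        model.intercept = 1.0
        x = pd.DataFrame([[0.0, 0.0, 0.0, 0.0]], columns=model.feature_names)
        assert signature_probability(model, x)[0] == pytest.approx(expit(1.0))


def test_signature_separation_on_planted_cohort():
    # sign convention: the generalized group has the higher mean signature
    t = _planted_cohort(seed=9, n=120, n_noise=2, beta=1.5)
    (tn,), params = zscore_fit_apply(t)
    model = fit_lasso_loocv(tn, LassoConfig(n_lambdas=30), normalization=params)
    s = compute_signature(model, tn.features)
    assert s[tn.labels == 1].mean() > s[tn.labels == 0].mean()
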