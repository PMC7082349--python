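import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from radepi.evaluation import (
    RocResult,
    build_nomogram,
    compare_cohorts,
    decision_curve,
    delong_auc_variance,
    fisher_2x2,
    fit_multivariable_aic,
    hosmer_lemeshow_calibration,
    nomogram_lookup_table,
    roc_auc_ci,
)

from .oracles import naive_pairwise_auc


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc_ci(np.array([1.0, 1.0, 0.0, 0.0]), np.array([1, 1, 0, 0]))
        assert r.auc == pytest.approx(1.0)
        assert r.accuracy == pytest.approx(1.0)

    def test_all_ties_give_half(self):
        r = roc_auc_ci(np.full(10, 0.7), np.array([1, 0] * 5))
        assert r.auc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=20)  # force ties
        labels = rng.integers(0, 2, 20)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        auc, _ = delong_auc_variance(scores, labels)
        assert auc == pytest.approx(naive_pairwise_auc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        a = roc_auc_ci(scores, labels, threshold=0.0).auc
        b = roc_auc_ci(np.exp(scores), labels, threshold=1.0).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_ci_contains_auc_and_is_clipped(self, rng):
        scores = rng.normal(size=40)
        labels = (scores + rng.normal(size=40) > 0).astype(int)
        r = roc_auc_ci(scores, labels, threshold=0.0)
        assert 0.0 <= r.ci_lower <= r.auc <= r.ci_upper <= 1.0

    def test_ci_width_shrinks_like_sqrt_n(self):
        rng = np.random.default_rng(7)

        def mean_width(n, reps=60):
            widths = []
            for _ in range(reps):
                s = rng.normal(size=n)
                y = (s + rng.normal(size=n) * 1.5 > 0).astype(int)
                if y.min() == y.max():
                    continue
                r = roc_auc_ci(s, y, threshold=0.0)
                widths.append(r.ci_upper - r.ci_lower)
            return np.mean(widths)

        ratio = mean_width(50) / mean_width(200)
        assert 1.5 < ratio < 2.7  # ~ sqrt(200/50) = 2

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc_ci(np.array([0.1, 0.9]), np.array([1, 1]))


class TestHosmerLemeshow:
    def test_two_bin_toy_hand_value(self):
        # bins with O=(1,3), E=(2,2), n_b=(4,4): each term = 1/(2*0.5) = 1 -> HL = 2
        probs = np.array([0.5] * 4 + [0.5] * 4)
        probs[:4] -= 0.0001  # stable ordering into two bins
        labels = np.array([1, 0, 0, 0, 1, 1, 1, 0])
        r = hosmer_lemeshow_calibration(probs, labels, n_bins=2)
        assert r.statistic == pytest.approx(2.0, rel=1e-3)

    def test_perfectly_calibrated_bins_give_zero(self):
        # O = E exactly in every bin -> HL = 0, p = 1
        probs = np.repeat([0.2, 0.4, 0.6, 0.8], 5)
        labels = np.concatenate([
            [1, 0, 0, 0, 0], [1, 1, 0, 0, 0], [1, 1, 1, 0, 0], [1, 1, 1, 1, 0],
        ])
        r = hosmer_lemeshow_calibration(probs, labels, n_bins=4)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_type_one_error_rate(self):
        # canonical HL setting: probabilities come from a model fitted to the
        # same data, which is what the chi2(n_bins - 2) reference assumes;
        # with *known* probabilities the statistic is ~chi2(n_bins) and the
        # test would be anticonservative by construction
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        rejections = 0
        reps = 300
        for _ in range(reps):
            x = rng.normal(size=500)
            y = (rng.random(500) < expit(0.8 * x)).astype(int)
            p_hat = sm.Logit(y, sm.add_constant(x)).fit(disp=0).predict()
            r = hosmer_lemeshow_calibration(np.clip(p_hat, 1e-9, 1 - 1e-9), y)
            rejections += r.p_value < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_bin_partition(self, rng):
        p = rng.uniform(0.1, 0.9, 100)
        y = (rng.random(100) < p).astype(int)
        r = hosmer_lemeshow_calibration(p, y)
        assert r.bin_sizes.sum() == 100
        assert r.dof == len(r.bin_sizes) - 2

    def test_probability_domain_enforced(self):
        with pytest.raises(ValueError, match="strictly"):
            hosmer_lemeshow_calibration(np.linspace(0, 1, 20), np.zeros(20, dtype=int))


class TestDecisionCurve:
    def test_toy_net_benefit(self):
        # N=10, TP=4, FP=1 at p_t=0.2 -> 0.4 - 0.1*0.25 = 0.375
        probs = np.array([0.9] * 4 + [0.9] + [0.05] * 4 + [0.1])
        labels = np.array([1] * 4 + [0] + [0] * 4 + [1])
        dc = decision_curve(probs, labels, thresholds=np.array([0.2]))
        assert dc.net_benefit_model[0] == pytest.approx(0.375)

    def test_treat_all_zero_at_prevalence_threshold(self):
        labels = np.array([1, 0] * 10)
        dc = decision_curve(np.full(20, 0.5), labels, thresholds=np.array([0.5]))
        assert dc.net_benefit_all[0] == pytest.approx(0.0)

    def test_perfect_model_net_benefit_equals_prevalence(self):
        labels = np.array([1] * 6 + [0] * 14)
        probs = np.where(labels == 1, 0.99, 0.01)
        dc = decision_curve(probs, labels, thresholds=np.array([0.1, 0.5, 0.9]))
        np.testing.assert_allclose(dc.net_benefit_model, 0.3)

    def test_model_never_beats_prevalence(self, rng):
        labels = rng.integers(0, 2, 200)
        probs = np.clip(rng.random(200), 0.01, 0.99)
        dc = decision_curve(probs, labels)
        assert np.all(dc.net_benefit_model <= labels.mean() + 1e-12)
        assert np.all(dc.net_benefit_none == 0.0)

    def test_treat_all_approaches_prevalence_at_low_threshold(self):
        labels = np.array([1] * 3 + [0] * 7)
        dc = decision_curve(np.full(10, 0.5), labels, thresholds=np.array([0.001]))
        assert dc.net_benefit_all[0] == pytest.approx(0.3, abs=1e-2)


def _sim_predictors(rng, n=500):
    return pd.DataFrame({
        "signal": rng.normal(size=n),
        "noise": rng.normal(size=n),
    })


class TestAicSelection:
    def test_noise_predictor_dropped_mostly(self):
        dropped = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = _sim_predictors(rng)
            y = (rng.random(500) < expit(1.2 * data["signal"])).astype(int)
            model = fit_multivariable_aic(data, y)
            dropped += "noise" not in model.predictors
        assert dropped >= 16  # >= 80% of seeds

    def test_informative_predictors_retained(self):
        rng = np.random.default_rng(100)
        n = 600
        data = pd.DataFrame(rng.normal(size=(n, 4)),
                            columns=["signature", "age", "gender", "histopathology"])
        eta = 1.0 * data.sum(axis=1)
        y = (rng.random(n) < expit(eta)).astype(int)
        model = fit_multivariable_aic(data, y)
        assert set(model.predictors) == {"signature", "age", "gender", "histopathology"}

    def test_aic_definition_on_flat_predictor(self):
        # adding a pure-noise predictor increases AIC by ~ 2 - chi2(1 draw)
        rng = np.random.default_rng(3)
        data = _sim_predictors(rng)
        y = rng.integers(0, 2, 500)
        import statsmodels.api as sm

        base = sm.Logit(y, np.ones((500, 1))).fit(disp=0)
        with_noise = sm.Logit(y, sm.add_constant(data[["noise"]])).fit(disp=0)
        delta = with_noise.aic - base.aic
        assert -2.0 < delta <= 2.0 + 1e-9  # 2 - chi2_1 sample
        model = fit_multivariable_aic(data[["noise"]], y, candidates=["noise"])
        # with one candidate the model cannot eliminate below one predictor
        assert model.predictors == ["noise"]


class TestNomogram:
    def _fitted(self, rng, n=300):
        data = pd.DataFrame({
            "signature": rng.normal(size=n),
            "age": rng.uniform(15, 65, size=n),
        })
        y = (rng.random(n) < expit(0.8 * data["signature"] + 0.02 * (data["age"] - 40))).astype(int)
        model = fit_multivariable_aic(data, y)
        return build_nomogram(model, data), data

    def test_widest_predictor_spans_100_points(self, rng):
        model, data = self._fitted(rng)
        max_points = max(s["max_points"] for s in model.point_scales.values())
        assert max_points == pytest.approx(100.0)

    def test_points_nonnegative(self, rng):
        model, data = self._fitted(rng)
        pts = model.points(data)
        assert (pts.drop(columns="total") >= -1e-9).all().all()

    def test_points_path_equals_direct_probability(self, rng):
        model, data = self._fitted(rng)
        direct = model.probability(data)
        via_points = model.probability_from_points(model.points(data)["total"].to_numpy())
        np.testing.assert_allclose(via_points, direct, atol=1e-6)

    def test_single_predictor_spans_full_scale(self, rng):
        data = pd.DataFrame({"signature": rng.normal(size=200)})
        y = (rng.random(200) < expit(data["signature"])).astype(int)
        model = build_nomogram(fit_multivariable_aic(data, y), data)
        assert model.point_scales["signature"]["max_points"] == pytest.approx(100.0)

    def test_equal_effects_both_span_100(self):
        from radepi.evaluation import NomogramModel

        model = NomogramModel(
            predictors=["a", "b"], coefficients={"a": 1.0, "b": -1.0},
            intercept=0.0, aic=0.0,
        )
        data = pd.DataFrame({"a": [0.0, 1.0], "b": [0.0, 1.0]})
        model = build_nomogram(model, data)
        assert model.point_scales["a"]["max_points"] == pytest.approx(100.0)
        assert model.point_scales["b"]["max_points"] == pytest.approx(100.0)

    def test_lookup_table_monotone(self, rng):
        model, _ = self._fitted(rng)
        table = nomogram_lookup_table(model)
        diffs = np.diff(table["probability"])
        assert np.all(diffs > -1e-12)


class TestCompareCohorts:
    def test_published_gender_counts(self):
        # 2x2 gender table (85,54 | 43,23) -> two-sided Fisher p = 0.645
        assert fisher_2x2(85, 54, 43, 23) == pytest.approx(0.645, abs=1e-3)

    def test_two_by_two_diagonal(self):
        # table (2,0; 0,2): exhaustive hypergeometric two-sided p = 1/3
        assert fisher_2x2(2, 0, 0, 2) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_identical_groups_t_p_one(self):
        rec = pd.DataFrame({
            "age": [30, 40, 50, 30, 40, 50],
            "signature": [0.1, 0.2, 0.3, 0.1, 0.2, 0.3],
            "gender": ["male", "male", "female"] * 2,
            "histopathology": ["oligodendroglial", "astrocytoma", "astrocytoma"] * 2,
            "epilepsy_type": ["generalized"] * 3 + ["focal"] * 3,
        })
        table = compare_cohorts(rec).table.set_index("variable")
        assert table.loc["age", "p_value"] == pytest.approx(1.0)
        assert table.loc["age", "statistic"] == pytest.approx(0.0)
        assert table.loc["gender", "p_value"] == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        rec = pd.DataFrame({"age": [30], "epilepsy_type": ["generalized"]})
        with pytest.raises(ValueError, match="nonempty"):
            compare_cohorts(rec)


def test_calibration_bins_within_binomial_bands(rng):
    """Self-generated cohort: ~>=90% of decile bins inside binomial 95% bands."""
    from scipy.stats import binom

    inside = total = 0
    for _ in range(10):
        p = rng.uniform(0.1, 0.9, 1000)
        y = (rng.random(1000) < p).astype(int)
        r = hosmer_lemeshow_calibration(p, y)
        for mean_p, obs, nb in zip(r.bin_mean_predicted, r.bin_observed_frequency,
                                   r.bin_sizes):
            lo, hi = binom.ppf([0.025, 0.975], int(nb), mean_p) / int(nb)
            inside += lo - 1e-9 <= obs <= hi + 1e-9
            total += 1
    assert inside / total >= 0.9
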