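"""Tests of the injury-risk evaluation: exact rank-sum test, logistic risk
curves, ROC/AUC, LOOCV, and the structural consequences of the case table."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.stats import mannwhitneyu

from contusim.risk import (
    evaluate_all_metrics,
    fit_logistic,
    load_cases,
    loocv_evaluate,
    predict_cases,
    risk_threshold,
    roc_auc,
    summary_table,
    wilcoxon_rank_sum_exact,
)
from contusim.standin import METRIC_NAMES


class TestWilcoxonExact:
    def test_disjoint_small_groups(self):
        # full enumeration of C(6,3)=20 labelings, two extreme tails
        assert wilcoxon_rank_sum_exact([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_two_vs_two(self):
        assert wilcoxon_rank_sum_exact([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_multisets_give_one(self):
        assert wilcoxon_rank_sum_exact([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_matches_normal_approximation_for_moderate_n(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.normal(size=9)
            b = rng.normal(loc=rng.uniform(-1, 1), size=5)
            exact = wilcoxon_rank_sum_exact(a, b)
            approx = mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic", use_continuity=True).pvalue
            assert abs(exact - approx) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum_exact([], [1.0])

    def test_enumeration_size_guard(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum_exact(np.arange(13.0), np.arange(13.0) + 0.5)


class TestLogisticFit:
    def test_constant_predictor_no_information_fit(self):
        model = fit_logistic(np.ones(10), np.array([1, 0] * 5))
        assert model.b1 == 0.0
        assert model.b0 == pytest.approx(0.0)  # logit of prevalence 0.5
        with pytest.raises(ValueError):
            risk_threshold(model)

    def test_symmetric_constructed_set_has_zero_intercept(self):
        x = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        y = np.array([0, 1, 0, 1, 0, 1])  # one flipped pair on each side
        model = fit_logistic(x, y)
        assert model.b0 == pytest.approx(0.0, abs=1e-6)

    def test_matches_generic_likelihood_optimizer(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = (x + rng.normal(scale=1.5, size=30) > 0).astype(int)
        model = fit_logistic(x, y)

        def nll(beta):
            z = beta[0] + beta[1] * x
            return np.sum(np.log1p(np.exp(z)) - y * z)

        res = minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        assert model.b0 == pytest.approx(res.x[0], abs=1e-5)
        assert model.b1 == pytest.approx(res.x[1], abs=1e-5)

    def test_log_likelihood_is_a_maximum(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=25)
        y = (x > 0.2).astype(int)
        y[:3] = 1 - y[:3]  # keep it non-separable
        model = fit_logistic(x, y)

        def ll(b0, b1):
            z = b0 + b1 * x
            return np.sum(y * z - np.log1p(np.exp(z)))

        best = ll(model.b0, model.b1)
        for _ in range(1000):
            db = rng.normal(scale=0.3, size=2)
            assert ll(model.b0 + db[0], model.b1 + db[1]) <= best + 1e-9

    def test_separation_flagged(self):
        x = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = fit_logistic(x, y)
        assert model.separation
        with pytest.raises(ValueError):
            risk_threshold(model)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.arange(5.0), np.ones(5))


class TestRiskThreshold:
    def test_hand_arithmetic(self):
        from contusim.risk import InjuryRiskModel

        model = InjuryRiskModel("mps", b0=-4.0, b1=25.0, converged=True, separation=False)
        assert risk_threshold(model) == pytest.approx(0.16)
        assert model.probability(0.16) == pytest.approx(0.5, abs=1e-12)

    def test_zero_intercept(self):
        from contusim.risk import InjuryRiskModel

        model = InjuryRiskModel("m", b0=0.0, b1=3.0, converged=True, separation=False)
        assert risk_threshold(model) == 0.0

    def test_sign_flip_invariance(self):
        from contusim.risk import InjuryRiskModel

        a = InjuryRiskModel("m", b0=-4.0, b1=25.0, converged=True, separation=False)
        b = InjuryRiskModel("m", b0=4.0, b1=-25.0, converged=True, separation=False)
        assert risk_threshold(a) == risk_threshold(b)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_tabulated_tie_example(self):
        scores = [0.9, 0.8, 0.5, 0.5, 0.2]
        labels = [1, 1, 1, 0, 0]
        assert roc_auc(scores, labels) == pytest.approx(5.5 / 6)

    def test_label_inversion_complement(self):
        rng = np.random.default_rng(3)
        scores = rng.random(20)
        labels = rng.integers(0, 2, 20)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels) == pytest.approx(1 - roc_auc(scores, 1 - labels))

    @given(st.integers(0, 10_000))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 6, 20).astype(float)  # force ties
        labels = rng.integers(0, 2, 20)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        pos, neg = scores[labels == 1], scores[labels == 0]
        pairs = [(1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg]
        assert roc_auc(scores, labels) == pytest.approx(np.mean(pairs))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestLoocv:
    def test_perfectly_separable_scores(self):
        x = np.concatenate([np.arange(5.0), np.arange(10.0, 15.0)])
        y = np.array([0] * 5 + [1] * 5)
        report, _ = loocv_evaluate(x, y)
        assert report.accuracy == 1.0
        assert report.sensitivity == 1.0
        assert report.specificity == 1.0

    def test_duplicate_inputs_opposite_outcomes_force_misclassification(self):
        x = np.array([1.0, 1.0, 0.2, 0.3, 2.0, 2.1, 1.9, 2.2])
        y = np.array([0, 1, 0, 0, 1, 1, 1, 1])
        report, _ = loocv_evaluate(x, y)
        assert report.accuracy < 1.0

    def test_matches_hand_rolled_loop(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=12)
        y = (x + rng.normal(scale=1.0, size=12) > 0).astype(int)
        report, _ = loocv_evaluate(x, y)
        held = np.empty(12)
        for i in range(12):
            mask = np.arange(12) != i
            m = fit_logistic(x[mask], y[mask])
            held[i] = m.probability(x[i])
        pred = (held >= 0.5).astype(int)
        assert report.accuracy == pytest.approx(np.mean(pred == y))
        assert report.auc_testing == pytest.approx(roc_auc(held, y))

    def test_training_auc_ordering(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=14)
        y = (x > -0.2).astype(int)
        y[:2] = 1 - y[:2]
        report, _ = loocv_evaluate(x, y)
        assert report.auc_training_best >= report.auc_training_mean
        assert report.auc_training_mean >= report.auc_training_worst

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            loocv_evaluate(np.array([1.0, 2.0]), np.array([0, 1]))


class TestCasePipeline:
    def test_case_table_shape(self):
        cases = load_cases()
        assert len(cases) == 14
        assert sum(c.damage for c in cases) == 9

    def test_predictions_order_preserving(self, standin_model):
        table = predict_cases(standin_model)
        assert len(table) == 14
        assert table["animal"].tolist() == [c.animal for c in load_cases()]

    def test_duplicate_input_cases_identical_metrics(self, standin_model):
        table = predict_cases(standin_model)
        row_ii = table[table["animal"] == "II"].iloc[0]
        row_vii = table[table["animal"] == "VII"].iloc[0]
        for m in METRIC_NAMES:
            assert row_ii[m] == row_vii[m]

    def test_least_severe_case_has_smallest_mps(self, standin_model):
        table = predict_cases(standin_model)
        assert table.loc[table["mps"].idxmin(), "animal"] == "XIII"

    def test_full_evaluation_structure(self, standin_model):
        evaluations = evaluate_all_metrics(standin_model)
        table = summary_table(evaluations)
        assert len(table) == 4
        score_cols = ["accuracy", "sensitivity", "specificity", "auc_testing",
                      "auc_training_mean"]
        assert table[score_cols].map(lambda v: 0 <= v <= 1).all().all()

    def test_scaled_metrics_share_rank_statistics(self, standin_model):
        # mss is a positive multiple of mps: identical case ranking, hence
        # identical Wilcoxon p and identical AUCs
        evaluations = evaluate_all_metrics(standin_model)
        assert evaluations["mps"].wilcoxon_p == evaluations["mss"].wilcoxon_p
        assert evaluations["mps"].loocv.auc_testing == pytest.approx(
            evaluations["mss"].loocv.auc_testing
        )

    def test_full_data_fit_never_completely_separated(self, standin_model):
        evaluations = evaluate_all_metrics(standin_model)
        for ev in evaluations.values():
            assert not ev.risk_model.separation

    def test_monotone_transform_leaves_p_and_auc(self, standin_model):
        table = predict_cases(standin_model)
        y = table["damage"].to_numpy()
        x = table["mps"].to_numpy()
        for fn in (np.log, np.sqrt, lambda v: v**3):
            assert wilcoxon_rank_sum_exact(fn(x[y == 1]), fn(x[y == 0])) == \
                wilcoxon_rank_sum_exact(x[y == 1], x[y == 0])
            assert roc_auc(fn(x), y) == pytest.approx(roc_auc(x, y))

    def test_out_of_bounds_case_named(self, standin_model):
        from contusim.risk import CaseRecord

        with pytest.raises(ValueError, match="XV"):
            CaseRecord("XV", depth_mm=20.0, velocity_mps=1.0, damage=1)
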