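"""Prediction-suite tests: LOOCV against a brute-force statsmodels oracle,
trapezoid-vs-concordance AUC equivalence, cutoff selection, DeLong test
(frozen against R's pROC), bootstrap CI behavior, and the preset model suite.
"""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from swe_response.features import visit_features_table
from swe_response.pathology import score_pathology_table
from swe_response.prediction import (
    MODEL_SPECS,
    SeparationWarning,
    auc_confidence_interval,
    compare_aucs,
    feature_matrix,
    loocv_probabilities,
    optimal_cutoff,
    rank_auc,
    roc_and_auc,
    run_model_suite,
    summarize_model_suite,
)


def concordance_auc(scores, y):
    """Exhaustive pairwise concordance with ties counted 1/2 (oracle)."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_all_tied_scores_give_half(self):
        y = np.array([0, 1, 0, 1, 1])
        res = roc_and_auc(np.full(5, 0.3), y)
        assert res.auc == pytest.approx(0.5)

    def test_perfect_ranking_gives_one(self):
        res = roc_and_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.auc == pytest.approx(1.0)

    def test_one_swapped_pair(self):
        # 6 class pairs, one discordant (0.3 vs 0.4) -> AUC = 5/6
        res = roc_and_auc([0.9, 0.8, 0.3, 0.4, 0.2], [1, 1, 1, 0, 0])
        assert res.auc == pytest.approx(5.0 / 6.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_and_auc([0.1, 0.2], [1, 1])

    def test_roc_is_monotone_step_curve(self, rng):
        scores = rng.uniform(size=40)
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        res = roc_and_auc(scores, y)
        assert res.fpr[0] == 0 and res.tpr[0] == 0
        assert res.fpr[-1] == 1 and res.tpr[-1] == 1
        assert (np.diff(res.fpr) >= 0).all()
        assert (np.diff(res.tpr) >= 0).all()

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_trapezoid_equals_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 15))
        scores = np.round(rng.uniform(size=n), 1)  # force ties
        y = rng.integers(0, 2, size=n)
        if y.sum() in (0, n):
            return
        res = roc_and_auc(scores, y)
        assert res.auc == pytest.approx(concordance_auc(scores, y), abs=1e-12)
        assert rank_auc(scores, y) == pytest.approx(res.auc, abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.uniform(size=20)
        y = rng.integers(0, 2, size=20)
        if y.sum() in (0, 20):
            return
        a = roc_and_auc(scores, y).auc
        b = roc_and_auc(np.exp(3 * scores), y).auc
        assert a == pytest.approx(b, abs=1e-12)


class TestLoocv:
    def test_matches_brute_force_statsmodels_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        for _ in range(3):
            n = 18
            X = rng.normal(size=(n, 2))
            y = (X[:, 0] + rng.normal(scale=1.5, size=n) > 0).astype(int)
            if min(y.sum(), n - y.sum()) < 4:
                continue
            probs = loocv_probabilities(X, y)
            oracle = np.empty(n)
            for i in range(n):
                mask = np.ones(n, bool)
                mask[i] = False
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.Logit(y[mask], sm.add_constant(X[mask])).fit(
                        disp=0, method="newton", tol=1e-12
                    )
                oracle[i] = fit.predict(np.concatenate([[1.0], X[i]]))[0]
            np.testing.assert_allclose(probs, oracle, atol=1e-8)

    def test_constant_feature_returns_fold_prevalence(self):
        y = np.array([1] * 6 + [0] * 6)
        probs = loocv_probabilities(np.ones((12, 1)), y)
        # with sample i held out, prevalence is 5/11 (positives) or 6/11
        np.testing.assert_allclose(probs[y == 1], 5 / 11, atol=1e-6)
        np.testing.assert_allclose(probs[y == 0], 6 / 11, atol=1e-6)

    def test_separable_feature_ridge_fallback_and_perfect_auc(self):
        x = np.linspace(-3, 3, 14)[:, None]
        y = (x[:, 0] > 0).astype(int)
        with pytest.warns(SeparationWarning):
            probs = loocv_probabilities(x, y)
        # each fold trains its own stabilized model, so the two boundary
        # samples' held-out probabilities may swap; discrimination stays
        # essentially perfect
        assert roc_and_auc(probs, y).auc >= 0.95
        assert probs[y == 1].mean() > 0.9 and probs[y == 0].mean() < 0.1

    def test_row_order_invariance(self, rng):
        X = rng.normal(size=(16, 2))
        y = (X[:, 0] > 0).astype(int)
        y[0], y[-1] = 1, 0
        X[:, 0] += rng.normal(scale=2.0, size=16)  # avoid separation
        probs = loocv_probabilities(X, y)
        perm = rng.permutation(16)
        probs_perm = loocv_probabilities(X[perm], y[perm])
        np.testing.assert_allclose(probs_perm, probs[perm], atol=1e-10)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            loocv_probabilities(np.ones((5, 1)), [0, 1, 0, 1, 0])

    def test_single_class_fold_rejected(self):
        X = np.random.default_rng(0).normal(size=(11, 1))
        y = np.array([1] + [0] * 10)  # removing the one positive breaks a fold
        with pytest.raises(ValueError, match="both classes"):
            loocv_probabilities(X, y)


class TestOptimalCutoff:
    def test_perfect_classifier(self):
        res = roc_and_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        cut = optimal_cutoff(res)
        assert cut["sensitivity"] == 1.0 and cut["specificity"] == 1.0

    def test_matches_brute_force_search(self, rng):
        scores = rng.uniform(size=25)
        y = rng.integers(0, 2, size=25)
        y[:2] = [0, 1]
        res = roc_and_auc(scores, y)
        cut = optimal_cutoff(res)
        dists = np.hypot(1 - res.tpr, res.fpr)
        assert np.hypot(1 - cut["sensitivity"], 1 - cut["specificity"]) == (
            pytest.approx(dists.min())
        )

    def test_cutoff_point_lies_on_roc(self, rng):
        scores = rng.uniform(size=30)
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        res = roc_and_auc(scores, y)
        cut = optimal_cutoff(res)
        pairs = set(zip(np.round(res.tpr, 12), np.round(1 - res.fpr, 12)))
        assert (round(cut["sensitivity"], 12), round(cut["specificity"], 12)) in pairs

    def test_useless_scores_tie_break_prefers_sensitivity(self):
        res = roc_and_auc(np.full(10, 0.5), [0, 1] * 5)
        cut = optimal_cutoff(res)
        # diagonal ROC: (0,0) and (1,1) are equidistant; pick sensitivity 1
        assert cut["sensitivity"] == 1.0


class TestBootstrapCi:
    def test_deterministic_given_seed(self, rng):
        probs = rng.uniform(size=30)
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        a = auc_confidence_interval(probs, y, seed=5, n_boot=300)
        b = auc_confidence_interval(probs, y, seed=5, n_boot=300)
        assert a == b

    def test_contains_point_estimate(self, rng):
        probs = rng.uniform(size=40)
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        lo, hi = auc_confidence_interval(probs, y, seed=1, n_boot=300)
        auc = rank_auc(probs, y)
        assert lo <= auc <= hi

    def test_separable_data_collapses_to_one(self):
        probs = np.array([0.1] * 10 + [0.9] * 10)
        y = np.array([0] * 10 + [1] * 10)
        lo, hi = auc_confidence_interval(probs, y, seed=2, n_boot=300)
        assert hi == 1.0
        assert lo == 1.0

    def test_coverage_of_binormal_truth(self):
        # known binormal separation: AUC = Phi(1/sqrt(2)) ~ 0.760
        from scipy.stats import norm

        truth = float(norm.cdf(1 / np.sqrt(2)))
        rng = np.random.default_rng(99)
        hits = 0
        reps = 60
        for _ in range(reps):
            neg = rng.normal(0, 1, 60)
            pos = rng.normal(1, 1, 60)
            scores = np.concatenate([neg, pos])
            y = np.array([0] * 60 + [1] * 60)
            lo, hi = auc_confidence_interval(
                scores, y, seed=int(rng.integers(2**31)), n_boot=400
            )
            hits += lo <= truth <= hi
        assert hits / reps >= 0.85


class TestDeLong:
    def _paired_results(self, pa, pb, y):
        ids = np.arange(len(y))
        return (
            roc_and_auc(pa, y, patient_ids=ids),
            roc_and_auc(pb, y, patient_ids=ids),
        )

    def test_identical_models_give_p_one(self, rng):
        probs = rng.uniform(size=30)
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        ra, rb = self._paired_results(probs, probs, y)
        assert compare_aucs(ra, rb) == pytest.approx(1.0)

    def test_frozen_against_r_proc(self):
        # expected p computed once with pROC::roc.test(method="delong", paired=TRUE)
        y = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
        a = np.array([0.1, 0.2, 0.3, 0.35, 0.4, 0.5, 0.55, 0.6, 0.7, 0.8, 0.9, 0.95])
        b = np.array([0.3, 0.1, 0.4, 0.2, 0.5, 0.45, 0.7, 0.3, 0.6, 0.65, 0.8, 0.5])
        ra, rb = self._paired_results(a, b, y)
        assert compare_aucs(ra, rb) == pytest.approx(0.2850494074, abs=1e-9)

    def test_null_type_i_error_near_level(self):
        rng = np.random.default_rng(321)
        rejections = 0
        reps = 200
        for _ in range(reps):
            n = 80
            y = np.array([0] * 40 + [1] * 40)
            base = rng.normal(size=n) + y  # informative shared signal
            pa = base + rng.normal(scale=0.8, size=n)
            pb = base + rng.normal(scale=0.8, size=n)
            ra, rb = self._paired_results(pa, pb, y)
            rejections += compare_aucs(ra, rb) < 0.05
        assert 0.01 <= rejections / reps <= 0.11

    def test_strong_alternative_detected(self):
        rng = np.random.default_rng(11)
        n = 200
        y = np.array([0] * 100 + [1] * 100)
        perfect = y + rng.uniform(0, 0.1, size=n)
        noise = rng.uniform(size=n)
        ra, rb = self._paired_results(perfect, noise, y)
        assert compare_aucs(ra, rb) < 0.001

    def test_restricted_to_shared_patients(self, rng):
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        probs = rng.uniform(size=40)
        ra = roc_and_auc(probs, y, patient_ids=np.arange(40))
        rb = roc_and_auc(probs[:30], y[:30], patient_ids=np.arange(30))
        assert compare_aucs(ra, rb) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def matrix(study_cohort):
    feats = visit_features_table(study_cohort.visits)
    pathology = score_pathology_table(study_cohort.patients)
    return feature_matrix(feats, pathology)


class TestModelSuite:
    def test_six_presets_produce_full_report(self, matrix):
        results = run_model_suite(matrix, ci_boot=200, seed=0)
        assert set(results) == {s.name for s in MODEL_SPECS}
        report = summarize_model_suite(results)
        assert len(report) == 6
        assert report.notna().all().all()
        assert ((report["auc"] >= 0) & (report["auc"] <= 1)).all()
        assert (report["auc_ci_lo"] <= report["auc"]).all()
        assert (report["auc"] <= report["auc_ci_hi"]).all()

    def test_mixed_models_restricted_to_er_positive(self, matrix):
        results = run_model_suite(matrix, ci_boot=100, seed=0)
        n_er_pos = int(matrix["er_pos"].sum())
        assert results["mixed_v1"].n_used <= n_er_pos
        assert results["noninvasive_v1"].n_used > results["mixed_v1"].n_used

    def test_shuffled_labels_give_null_aucs(self, study_cohort):
        feats = visit_features_table(study_cohort.visits)
        pathology = score_pathology_table(study_cohort.patients)
        rng = np.random.default_rng(8)
        shuffled = pathology.copy()
        shuffled["responder"] = rng.permutation(
            shuffled["responder"].to_numpy()
        )
        matrix = feature_matrix(feats, shuffled)
        results = run_model_suite(
            matrix, specs=MODEL_SPECS[:3], ci_boot=100, seed=0
        )
        for r in results.values():
            assert abs(r.auc - 0.5) < 0.25  # null behavior at n ~ 60

    def test_sparse_preset_skipped_with_warning(self, matrix):
        tiny = matrix.head(5)
        with pytest.warns(UserWarning, match="complete cases"):
            results = run_model_suite(tiny, specs=MODEL_SPECS[:1], ci_boot=100)
        assert results == {}
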