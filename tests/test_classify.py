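"""Task labeling, closed-form LDA, leave-one-out CV and ROC/AUC."""


import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal, norm

from cesm_radiomics import (
    TASKS,
    CohortConfig,
    binarize_labels,
    extract_cohort_features,
    features_to_frame,
    fit_lda,
    generate_cohort,
    lda_score,
    loo_cv,
    roc_auc,
    run_all_tasks,
    task_summary_frame,
)
from cesm_radiomics.cohort_io import LesionRecord

from oracle_utils import pairwise_auc

TASK = {t.name: t for t in TASKS}


def _record(**kw):
    base = dict(lesion_id="L0", patient_id="P0", er_pct=50.0, pr_pct=50.0,
                ki67_pct=50.0, her2="-", grade="G2")
    base.update(kw)
    return LesionRecord(**base)


class TestBinarize:
    @pytest.mark.parametrize("er,expected", [(0.5, 0), (1.0, 1), (99.0, 1), (0.0, 0)])
    def test_er_cutoff_is_inclusive_at_one_percent(self, er, expected):
        y, _, _ = binarize_labels([_record(er_pct=er)], TASK["ER"])
        assert y[0] == expected

    @pytest.mark.parametrize("task,field,cut", [("PR", "pr_pct", 20.0), ("Ki67", "ki67_pct", 20.0)])
    def test_twenty_percent_cutoffs(self, task, field, cut):
        below, _, _ = binarize_labels([_record(**{field: cut - 0.01})], TASK[task])
        at, _, _ = binarize_labels([_record(**{field: cut})], TASK[task])
        assert below[0] == 0 and at[0] == 1

    def test_grade_task_splits_g3_from_g1_g2(self):
        for grade, expected in (("G1", 0), ("G2", 0), ("G3", 1)):
            y, _, _ = binarize_labels([_record(grade=grade)], TASK["Grade"])
            assert y[0] == expected

    def test_triple_negative_requires_all_three_negative(self):
        tn = _record(er_pct=0.0, pr_pct=0.0, her2="-")
        y, n_pos, n_neg = binarize_labels([tn], TASK["TN"])
        assert y[0] == 1 and n_pos == 1 and n_neg == 0
        her2_blocks = _record(er_pct=0.0, pr_pct=0.0, her2="+")
        assert binarize_labels([her2_blocks], TASK["TN"])[0][0] == 0
        pr_blocks = _record(er_pct=0.0, pr_pct=30.0, her2="-")
        assert binarize_labels([pr_blocks], TASK["TN"])[0][0] == 0


class TestLDA:
    def test_matches_reference_implementation(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = rng.normal(size=(12, 3))
        y = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
        X[y == 1] += 1.0
        model = fit_lda(X, y, ridge=0.0)
        ref = LinearDiscriminantAnalysis(store_covariance=True).fit(X, y)
        assert np.allclose(model.class_means, ref.means_, atol=1e-10)
        n = len(y)
        assert np.allclose(model.pooled_covariance * (n - 2) / n, ref.covariance_,
                           atol=1e-8)
        # the scores are a strictly increasing transform of the reference
        # decision function, so the rankings (and AUC) agree exactly
        ours = lda_score(model, X)
        theirs = ref.decision_function(X)
        _, auc_ours = roc_auc(ours, y)
        _, auc_ref = roc_auc(theirs, y)
        assert auc_ours == pytest.approx(auc_ref, abs=1e-12)
        assert np.all(np.diff(theirs[np.argsort(ours)]) > 0)

    def test_symmetric_one_dimensional_threshold(self, rng):
        x = np.concatenate([rng.normal(0, 1, 5000), rng.normal(2, 1, 5000)])[:, None]
        y = np.repeat([0, 1], 5000)
        model = fit_lda(x, y)
        # equal priors and variance: decision point near the midpoint x = 1
        s_lo = lda_score(model, np.array([0.0]))
        s_hi = lda_score(model, np.array([2.0]))
        assert s_lo < 0 < s_hi
        root = 1.0 - lda_score(model, np.array([1.0])) / (s_hi - s_lo) * 2.0
        assert root == pytest.approx(1.0, abs=0.15)

    def test_duplicated_column_is_singular_at_zero_ridge(self, rng):
        X = rng.normal(size=(20, 2))
        X = np.hstack([X, X[:, :1]])
        y = np.repeat([0, 1], 10)
        with pytest.raises(ValueError, match="ridge"):
            fit_lda(X, y, ridge=0.0)

    def test_one_class_input_rejected(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            fit_lda(rng.normal(size=(6, 2)), np.zeros(6, dtype=int))

    def test_midpoint_scores_zero_with_equal_priors(self, rng):
        X = rng.normal(size=(16, 4))
        y = np.repeat([0, 1], 8)
        X[y == 1] += 0.7
        model = fit_lda(X, y, ridge=1e-8)
        mid = model.class_means.mean(axis=0)
        assert lda_score(model, mid) == pytest.approx(0.0, abs=1e-10)

    def test_score_is_affine_along_discriminant_direction(self, rng):
        X = rng.normal(size=(30, 3))
        y = (rng.random(30) < 0.5).astype(int)
        y[:2] = [0, 1]
        model = fit_lda(X, y, ridge=1e-6)
        x0 = rng.normal(size=3)
        d = np.linalg.solve(model.pooled_covariance,
                            model.class_means[1] - model.class_means[0])
        ts = np.linspace(-2, 2, 7)
        scores = np.array([lda_score(model, x0 + t * d) for t in ts])
        assert np.allclose(np.diff(scores, 2), 0.0, atol=1e-8)

    def test_sigmoid_of_score_equals_gaussian_posterior(self, rng):
        X = rng.normal(size=(40, 3))
        y = (rng.random(40) < 0.4).astype(int)
        y[:4] = [0, 0, 1, 1]
        model = fit_lda(X, y, ridge=0.0)
        x = rng.normal(size=3)
        s = lda_score(model, x)
        like = np.array([
            multivariate_normal.pdf(x, mean=model.class_means[k],
                                    cov=model.pooled_covariance)
            for k in (0, 1)
        ])
        post = like[1] * model.priors[1] / (like * model.priors).sum()
        assert 1.0 / (1.0 + np.exp(-s)) == pytest.approx(post, rel=1e-10)


class TestLOO:
    def test_equals_independent_refits(self, rng):
        X = rng.normal(size=(8, 2))
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        scores = loo_cv(X, y, ridge=1e-6)
        for i in range(8):
            keep = np.arange(8) != i
            model = fit_lda(X[keep], y[keep], ridge=1e-6)
            assert scores[i] == pytest.approx(lda_score(model, X[i]), rel=1e-12)

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.tile([0, 1], 6)
        perm = rng.permutation(12)
        a = loo_cv(X, y, ridge=1e-6)
        b = loo_cv(X[perm], y[perm], ridge=1e-6)
        assert np.allclose(a[perm], b, rtol=1e-10)

    def test_separable_case_signs(self):
        X = np.array([[-2.0], [-1.5], [1.5], [2.0], [-1.8], [1.8]])
        y = np.array([0, 0, 1, 1, 0, 1])
        scores = loo_cv(X, y, ridge=1e-9)
        assert np.all(np.sign(scores) == np.where(y == 1, 1, -1))

    def test_emptying_a_class_is_infeasible(self):
        X = np.arange(10, dtype=float).reshape(5, 2)
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="infeasible|class"):
            loo_cv(X, y)

    def test_within_fold_standardization_does_not_inflate_null_auc(self, rng):
        # labels independent of features: the LOO AUC should hover at chance
        X = rng.normal(size=(60, 5))
        y = np.tile([0, 1], 30)
        _, auc = roc_auc(loo_cv(X, y, standardize=True), y)
        assert 0.25 < auc < 0.75

    def test_bayes_auc_recovered_for_separated_gaussians(self, rng):
        # two equal-covariance Gaussians at Mahalanobis distance D: the
        # optimal linear rule attains AUC = Phi(D / sqrt(2))
        d = 2.0
        n = 800
        X = rng.normal(size=(n, 3))
        y = np.tile([0, 1], n // 2)
        X[y == 1, 0] += d
        _, auc = roc_auc(loo_cv(X, y, ridge=1e-9), y)
        assert auc == pytest.approx(norm.cdf(d / np.sqrt(2)), abs=0.04)


class TestROC:
    def test_perfect_separation(self):
        pts, auc = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert auc == 1.0
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)

    def test_all_ties_give_half(self):
        _, auc = roc_auc([1.0] * 10, [0, 1] * 5)
        assert auc == pytest.approx(0.5)

    def test_trapezoid_equals_pairwise_identity(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 40))
            y = rng.integers(0, 2, size=n)
            y[:2] = [0, 1]
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            _, auc = roc_auc(scores, y)
            assert auc == pytest.approx(pairwise_auc(scores, y), abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), slope=st.floats(0.1, 5.0), offset=st.floats(-3, 3))
    def test_auc_invariant_under_strictly_increasing_transforms(self, seed, slope, offset):
        r = np.random.default_rng(seed)
        n = 25
        scores = r.normal(size=n)
        y = r.integers(0, 2, size=n)
        y[:2] = [0, 1]
        _, auc = roc_auc(scores, y)
        for transform in (lambda s: slope * s + offset, np.tanh, lambda s: np.exp(0.3 * s)):
            _, auc_t = roc_auc(transform(scores), y)
            assert auc_t == pytest.approx(auc, abs=1e-12)

    def test_curve_is_monotone(self, rng):
        scores = rng.normal(size=50)
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        pts, _ = roc_auc(scores, y)
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])


class TestRunAllTasks:
    def test_six_tasks_reported(self, small_cohort, small_features):
        _, records, _ = small_cohort
        results = run_all_tasks(small_features, records)
        assert [r.task.name for r in results] == ["ER", "PR", "Ki67", "Grade", "TN", "HER2"]
        summary = task_summary_frame(results)
        assert len(summary) == 6
        for res in results:
            if res.feasible:
                assert 0.0 <= res.auc <= 1.0
                assert len(res.loo_scores) == res.n_pos + res.n_neg

    def test_undersized_class_degrades_gracefully(self, rng):
        # one single TN-positive lesion: that task is infeasible, others run
        records = []
        for i in range(20):
            records.append(_record(lesion_id=f"L{i:04d}", patient_id=f"P{i:04d}",
                                   er_pct=float(rng.uniform(30, 90)),
                                   pr_pct=float(rng.uniform(0, 90)),
                                   ki67_pct=float(rng.uniform(0, 90)),
                                   her2="+" if i % 3 == 0 else "-",
                                   grade=("G1", "G2", "G3")[i % 3]))
        records[0] = _record(lesion_id="L0000", patient_id="P0000",
                             er_pct=0.0, pr_pct=0.0, her2="-")
        cfg = CohortConfig(n_lesions=20, seed=55, image_size=32, roi_radius_px=8)
        _, pairs = generate_cohort(cfg)
        feats = features_to_frame(extract_cohort_features(pairs))
        feats.index = [r.lesion_id for r in records]
        results = {r.task.name: r for r in run_all_tasks(feats, records)}
        assert not results["TN"].feasible
        assert "too small" in results["TN"].reason
        assert results["Ki67"].feasible

    def test_planted_her2_separation_yields_high_auc(self):
        cfg = CohortConfig(n_lesions=68, seed=2024,
                           effect_map=(("her2", "RC_VC", 1.5),
                                       ("her2", "RC_Mean", 1.5)))
        records, pairs = generate_cohort(cfg)
        feats = features_to_frame(extract_cohort_features(pairs))
        results = {r.task.name: r for r in run_all_tasks(feats, records)}
        assert results["HER2"].feasible
        assert results["HER2"].auc > 0.75
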