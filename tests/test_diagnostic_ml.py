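import numpy as np
import pytest

from actidx import (
    TASKS,
    clopper_pearson,
    f1_score_pct,
    feature_importance,
    fit_logistic,
    loocv_probabilities,
    mrmr_rank,
    nested_loocv_predict,
    optimal_threshold,
    performance_metrics,
    sfs_select,
    single_feature_baseline,
)
from actidx.diagnostic_ml import ClassificationResult, MLConfig


# ---------------------------------------------------------------------------
# logistic solver
# ---------------------------------------------------------------------------

class TestLogisticSolver:
    def test_matches_sklearn_unregularized(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 3))
        y = (rng.random(80) < 1 / (1 + np.exp(-(0.5 + X @ [1.0, -0.7, 0.2])))
             ).astype(int)
        beta = fit_logistic(X, y)
        sk = LogisticRegression(C=1e10, tol=1e-10, max_iter=2000)
        sk.fit(X, y)
        np.testing.assert_allclose(beta[0], sk.intercept_[0], atol=1e-4)
        np.testing.assert_allclose(beta[1:], sk.coef_[0], atol=1e-4)

    def test_separation_stays_finite(self):
        X = np.linspace(-1, 1, 20)[:, None]
        y = (X[:, 0] > 0).astype(int)
        beta = fit_logistic(X, y, coef_cap=15.0)
        assert np.abs(beta).max() <= 15.0

    def test_loocv_matches_per_fold_refits(self):
        rng = np.random.default_rng(9)
        for rep in range(3):
            X = rng.normal(size=(25, 3))
            y = (rng.random(25) < 0.5).astype(int)
            y[:3] = 1
            y[-3:] = 0
            fast = loocv_probabilities(X, y.astype(float))
            slow = np.empty(25)
            from scipy.special import expit
            for i in range(25):
                tr = np.ones(25, bool)
                tr[i] = False
                b = fit_logistic(X[tr], y[tr])
                slow[i] = expit(b[0] + X[i] @ b[1:])
            np.testing.assert_allclose(fast, slow, atol=1e-4)


# ---------------------------------------------------------------------------
# mRMR
# ---------------------------------------------------------------------------

def mrmr_reference(X, y, k):
    """Independent greedy mRMR with explicit-loop MI estimation."""
    from collections import Counter

    def discretize(v):
        q1, q2 = np.quantile(v, [1 / 3, 2 / 3])
        return (v > q1).astype(int) + (v > q2).astype(int)

    def mi(a, b):
        n = len(a)
        cab = Counter(zip(a.tolist(), b.tolist()))
        ca, cb = Counter(a.tolist()), Counter(b.tolist())
        total = 0.0
        for (va, vb), c in cab.items():
            p = c / n
            total += p * np.log(p / (ca[va] / n * cb[vb] / n))
        return total

    p = X.shape[1]
    codes = [discretize(X[:, j]) for j in range(p)]
    rel = [mi(codes[j], np.asarray(y)) for j in range(p)]
    selected = [int(np.argmax(rel))]
    while len(selected) < k:
        best, bj = -np.inf, None
        for j in range(p):
            if j in selected:
                continue
            red = np.mean([mi(codes[j], codes[s]) for s in selected])
            score = rel[j] - red
            if score > best + 1e-12:
                best, bj = score, j
        selected.append(bj)
    return selected


class TestMrmr:
    def test_label_copy_ranked_first(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 15)
        X = np.column_stack([y + 0.0, rng.normal(size=30),
                             rng.normal(size=30)])
        assert mrmr_rank(X, y, 3)[0] == 0

    def test_matches_reference_greedy(self):
        rng = np.random.default_rng(2)
        y = (rng.random(20) < 0.5).astype(int)
        X = rng.normal(size=(20, 6))
        X[:, 0] += y          # relevant
        X[:, 1] = X[:, 0]     # redundant copy
        assert mrmr_rank(X, y, 6) == mrmr_reference(X, y, 6)

    def test_duplicate_feature_penalized(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 20)
        a = y + rng.normal(0, 0.3, size=40)
        weak = y + rng.normal(0, 2.0, size=40)
        X = np.column_stack([a, a.copy(), weak])
        order = mrmr_rank(X, y, 3)
        assert order[0] == 0
        assert order[1] == 2  # the weak-but-new feature beats the copy

    def test_constant_feature_zero_relevance_no_nan(self):
        y = np.repeat([0, 1], 10)
        X = np.column_stack([np.ones(20), y + 0.0])
        order = mrmr_rank(X, y, 2)
        assert order[0] == 1

    def test_k_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            mrmr_rank(np.ones((4, 2)), np.array([0, 1, 0, 1]), 0)


# ---------------------------------------------------------------------------
# SFS
# ---------------------------------------------------------------------------

class TestSfs:
    def test_perfect_separator_selected_alone(self):
        rng = np.random.default_rng(5)
        y = np.repeat([0.0, 1.0], 15)
        X = np.column_stack([rng.normal(size=30), 3.0 * (y - 0.5),
                             rng.normal(size=30)])
        assert sfs_select(X, y, [1, 0, 2]) == [1]

    @staticmethod
    def _complementary_pair():
        # two noisy label copies with perturbations on disjoint subjects:
        # either alone misclassifies its perturbed subjects, while their
        # average classifies everyone correctly
        y = np.repeat([0.0, 1.0], 15)
        x0, x1 = y.copy(), y.copy()
        bad0 = [0, 1, 2, 15, 16, 17]
        bad1 = [3, 4, 5, 18, 19, 20]
        x0[bad0] += 0.9 * (1 - 2 * y[bad0])   # push across the boundary
        x1[bad1] += 0.9 * (1 - 2 * y[bad1])
        noise = np.sin(np.arange(30) * 2.17)
        return np.column_stack([x0, x1, noise]), y

    def test_max_features_cap_truncates(self):
        X, y = self._complementary_pair()
        assert len(sfs_select(X, y, [0, 1, 2], max_features=1)) == 1
        sel = sfs_select(X, y, [0, 1, 2], max_features=2)
        assert sorted(sel) == [0, 1]

    def test_noise_candidates_rarely_selected(self):
        # pure-noise candidates with balanced labels: selection stops at
        # zero or one feature in at least 80% of seeded runs
        lens = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.repeat([0.0, 1.0], 15)
            X = rng.normal(size=(30, 10))
            lens.append(len(sfs_select(X, y, list(range(10)))))
        assert sum(n <= 1 for n in lens) >= 16


# ---------------------------------------------------------------------------
# nested LOOCV
# ---------------------------------------------------------------------------

class TestNestedLoocv:
    def test_label_feature_gives_perfect_accuracy(self):
        rng = np.random.default_rng(7)
        y = np.repeat([0, 1], 12)
        X = np.column_stack([y + rng.normal(0, 0.05, 24),
                             rng.normal(size=24)])
        res = nested_loocv_predict(X, y)
        assert np.all((res.probabilities > 0.5) == (y == 1))

    def test_one_probability_per_subject_and_fold_logs(self):
        rng = np.random.default_rng(8)
        y = np.repeat([0, 1], 10)
        X = rng.normal(size=(20, 15))
        res = nested_loocv_predict(X, y, config=MLConfig(mrmr_k=5,
                                                         sfs_max=3))
        assert len(res.probabilities) == 20
        assert len(res.fold_features) == 20
        assert all(len(f) <= 3 for f in res.fold_features)

    def test_missing_values_rejected(self):
        X = np.ones((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            nested_loocv_predict(X, np.repeat([0, 1], 5))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            nested_loocv_predict(np.random.default_rng(0).normal(size=(8, 2)),
                                 np.zeros(8, dtype=int))


# ---------------------------------------------------------------------------
# threshold optimization
# ---------------------------------------------------------------------------

def roc_distance(probs, y, thr):
    pred = probs > thr
    sens = np.sum(pred & (y == 1)) / np.sum(y == 1)
    spec = np.sum(~pred & (y == 0)) / np.sum(y == 0)
    return np.hypot(1 - sens, 1 - spec)


class TestOptimalThreshold:
    def test_perfect_separation_zero_distance(self):
        y = np.repeat([0, 1], 5)
        probs = np.concatenate([np.linspace(0, 0.3, 5),
                                np.linspace(0.7, 1, 5)])
        thr = optimal_threshold(probs, y)
        assert roc_distance(probs, y, thr) == 0.0

    def test_binary_probabilities(self):
        y = np.array([0, 0, 1, 1])
        thr = optimal_threshold(y.astype(float), y)
        assert roc_distance(y.astype(float), y, thr) == 0.0

    def test_matches_operating_point_enumeration(self):
        # oracle: every achievable (sens, spec) pair comes from splitting
        # the sorted distinct probabilities; take the corner-nearest one
        rng = np.random.default_rng(10)
        for _ in range(50):
            y = (rng.random(20) < 0.5).astype(int)
            if len(np.unique(y)) < 2:
                continue
            probs = np.round(rng.random(20), 2)   # force some ties
            uniq = np.sort(np.unique(probs))
            best = np.inf
            for k in range(len(uniq) + 1):
                pred = np.zeros(20, bool) if k == len(uniq) else (
                    probs >= uniq[k])
                sens = np.sum(pred & (y == 1)) / np.sum(y == 1)
                spec = np.sum(~pred & (y == 0)) / np.sum(y == 0)
                best = min(best, np.hypot(1 - sens, 1 - spec))
            thr = optimal_threshold(probs, y)
            assert roc_distance(probs, y, thr) == pytest.approx(best,
                                                                abs=1e-12)

    def test_six_point_worked_example(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        probs = np.array([0.1, 0.4, 0.6, 0.35, 0.7, 0.9])
        thr = optimal_threshold(probs, y)
        # exhaustive enumeration: the corner-nearest point is sens=2/3,
        # spec=1 at any threshold in [0.6, 0.7)
        assert roc_distance(probs, y, thr) == pytest.approx(1 / 3)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            optimal_threshold(np.array([0.2, 0.8]), np.array([1, 1]))


# ---------------------------------------------------------------------------
# performance metrics and exact intervals
# ---------------------------------------------------------------------------

class TestPerformanceMetrics:
    def test_confusion_identities_random(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            y = (rng.random(30) < 0.5).astype(int)
            if len(np.unique(y)) < 2:
                continue
            probs = rng.random(30)
            rep = performance_metrics(probs, y, 0.5)
            n = rep.tp + rep.fp + rep.tn + rep.fn
            assert n == 30
            assert rep.accuracy == pytest.approx(
                100 * (rep.tp + rep.tn) / n)
            if rep.tp + rep.fp > 0:
                assert rep.precision == pytest.approx(
                    100 * rep.tp / (rep.tp + rep.fp))
                if not np.isnan(rep.f1):
                    assert rep.f1 == pytest.approx(
                        2 * rep.precision * rep.sensitivity
                        / (rep.precision + rep.sensitivity))

    def test_f1_harmonic_identity(self):
        assert f1_score_pct(80.0, 80.0) == 80.0

    def test_all_correct_gives_saturated_metrics(self):
        y = np.repeat([0, 1], 10)
        rep = performance_metrics(y.astype(float), y, 0.5)
        assert (rep.sensitivity, rep.specificity, rep.accuracy,
                rep.precision, rep.f1) == (100.0,) * 5
        lo, hi = rep.ci["accuracy"]
        assert hi == 100.0
        assert lo == pytest.approx(100 * 0.025 ** (1 / 20))

    def test_no_predicted_positives_missing_precision(self):
        y = np.repeat([0, 1], 5)
        rep = performance_metrics(np.zeros(10), y, 0.5)
        assert np.isnan(rep.precision) and np.isnan(rep.f1)


class TestClopperPearson:
    def test_k_zero_closed_form(self):
        lo, hi = clopper_pearson(0, 20)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 20), rel=1e-10)

    def test_k_n_closed_form(self):
        lo, hi = clopper_pearson(20, 20)
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / 20), rel=1e-10)

    def test_symmetry(self):
        lo, hi = clopper_pearson(7, 25)
        lo2, hi2 = clopper_pearson(18, 25)
        assert lo == pytest.approx(1 - hi2)
        assert hi == pytest.approx(1 - lo2)

    def test_matches_statsmodels_beta_interval(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(3, 17), (10, 50), (49, 50)]:
            lo, hi = clopper_pearson(k, n)
            slo, shi = proportion_confint(k, n, method="beta")
            assert lo == pytest.approx(slo, abs=1e-10)
            assert hi == pytest.approx(shi, abs=1e-10)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(0, 0)


# ---------------------------------------------------------------------------
# baseline and importance
# ---------------------------------------------------------------------------

class TestSingleFeatureBaseline:
    def test_informative_feature_near_perfect(self):
        rng = np.random.default_rng(12)
        y = np.repeat([0, 1], 15)
        x = y + rng.normal(0, 0.05, 30)
        res = single_feature_baseline(x, y)
        assert np.mean((res.probabilities > 0.5) == (y == 1)) == 1.0

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError):
            single_feature_baseline(np.ones(10), np.repeat([0, 1], 5))

    def test_monotone_transform_preserves_roc_metrics(self):
        # probabilities of a full-data single-feature fit are monotone in
        # the feature, so ROC-derived metrics are transform-invariant
        from scipy.special import expit

        rng = np.random.default_rng(13)
        y = (rng.random(40) < 0.5).astype(int)
        y[:2], y[-2:] = 0, 1
        x = rng.normal(size=40) + 0.8 * y
        reps = []
        for feat in (x, np.exp(x / 2)):
            z = (feat - feat.mean()) / feat.std()
            b = fit_logistic(z[:, None], y)
            probs = expit(b[0] + b[1] * z)
            thr = optimal_threshold(probs, y)
            reps.append(performance_metrics(probs, y, thr))
        ma, mb = reps
        assert (ma.tp, ma.fp, ma.tn, ma.fn) == (mb.tp, mb.fp, mb.tn, mb.fn)


class TestFeatureImportance:
    def _result(self, fold_features, fold_coefs):
        n = len(fold_features)
        return ClassificationResult(
            subject_ids=[f"S{i}" for i in range(n)],
            y=np.zeros(n, dtype=int), probabilities=np.zeros(n),
            fold_features=fold_features,
            fold_coefs=[np.asarray(c, dtype=float) for c in fold_coefs],
            fold_intercepts=[0.0] * n, feature_names=["a", "b"], config={})

    def test_always_selected_constant_coef(self):
        res = self._result([["a"]] * 4, [[2.0]] * 4)
        imp = feature_importance(res)
        assert imp.loc[0, "feature"] == "a"
        assert imp.loc[0, "importance"] == 2.0

    def test_half_selected_averages_with_zeros(self):
        folds = [["a"]] * 5 + [[]] * 5
        coefs = [[1.0]] * 5 + [[]] * 5
        imp = feature_importance(self._result(folds, coefs))
        assert imp.loc[0, "importance"] == 0.5

    def test_never_selected_absent(self):
        imp = feature_importance(self._result([[]] * 3, [[]] * 3))
        assert imp.empty


class TestTaskDefinitions:
    def test_group_merging(self):
        diag = np.array(["AD", "DLB", "MixedAD", "VCD", "HC"])
        y, inc = TASKS["AD_vs_CVD"].labels(diag)
        assert inc.tolist() == [True, False, True, True, False]
        assert y.tolist() == [0, 1, 1]
        y2, inc2 = TASKS["HC_vs_disease"].labels(diag)
        assert inc2.all()
        assert y2.tolist() == [1, 1, 1, 1, 0]
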