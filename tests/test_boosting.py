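import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdboost.boosting import (
    BoostConfig,
    Leaf,
    PairBoostClassifier,
    WeightedDecisionTree,
    classifier_weight,
    fit_weak,
    normalizer,
    score_samples,
    train_strong,
    update_weights,
    weighted_error,
)
from mdboost.sampling import SamplingConfig, TrainingSet, build_training_set
from mdboost.similarity import gip_kernel, integrate_disease_similarity


def stump_oracle(X, y, w):
    """Exhaustive enumeration of every (feature, midpoint) stump.

    Returns the (feature, threshold) minimizing the weighted Gini impurity
    of the split, with the same tie-break as the implementation (lowest
    feature, then smallest threshold), or None if no split reduces
    impurity.
    """

    def gini(mask):
        wt = w[mask].sum()
        if wt == 0:
            return 0.0
        p = (w[mask] * y[mask]).sum() / wt
        return wt * 2 * p * (1 - p)

    p_all = (w * y).sum() / w.sum()
    parent = w.sum() * 2 * p_all * (1 - p_all)
    best = None
    for f in range(X.shape[1]):
        vals = np.unique(X[:, f])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2
            left = X[:, f] <= thr
            imp = gini(left) + gini(~left)
            if parent - imp > 1e-12 and (best is None or imp < best[0] - 1e-15):
                best = (imp, f, thr)
    return None if best is None else (best[1], best[2])


def synthetic_training_set(seed, n_pos=40, n_neg=40, p=6):
    """Noisy two-cluster classification set with uniform weights."""
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [
            rng.normal(0.35, 0.18, (n_pos, p)),
            rng.normal(0.65, 0.18, (n_neg, p)),
        ]
    ).clip(0, 1)
    y = np.r_[np.ones(n_pos, dtype=np.int8), np.zeros(n_neg, dtype=np.int8)]
    n = n_pos + n_neg
    return TrainingSet(X, y, np.full(n, 1 / n))


class TestWeakLearner:
    def test_separable_stump_finds_midpoint(self):
        X = np.array([[0.1], [0.2], [0.8], [0.9]])
        y = np.array([0, 0, 1, 1])
        tree = fit_weak(X, y, np.full(4, 0.25), max_depth=1)
        assert tree.root_.feature == 0
        assert tree.root_.threshold == pytest.approx(0.5)
        assert weighted_error(tree.predict(X), y, np.full(4, 0.25)) == 0.0

    def test_single_class_input_yields_single_leaf(self):
        X = np.random.default_rng(0).random((5, 2))
        tree = fit_weak(X, np.ones(5, dtype=int), np.full(5, 0.2))
        assert isinstance(tree.root_, Leaf)
        assert tree.root_.fraction == 1.0

    def test_dominant_weight_sample_decides_its_leaf(self):
        X = np.array([[0.1], [0.2], [0.8], [0.9]])
        y = np.array([1, 0, 0, 0])
        w = np.array([0.97, 0.01, 0.01, 0.01])
        tree = fit_weak(X, y, w, max_depth=1)
        assert tree.predict(np.array([[0.1]]))[0] == 1

    def test_leaf_fraction_is_weighted_positive_proportion(self):
        X = np.array([[0.1], [0.2], [0.8], [0.9]])
        y = np.array([0, 1, 1, 0])
        w = np.array([0.4, 0.2, 0.2, 0.2])
        tree = fit_weak(X, y, w, max_depth=1)
        # optimal Gini split isolates the heavy negative: threshold 0.15,
        # right leaf holds weights (.2, .2, .2) with two positives
        assert tree.root_.threshold == pytest.approx(0.15)
        fracs = tree.positive_fraction(np.array([[0.0], [1.0]]))
        np.testing.assert_allclose(fracs, [0.0, 2 / 3])

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        n=st.integers(4, 20),
        p=st.integers(1, 3),
        seed=st.integers(0, 10_000),
    )
    def test_stump_matches_exhaustive_enumeration(self, n, p, seed):
        rng = np.random.default_rng(seed)
        X = np.round(rng.random((n, p)), 2)
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            return
        w = rng.random(n) + 0.05
        w /= w.sum()
        tree = fit_weak(X, y, w, max_depth=1)
        expected = stump_oracle(X, y.astype(float), w)
        if expected is None:
            assert isinstance(tree.root_, Leaf)
        else:
            assert (tree.root_.feature, tree.root_.threshold) == (
                expected[0],
                pytest.approx(expected[1]),
            )

    def test_agrees_with_sklearn_tree_on_training_error(self):
        # same criterion family: the chosen stump should achieve the same
        # weighted training error as sklearn's depth-1 Gini tree
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(5)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.random((30, 4))
            y = rng.integers(0, 2, 30)
            if len(np.unique(y)) < 2:
                continue
            w = rng.random(30) + 0.1
            w /= w.sum()
            mine = fit_weak(X, y, w, max_depth=1)
            skl = DecisionTreeClassifier(max_depth=1, random_state=0).fit(
                X, y, sample_weight=w
            )
            e_mine = weighted_error(mine.predict(X), y, w)
            e_skl = weighted_error(skl.predict(X), y, w)
            assert e_mine == pytest.approx(e_skl, abs=1e-12)

    def test_depth_cap_respected(self):
        ts = synthetic_training_set(0)
        tree = fit_weak(ts.features, ts.labels, ts.weights, max_depth=2)

        def depth(node):
            if isinstance(node, Leaf):
                return 0
            return 1 + max(depth(node.left), depth(node.right))

        assert depth(tree.root_) <= 2


class TestBoostingFormulas:
    @pytest.mark.parametrize(
        "eps, expected",
        [
            (0.5, 0.0),
            (1 / (1 + math.e**2), 1.0),
            (0.25, 0.5 * math.log(3)),
        ],
    )
    def test_classifier_weight_closed_forms(self, eps, expected):
        assert classifier_weight(eps) == pytest.approx(expected, abs=1e-12)

    def test_classifier_weight_decreasing_and_domain_checked(self):
        assert classifier_weight(0.1) > classifier_weight(0.2) > 0
        with pytest.raises(ValueError):
            classifier_weight(0.0)

    @pytest.mark.parametrize(
        "eps, expected", [(0.5, 1.0), (0.1, 0.6), (0.25, 2 * math.sqrt(0.1875))]
    )
    def test_normalizer_closed_forms(self, eps, expected):
        assert normalizer(eps) == pytest.approx(expected, abs=1e-12)

    def test_weighted_error_is_mass_of_mistakes(self):
        w = np.full(4, 0.25)
        y = np.array([1, 1, 0, 0])
        assert weighted_error(np.array([1, 1, 0, 0]), y, w) == 0.0
        assert weighted_error(np.array([0, 0, 1, 1]), y, w) == 1.0
        assert weighted_error(np.array([0, 1, 0, 0]), y, w) == pytest.approx(0.25)

    def test_update_with_zero_alpha_is_identity(self):
        w = np.array([0.1, 0.2, 0.3, 0.4])
        out = update_weights(w, 0.0, np.array([1, 0, 1, 0]), np.array([0, 0, 1, 1]))
        np.testing.assert_allclose(out, w)

    def test_worked_four_sample_update(self):
        # one of four misclassified at alpha = ln(3)/2: its weight becomes
        # exactly 1/2, the three correct ones 1/6 each
        w = np.full(4, 0.25)
        y = np.array([1, 1, 0, 0])
        h = np.array([0, 1, 0, 0])
        out = update_weights(w, 0.5 * math.log(3), y, h)
        np.testing.assert_allclose(out, [0.5, 1 / 6, 1 / 6, 1 / 6], atol=1e-15)

    def test_all_correct_update_keeps_distribution(self):
        w = np.array([0.1, 0.2, 0.7])
        y = np.array([1, 0, 1])
        out = update_weights(w, 0.8, y, y)
        np.testing.assert_allclose(out, w)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(n=st.integers(2, 30), seed=st.integers(0, 9999))
    def test_misclassified_mass_becomes_half(self, n, seed):
        rng = np.random.default_rng(seed)
        w = rng.random(n) + 1e-3
        w /= w.sum()
        y = rng.integers(0, 2, n)
        h = rng.integers(0, 2, n)
        wrong = h != y
        eps = w[wrong].sum()
        if not 0 < eps < 0.5:
            return
        out = update_weights(w, classifier_weight(eps), y, h)
        assert out[wrong].sum() == pytest.approx(0.5, abs=1e-9)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert (out > 0).all()


class TestStrongClassifier:
    def test_separable_toy_is_fit_perfectly(self):
        X = np.linspace(0, 1, 12).reshape(-1, 1)
        y = (X[:, 0] > 0.5).astype(np.int8)
        ts = TrainingSet(X, y, np.full(12, 1 / 12))
        sc = train_strong(ts, BoostConfig(rounds=30, max_depth=1))
        assert sc.stop_reason_ == "perfect_fit"
        np.testing.assert_array_equal(sc.predict(X), y)

    def test_single_round_reduces_to_one_weighted_tree(self):
        ts = synthetic_training_set(1)
        sc = train_strong(ts, BoostConfig(rounds=1))
        assert len(sc.estimators_) == 1
        expected = sc.alphas_[0] * sc.estimators_[0].positive_fraction(ts.features)
        np.testing.assert_allclose(sc.decision_function(ts.features), expected)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_training_error_bounded_by_z_product(self, seed):
        ts = synthetic_training_set(seed)
        sc = train_strong(ts, BoostConfig())
        err = (sc.predict(ts.features) != ts.labels).mean()
        assert err <= sc.z_product_ + 1e-12

    def test_trace_invariants(self):
        ts = synthetic_training_set(2)
        sc = train_strong(ts, BoostConfig())
        assert len(sc.trace_) == len(sc.estimators_) == len(sc.alphas_)
        for r in sc.trace_:
            assert 0 < r.epsilon < 0.5
            assert r.alpha > 0
            assert 0 < r.z < 1

    def test_deterministic_given_inputs(self):
        ts = synthetic_training_set(3)
        a = train_strong(ts, BoostConfig())
        b = train_strong(ts, BoostConfig())
        assert a.trace_ == b.trace_
        np.testing.assert_array_equal(
            a.decision_function(ts.features), b.decision_function(ts.features)
        )

    def test_uninformative_data_raises(self):
        # identical feature vectors for both classes: no split beats chance
        X = np.full((10, 3), 0.5)
        y = np.r_[np.ones(5, dtype=np.int8), np.zeros(5, dtype=np.int8)]
        ts = TrainingSet(X, y, np.full(10, 0.1))
        with pytest.raises(RuntimeError, match="no usable signal"):
            train_strong(ts, BoostConfig())

    def test_scores_bounded_by_alpha_sum(self):
        ts = synthetic_training_set(4)
        sc = train_strong(ts, BoostConfig())
        s = sc.decision_function(ts.features)
        assert s.min() >= 0.0
        assert s.max() <= sc.alphas_.sum() + 1e-12

    def test_manual_two_round_score_is_dot_product(self):
        sc = PairBoostClassifier()
        t1, t2 = WeightedDecisionTree(), WeightedDecisionTree()
        t1.root_, t1.n_features_in_ = Leaf(1, 1.0), 2
        t2.root_, t2.n_features_in_ = Leaf(0, 0.4), 2
        sc.estimators_, sc.alphas_ = [t1, t2], np.array([0.5, 1.0])
        sc.trace_, sc.n_features_in_ = [], 2
        assert sc.decision_function(np.zeros((1, 2)))[0] == pytest.approx(0.9)

    def test_feature_width_mismatch_rejected(self):
        ts = synthetic_training_set(5)
        sc = train_strong(ts, BoostConfig())
        with pytest.raises(ValueError, match="width"):
            score_samples(sc, np.zeros((2, ts.features.shape[1] + 1)))

    def test_end_to_end_on_pair_features(self, small_dataset):
        assoc, sdm, _ = small_dataset
        KD = gip_kernel(assoc, "disease")
        KM = gip_kernel(assoc, "microbe")
        SD = integrate_disease_similarity(KD, sdm)
        ts = build_training_set(assoc, SD, KM, SamplingConfig(k=5, seed=0))
        sc = train_strong(ts, BoostConfig())
        err = (sc.predict(ts.features) != ts.labels).mean()
        assert err <= sc.z_product_ + 1e-12
        assert err < 0.5
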