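"""Adaptive boosting of shallow weighted decision trees.

This is the scoring engine: a strong classifier built from T (default 30)
weak classifiers, each a depth-limited CART tree grown on the current
sample weights. Per round i,

    eps_i   = sum of weights of misclassified samples
    alpha_i = (1/2) ln((1 - eps_i) / eps_i)        (vote weight)
    Z_i     = 2 sqrt(eps_i (1 - eps_i))            (weight normalizer)
    D_{i+1}(j) ∝ D_i(j) exp(-alpha_i y*_j h*_j)    (y*, h* in {-1, +1})

Rounds with eps_i >= 1/2 are rejected and training stops; eps_i is clipped
below by a small floor so a perfect weak learner keeps a finite alpha (and
also ends training, since weights then stop changing informatively). The
classic guarantee that the training error of the thresholded ensemble is
at most prod_i Z_i holds and is exercised by the test suite.

A pair's relation score is s(j) = sum_i alpha_i H_i(j), where H_i(j) is by
default the positive-class fraction of the leaf sample j falls into —
a graded score suited to ranking — or the hard leaf label under
``hard_votes``.

The public face is :class:`PairBoostClassifier`, a scikit-learn-style
estimator (``fit``/``predict``/``decision_function``, ``get_params``);
the module-level functions are thin wrappers kept for pipeline use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .sampling import TrainingSet

__all__ = [
    "BoostConfig",
    "DecisionNode",
    "Leaf",
    "WeightedDecisionTree",
    "BoostRound",
    "PairBoostClassifier",
    "fit_weak",
    "weighted_error",
    "classifier_weight",
    "normalizer",
    "update_weights",
    "train_strong",
    "score_samples",
]

_GAIN_TOL = 1e-12


@dataclass(frozen=True)
class BoostConfig:
    """Ensemble size T, weak-learner depth, error floor."""

    rounds: int = 30
    max_depth: int = 3
    epsilon_floor: float = 1e-10
    hard_votes: bool = False
    seed: int = 0  # reserved; training is deterministic given the data

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not 0 < self.epsilon_floor < 0.5:
            raise ValueError("epsilon_floor must lie in (0, 0.5)")


@dataclass
class Leaf:
    label: int
    fraction: float  # weighted positive-class proportion at this leaf


@dataclass
class DecisionNode:
    feature: int
    threshold: float
    left: "DecisionNode | Leaf"
    right: "DecisionNode | Leaf"


@njit(cache=True)
def _split_scan(Xs, wi, wyi, tol):  # pragma: no cover - exercised via fit
    """Scan all (feature, midpoint) candidates for the best weighted-Gini split.

    ``Xs``/``wi``/``wyi`` hold the node's feature values, weights and
    weight*label, each row sorted by that feature. Minimizing the weighted
    Gini impurity of the induced split is equivalent to maximizing
    g = wyl^2/wl + wyr^2/wr; a split must beat the parent's g by tol/2
    (i.e. reduce impurity by more than tol). Returns (feature, position)
    or (-1, -1); ties keep the lowest feature index, then the smallest
    threshold.
    """
    p, m = Xs.shape
    w_tot = 0.0
    wy_tot = 0.0
    for t in range(m):
        w_tot += wi[0, t]
        wy_tot += wyi[0, t]
    best_g = wy_tot * wy_tot / w_tot + 0.5 * tol
    best_f = -1
    best_pos = -1
    for f in range(p):
        wl = 0.0
        wyl = 0.0
        for t in range(m - 1):
            wl += wi[f, t]
            wyl += wyi[f, t]
            if Xs[f, t + 1] > Xs[f, t]:
                wyr = wy_tot - wyl
                g = wyl * wyl / wl + wyr * wyr / (w_tot - wl)
                if g > best_g:
                    best_g = g
                    best_f = f
                    best_pos = t
    return best_f, best_pos


class _NodeData(NamedTuple):
    """Per-node views, each row in that feature's sorted order."""

    idx: np.ndarray  # (p, m) sample indices
    Xs: np.ndarray  # (p, m) feature values
    wi: np.ndarray  # (p, m) sample weights
    wyi: np.ndarray  # (p, m) weight * label


@njit(cache=True)
def _filter_scan(idx, Xs, wi, wyi, keep):  # pragma: no cover - exercised via fit
    """Compact per-feature sorted arrays to the samples flagged by ``keep``."""
    p, m = idx.shape
    cnt = 0
    for t in range(m):
        if keep[idx[0, t]]:
            cnt += 1
    oidx = np.empty((p, cnt), idx.dtype)
    oXs = np.empty((p, cnt), Xs.dtype)
    owi = np.empty((p, cnt), wi.dtype)
    owyi = np.empty((p, cnt), wyi.dtype)
    for f in range(p):
        k = 0
        for t in range(m):
            j = idx[f, t]
            if keep[j]:
                oidx[f, k] = j
                oXs[f, k] = Xs[f, t]
                owi[f, k] = wi[f, t]
                owyi[f, k] = wyi[f, t]
                k += 1
    return oidx, oXs, owi, owyi


def _filter_sorted(nd: _NodeData, keep: np.ndarray) -> _NodeData:
    """Restrict per-feature sorted arrays to a sample subset."""
    return _NodeData(*_filter_scan(nd.idx, nd.Xs, nd.wi, nd.wyi, keep))


def _grow(X: np.ndarray, nd: _NodeData, depth: int) -> DecisionNode | Leaf:
    frac = float(nd.wyi[0].sum() / nd.wi[0].sum())
    if depth == 0 or frac in (0.0, 1.0) or nd.idx.shape[1] < 2:
        return Leaf(label=int(frac >= 0.5), fraction=frac)
    feat, pos = _split_scan(nd.Xs, nd.wi, nd.wyi, _GAIN_TOL)
    if feat < 0:
        return Leaf(label=int(frac >= 0.5), fraction=frac)
    threshold = float((nd.Xs[feat, pos] + nd.Xs[feat, pos + 1]) / 2.0)
    members = nd.idx[0]
    go_left = np.zeros(X.shape[0], dtype=bool)
    go_left[members] = X[members, feat] <= threshold
    in_node = np.zeros(X.shape[0], dtype=bool)
    in_node[members] = True
    left = _grow(X, _filter_sorted(nd, go_left), depth - 1)
    right = _grow(X, _filter_sorted(nd, in_node & ~go_left), depth - 1)
    return DecisionNode(int(feat), threshold, left, right)


def _presort(X: np.ndarray) -> np.ndarray:
    """Per-feature stable sort order of the full training matrix, (p, n)."""
    return np.argsort(X.T, axis=1, kind="stable")


def _root_data(X: np.ndarray, y: np.ndarray, w: np.ndarray, idx: np.ndarray) -> _NodeData:
    return _NodeData(idx, np.take_along_axis(X.T, idx, axis=1), w[idx], (w * y)[idx])


class WeightedDecisionTree(BaseEstimator, ClassifierMixin):
    """Greedy CART on weighted samples, split by weighted Gini impurity.

    Candidate thresholds are midpoints between consecutive distinct sorted
    feature values; growth stops at ``max_depth``, at a pure node, or when
    no split reduces impurity. Each leaf stores the weighted majority label
    and the weighted positive-class fraction of the samples reaching it.
    """

    def __init__(self, max_depth: int = 3):
        self.max_depth = max_depth

    def fit(self, X, y, sample_weight=None, _presorted=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a non-empty 2-D array")
        if not ((y == 0) | (y == 1)).all():
            raise ValueError("labels must be binary 0/1")
        if sample_weight is None:
            sample_weight = np.full(X.shape[0], 1.0 / X.shape[0])
        w = np.asarray(sample_weight, dtype=float)
        if (w <= 0).any():
            raise ValueError("sample weights must be strictly positive")
        idx = _presort(X) if _presorted is None else _presorted
        yf = y.astype(float)
        self.root_ = _grow(X, _root_data(X, yf, w, idx), self.max_depth)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        return self

    def _apply(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        labels = np.empty(X.shape[0], dtype=np.int8)
        fracs = np.empty(X.shape[0], dtype=float)

        def recurse(node, idx):
            if isinstance(node, Leaf):
                labels[idx] = node.label
                fracs[idx] = node.fraction
                return
            go_left = X[idx, node.feature] <= node.threshold
            recurse(node.left, idx[go_left])
            recurse(node.right, idx[~go_left])

        recurse(self.root_, np.arange(X.shape[0]))
        return labels, fracs

    def predict(self, X):
        check_is_fitted(self, "root_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature width mismatch")
        return self._apply(X)[0]

    def predict_proba(self, X):
        check_is_fitted(self, "root_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature width mismatch")
        frac = self._apply(X)[1]
        return np.column_stack([1 - frac, frac])

    def positive_fraction(self, X):
        """Leaf positive-class fraction per sample (the graded vote H_i(j))."""
        return self.predict_proba(X)[:, 1]


class BoostRound(NamedTuple):
    epsilon: float
    alpha: float
    z: float


def weighted_error(predictions, labels, weights) -> float:
    """eps = sum of weights of samples whose prediction differs from the label."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    weights = np.asarray(weights, dtype=float)
    if not predictions.shape == labels.shape == weights.shape:
        raise ValueError("predictions, labels and weights disagree in length")
    return float(weights[predictions != labels].sum())


def classifier_weight(epsilon: float) -> float:
    """alpha = (1/2) ln((1 - eps)/eps); strictly decreasing, 0 at eps = 1/2."""
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    return 0.5 * math.log((1 - epsilon) / epsilon)


def normalizer(epsilon: float) -> float:
    """Z = 2 sqrt(eps (1 - eps)); the analytic weight-distribution normalizer."""
    if not 0 <= epsilon <= 1:
        raise ValueError("epsilon must lie in [0, 1]")
    return 2.0 * math.sqrt(epsilon * (1 - epsilon))


def update_weights(weights, alpha: float, labels, predictions) -> np.ndarray:
    """One AdaBoost reweighting step, explicitly renormalized to sum 1.

    Labels and predictions in {0, 1} are mapped to {-1, +1} inside the
    exponent, so misclassified samples gain weight and correctly classified
    ones lose it.
    """
    weights = np.asarray(weights, dtype=float)
    if (weights <= 0).any():
        raise ValueError("weights must be strictly positive")
    y = 2.0 * np.asarray(labels) - 1.0
    h = 2.0 * np.asarray(predictions) - 1.0
    out = weights * np.exp(-alpha * y * h)
    return out / out.sum()


class PairBoostClassifier(BaseEstimator, ClassifierMixin):
    """AdaBoost ensemble of weighted CART trees for pair scoring.

    Parameters
    ----------
    n_rounds : int, default 30
        Maximum number of weak classifiers T.
    max_depth : int, default 3
        Depth cap of each weak tree.
    epsilon_floor : float, default 1e-10
        Lower clip for a round's weighted error, keeping alpha finite.
    hard_votes : bool, default False
        Score with hard leaf labels instead of leaf positive fractions.

    Attributes
    ----------
    estimators_ : list of WeightedDecisionTree
        Accepted weak classifiers, in training order.
    alphas_ : ndarray
        Vote weight per accepted round, all positive.
    trace_ : list of BoostRound
        Per accepted round: (epsilon, alpha, Z).
    stop_reason_ : str
        "completed", "error_at_chance" (round with eps >= 1/2 rejected) or
        "perfect_fit" (weak learner reached zero error).
    """

    def __init__(
        self,
        n_rounds: int = 30,
        max_depth: int = 3,
        epsilon_floor: float = 1e-10,
        hard_votes: bool = False,
    ):
        self.n_rounds = n_rounds
        self.max_depth = max_depth
        self.epsilon_floor = epsilon_floor
        self.hard_votes = hard_votes

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree in length")
        if not ((y == 0) | (y == 1)).all():
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        n = X.shape[0]
        if sample_weight is None:
            w = np.full(n, 1.0 / n)
        else:
            w = np.asarray(sample_weight, dtype=float)
            w = w / w.sum()

        self.estimators_ = []
        alphas: list[float] = []
        self.trace_ = []
        self.stop_reason_ = "completed"
        yf = y.astype(float)
        presorted = _presort(X)  # X is fixed across rounds; sort once
        for _ in range(self.n_rounds):
            tree = WeightedDecisionTree(max_depth=self.max_depth).fit(
                X, y, sample_weight=w, _presorted=presorted
            )
            h = tree.predict(X)
            eps_raw = weighted_error(h, y, w)
            if eps_raw >= 0.5:
                self.stop_reason_ = "error_at_chance"
                break
            eps = max(eps_raw, self.epsilon_floor)
            alpha = classifier_weight(eps)
            self.estimators_.append(tree)
            alphas.append(alpha)
            self.trace_.append(BoostRound(eps, alpha, normalizer(eps)))
            if eps_raw <= self.epsilon_floor:
                self.stop_reason_ = "perfect_fit"
                break
            w = update_weights(w, alpha, yf, h)
        if not self.estimators_:
            raise RuntimeError(
                "no weak classifier beat chance on the first round; "
                "training data carries no usable signal"
            )
        self.alphas_ = np.asarray(alphas)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X):
        """Relation score s(j) = sum_i alpha_i H_i(j), in [0, sum alpha]."""
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature width mismatch")
        scores = np.zeros(X.shape[0])
        for alpha, tree in zip(self.alphas_, self.estimators_):
            if self.hard_votes:
                scores += alpha * tree.predict(X)
            else:
                scores += alpha * tree.positive_fraction(X)
        return scores

    def predict(self, X):
        """Hard-vote classification: weighted majority of leaf labels."""
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature width mismatch")
        votes = np.zeros(X.shape[0])
        for alpha, tree in zip(self.alphas_, self.estimators_):
            votes += alpha * tree.predict(X)
        return (votes >= 0.5 * self.alphas_.sum()).astype(np.int8)

    @property
    def z_product_(self) -> float:
        """prod_i Z_i, the AdaBoost training-error bound."""
        check_is_fitted(self, "trace_")
        return float(np.prod([r.z for r in self.trace_]))


def fit_weak(features, labels, weights, max_depth: int = 3) -> WeightedDecisionTree:
    """Fit one weighted CART weak classifier."""
    return WeightedDecisionTree(max_depth=max_depth).fit(
        features, labels, sample_weight=weights
    )


def train_strong(ts: TrainingSet, config: BoostConfig) -> PairBoostClassifier:
    """Train the strong classifier on an assembled training set."""
    clf = PairBoostClassifier(
        n_rounds=config.rounds,
        max_depth=config.max_depth,
        epsilon_floor=config.epsilon_floor,
        hard_votes=config.hard_votes,
    )
    return clf.fit(ts.features, ts.labels, sample_weight=ts.weights)


def score_samples(sc: PairBoostClassifier, features) -> np.ndarray:
    """Score samples with a trained strong classifier."""
    return sc.decision_function(features)
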