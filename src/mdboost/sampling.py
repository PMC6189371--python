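"""Training-set assembly: pair features, k-means undersampling, weights.

A disease-microbe pair (i, j) is represented by concatenating row i of the
integrated disease similarity SD with row j of the microbe kernel KM, a
vector of length nd + nm. Known associations are positive samples; all
remaining pairs are unknown. Because unknowns vastly outnumber positives
(~97% of all pairs in curated databases), the unknowns are clustered with
k-means (default k=23) in feature space and negatives are drawn from every
cluster — proportionally to cluster size, by largest-remainder rounding —
until the negative count reaches ``round(ratio * n_positives)`` (ratio
defaults to 1, a balanced set). Every training sample starts with weight
1/n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .data import AssociationMatrix, SimilarityMatrix

__all__ = [
    "SamplePair",
    "SamplingConfig",
    "TrainingSet",
    "build_features",
    "cluster_unknowns",
    "proportional_quotas",
    "sample_negatives",
    "assemble_training_set",
    "build_training_set",
]


class SamplePair(NamedTuple):
    disease_index: int
    microbe_index: int


@dataclass(frozen=True)
class SamplingConfig:
    """Undersampling parameters: cluster count k, negative ratio, seed."""

    k: int = 23
    negative_to_positive_ratio: float = 1.0
    seed: int = 0
    equal_per_cluster: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.negative_to_positive_ratio <= 0:
            raise ValueError("negative-to-positive ratio must be > 0")


@dataclass
class TrainingSet:
    """Features, binary labels and per-sample weights (initially 1/n)."""

    features: np.ndarray
    labels: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.features.shape[0]
        if self.labels.shape != (n,) or self.weights.shape != (n,):
            raise ValueError("features, labels and weights disagree in length")
        if not ((self.labels == 0) | (self.labels == 1)).all():
            raise ValueError("labels must be binary")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("training set must contain both classes")
        if (self.weights <= 0).any():
            raise ValueError("weights must be strictly positive")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    @property
    def n(self) -> int:
        return self.features.shape[0]


def build_features(
    SD: SimilarityMatrix,
    KM: SimilarityMatrix,
    pairs: Sequence[SamplePair] | np.ndarray,
) -> np.ndarray:
    """Feature matrix with one row [SD row i | KM row j] per pair (i, j)."""
    pairs = np.asarray(pairs, dtype=int)
    if pairs.size == 0:
        return np.empty((0, SD.n + KM.n))
    d_idx, m_idx = pairs[:, 0], pairs[:, 1]
    if d_idx.min() < 0 or d_idx.max() >= SD.n:
        raise IndexError("disease index out of bounds")
    if m_idx.min() < 0 or m_idx.max() >= KM.n:
        raise IndexError("microbe index out of bounds")
    return np.hstack([SD.values[d_idx], KM.values[m_idx]])


def cluster_unknowns(features: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Seeded k-means (k-means++ init, Lloyd iterations) over unknown pairs."""
    features = np.asarray(features, dtype=float)
    if features.shape[0] < k:
        raise ValueError(
            f"only {features.shape[0]} unknown samples but k={k}; choose a smaller k"
        )
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=1,
        max_iter=300,
        tol=1e-4,
        random_state=seed,
    )
    return km.fit_predict(features)


def proportional_quotas(sizes: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` across cluster sizes.

    Quotas are proportional to size, floored, then the leftover units go to
    the clusters with the largest fractional remainders (ties to the lower
    cluster id). Quotas sum exactly to ``total`` and never exceed sizes
    when ``total <= sizes.sum()``.
    """
    sizes = np.asarray(sizes, dtype=np.int64)
    if total < 0 or total > sizes.sum():
        raise ValueError("total must lie in [0, sum(sizes)]")
    exact = total * sizes / sizes.sum()
    base = np.floor(exact).astype(np.int64)
    remainder = exact - base
    short = total - int(base.sum())
    # stable sort on -remainder keeps lower cluster ids first among ties
    order = np.argsort(-remainder, kind="stable")
    base[order[:short]] += 1
    return base


def sample_negatives(
    assignment: np.ndarray, n_negatives: int, seed: int, *, equal_per_cluster: bool = False
) -> np.ndarray:
    """Draw negative indices from every cluster, without replacement.

    Returns positions into the unknown-sample array the assignment was
    computed on. Per-cluster quotas are proportional to cluster size by
    default; ``equal_per_cluster`` splits the budget evenly instead (any
    shortfall redistributed by largest remainder over leftover capacity).
    """
    assignment = np.asarray(assignment)
    if assignment.size == 0:
        raise ValueError("empty cluster assignment")
    if n_negatives < 1 or n_negatives > assignment.size:
        raise ValueError("n_negatives must lie in [1, number of unknowns]")
    cluster_ids = np.unique(assignment)
    sizes = np.array([(assignment == c).sum() for c in cluster_ids])
    if equal_per_cluster:
        quotas = np.minimum(sizes, n_negatives // len(cluster_ids))
        short = n_negatives - int(quotas.sum())
        if short:
            quotas += proportional_quotas(sizes - quotas, short)
    else:
        quotas = proportional_quotas(sizes, n_negatives)
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for c, q in zip(cluster_ids, quotas):
        members = np.flatnonzero(assignment == c)
        if q:
            chosen.append(rng.choice(members, size=int(q), replace=False))
    out = np.sort(np.concatenate(chosen))
    return out


def assemble_training_set(
    positives: Sequence[SamplePair] | np.ndarray,
    negatives: Sequence[SamplePair] | np.ndarray,
    SD: SimilarityMatrix,
    KM: SimilarityMatrix,
) -> TrainingSet:
    """Stack positive and negative pairs into a uniformly weighted set."""
    positives = np.asarray(positives, dtype=int)
    negatives = np.asarray(negatives, dtype=int)
    if positives.size == 0 or negatives.size == 0:
        raise ValueError("both classes must be non-empty")
    X = np.vstack(
        [build_features(SD, KM, positives), build_features(SD, KM, negatives)]
    )
    y = np.concatenate(
        [np.ones(len(positives), dtype=np.int8), np.zeros(len(negatives), dtype=np.int8)]
    )
    n = len(y)
    return TrainingSet(X, y, np.full(n, 1.0 / n))


def build_training_set(
    assoc: AssociationMatrix,
    SD: SimilarityMatrix,
    KM: SimilarityMatrix,
    config: SamplingConfig,
    *,
    positives: np.ndarray | None = None,
    unknowns: np.ndarray | None = None,
) -> TrainingSet:
    """Full sampling pipeline: cluster unknowns, draw negatives, weight.

    ``positives``/``unknowns`` override the pair pools derived from the
    adjacency matrix (used by cross-validation to hold a pair out or to
    exclude a query disease from the negative pool). Deterministic in
    (inputs, seed).
    """
    if positives is None:
        positives = assoc.positive_pairs()
    if unknowns is None:
        unknowns = assoc.unknown_pairs()
    n_neg = int(round(config.negative_to_positive_ratio * len(positives)))
    n_neg = max(1, min(n_neg, len(unknowns)))
    unknown_features = build_features(SD, KM, unknowns)
    assignment = cluster_unknowns(unknown_features, config.k, config.seed)
    picked = sample_negatives(
        assignment, n_neg, config.seed, equal_per_cluster=config.equal_per_cluster
    )
    return assemble_training_set(positives, unknowns[picked], SD, KM)
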