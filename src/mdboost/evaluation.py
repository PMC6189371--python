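"""Leave-one-out cross validation, ranking and new-disease prediction.

Global LOOCV holds each known disease-microbe pair out in turn, retrains
the whole pipeline on the remaining associations, and ranks the held-out
pair against every unknown pair; local LOOCV ranks it only against the
unknown pairs of the same disease. The held-out ranks across folds define
a single TPR/FPR sweep over rank thresholds, whose trapezoidal area is the
reported AUC — per-fold score scales differ, so raw scores are never
pooled.

By default the interaction-profile kernels are recomputed from the masked
adjacency matrix inside every fold; leaving the held-out 1 inside them
would leak the answer. ``recompute_kernels=False`` preserves the leaky
reading for speed comparisons only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boosting import BoostConfig, train_strong
from .data import AssociationMatrix, PredictionTable, SimilarityMatrix
from .sampling import SamplingConfig, build_features, build_training_set
from .similarity import (
    KernelConfig,
    align_similarity,
    gip_kernel,
    integrate_disease_similarity,
)

__all__ = [
    "EvalConfig",
    "LoocvResult",
    "derive_seed",
    "roc_auc",
    "rank_curve",
    "loocv",
    "loocv_both",
    "rank_all_unknown_pairs",
    "predict_new_disease",
    "per_disease_ranking",
]


def derive_seed(seed: int, *keys: int) -> int:
    """Deterministic sub-seed from a run seed and integer keys (< 2^31)."""
    ss = np.random.SeedSequence([int(seed), *map(int, keys)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation mode and the embedded pipeline configurations."""

    mode: str = "global"
    recompute_kernels: bool = True
    seed: int = 0
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    boost: BoostConfig = field(default_factory=BoostConfig)
    kernel: KernelConfig = field(default_factory=KernelConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("global", "local"):
            raise ValueError("mode must be 'global' or 'local'")


@dataclass
class LoocvResult:
    """AUC, per-fold held-out ranks and the rank-sweep ROC curve."""

    auc: float
    per_fold_rank: list[tuple[tuple[str, str], int, int]]
    roc_points: np.ndarray


def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """AUC by the rank-sum (Mann-Whitney) formula with mid-ranks for ties.

    Returns (auc, roc_points); ROC points come from sweeping all distinct
    score thresholds, with (0,0) and (1,1) endpoints, as (FPR, TPR).
    """
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)  # mid-ranks for ties
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    s = scores[order]
    tp = np.cumsum(y == 1)
    fp = np.cumsum(y == 0)
    # keep one operating point per distinct threshold value
    last = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tp[last] / n_pos]
    fpr = np.r_[0.0, fp[last] / n_neg]
    return float(auc), np.column_stack([fpr, tpr])


def rank_curve(ranks, sizes) -> tuple[float, np.ndarray]:
    """AUC from per-fold held-out ranks via a rank-threshold sweep.

    ``ranks[f]`` is the held-out pair's rank among its fold's comparison
    set (1 = top), ``sizes[f]`` that set's size. Calling the top-t
    predictions positive at threshold t gives TPR(t) = fraction of folds
    with rank <= t and FPR(t) = mean fraction of comparison pairs inside
    the top t; the curve's trapezoidal area is the AUC.
    """
    ranks = np.asarray(ranks, dtype=np.int64)
    sizes = np.asarray(sizes, dtype=np.int64)
    if ranks.size == 0:
        raise ValueError("no folds")
    t = np.arange(0, sizes.max() + 2)[:, None]  # thresholds x folds
    hit = ranks[None, :] <= t
    tpr = hit.mean(axis=1)
    neg_in_top = np.minimum(t - hit, sizes[None, :])
    fpr = (neg_in_top / sizes[None, :]).mean(axis=1)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


def _pipeline_scores(
    assoc: AssociationMatrix,
    SDM_aligned: SimilarityMatrix,
    config: EvalConfig,
    query_pairs: np.ndarray,
    *,
    positives: np.ndarray | None = None,
    negative_pool: np.ndarray | None = None,
    seed: int | None = None,
):
    """Kernels -> training set -> strong classifier -> scores for queries."""
    KD = gip_kernel(assoc, "disease", config.kernel)
    KM = gip_kernel(assoc, "microbe", config.kernel)
    SD = integrate_disease_similarity(KD, SDM_aligned)
    sampling = config.sampling
    if seed is not None:
        sampling = SamplingConfig(
            k=sampling.k,
            negative_to_positive_ratio=sampling.negative_to_positive_ratio,
            seed=seed,
            equal_per_cluster=sampling.equal_per_cluster,
        )
    ts = build_training_set(
        assoc, SD, KM, sampling, positives=positives, unknowns=negative_pool
    )
    clf = train_strong(ts, config.boost)
    return clf, clf.decision_function(build_features(SD, KM, query_pairs))


def _prepare_sdm(assoc: AssociationMatrix, SDM: SimilarityMatrix) -> SimilarityMatrix:
    if SDM.labels == assoc.diseases:
        return SDM
    return align_similarity(SDM, assoc.diseases)


def loocv_both(
    assoc: AssociationMatrix, SDM: SimilarityMatrix, config: EvalConfig
) -> dict[str, LoocvResult]:
    """Run LOOCV once, reporting both global and local results.

    One fold per known pair: the pair's entry is masked, kernels are
    rebuilt from the masked matrix (unless disabled), the training set is
    re-drawn with a fold-specific seed derived from (run seed, fold index),
    and the held-out pair is ranked among the unknown pairs (global) and
    among the unknown pairs of its disease (local).
    """
    SDM_aligned = _prepare_sdm(assoc, SDM)
    positives = assoc.positive_pairs()
    if len(positives) < 2:
        raise ValueError("LOOCV needs at least two known associations")
    unknowns = assoc.unknown_pairs()
    unknown_disease = unknowns[:, 0]

    global_ranks: list[int] = []
    local_ranks: list[int] = []
    local_sizes: list[int] = []
    fold_pairs: list[tuple[str, str]] = []

    for fold, (i, j) in enumerate(positives):
        masked = assoc.copy()
        masked.A[i, j] = 0
        # leaky mode keeps kernels from the unmasked matrix (speed studies only)
        kernel_source = masked if config.recompute_kernels else assoc
        train_positives = np.delete(positives, fold, axis=0)
        fold_seed = derive_seed(config.seed, fold)
        query = np.vstack([[i, j], unknowns])
        _, scores = _pipeline_scores(
            kernel_source,
            SDM_aligned,
            config,
            query,
            positives=train_positives,
            negative_pool=unknowns,
            seed=fold_seed,
        )
        s_test, s_cand = scores[0], scores[1:]
        global_ranks.append(1 + int((s_cand > s_test).sum()))
        local_mask = unknown_disease == i
        local_ranks.append(1 + int((s_cand[local_mask] > s_test).sum()))
        local_sizes.append(int(local_mask.sum()))
        fold_pairs.append((assoc.diseases[i], assoc.microbes[j]))

    n_unknown = len(unknowns)
    g_auc, g_roc = rank_curve(global_ranks, np.full(len(global_ranks), n_unknown))
    l_auc, l_roc = rank_curve(local_ranks, local_sizes)
    return {
        "global": LoocvResult(
            g_auc,
            list(zip(fold_pairs, global_ranks, [n_unknown] * len(global_ranks))),
            g_roc,
        ),
        "local": LoocvResult(
            l_auc, list(zip(fold_pairs, local_ranks, local_sizes)), l_roc
        ),
    }


def loocv(
    assoc: AssociationMatrix, SDM: SimilarityMatrix, config: EvalConfig
) -> LoocvResult:
    """Leave-one-out cross validation in the configured mode."""
    return loocv_both(assoc, SDM, config)[config.mode]


def rank_all_unknown_pairs(
    assoc: AssociationMatrix, SDM: SimilarityMatrix, config: EvalConfig
) -> PredictionTable:
    """Train once on the full matrix and rank every unknown pair globally."""
    SDM_aligned = _prepare_sdm(assoc, SDM)
    unknowns = assoc.unknown_pairs()
    if len(unknowns) == 0:
        raise ValueError("no unknown pairs to rank")
    _, scores = _pipeline_scores(
        assoc, SDM_aligned, config, unknowns, seed=derive_seed(config.seed)
    )
    labels = (
        (assoc.diseases[i], assoc.microbes[j]) for i, j in unknowns
    )
    return PredictionTable.from_scores(labels, scores)


def per_disease_ranking(table: PredictionTable) -> dict[str, PredictionTable]:
    """Regroup a global prediction table into per-disease rankings."""
    by_disease: dict[str, list] = {}
    for rec in table.records:
        by_disease.setdefault(rec.disease, []).append(rec)
    return {
        d: PredictionTable.from_scores(
            [(r.disease, r.microbe) for r in recs], [r.score for r in recs]
        )
        for d, recs in by_disease.items()
    }


def predict_new_disease(
    assoc: AssociationMatrix,
    SDM: SimilarityMatrix,
    disease_label: str,
    config: EvalConfig,
) -> PredictionTable:
    """Rank all microbes for a disease treated as having no known microbes.

    The disease's entire adjacency row is zeroed before training, so its
    interaction profile is empty and its integrated similarity row is
    driven purely by the symptom-based matrix — the regime of a genuinely
    new disease. Its pairs are excluded from the negative-sampling pool.
    """
    i = assoc.disease_index(disease_label)
    masked = assoc.copy()
    masked.A[i, :] = 0
    if masked.A.sum() == 0:
        raise ValueError("no associations left after masking the query disease")
    SDM_aligned = _prepare_sdm(assoc, SDM)
    query = np.array([[i, j] for j in range(assoc.n_microbes)])
    pool = masked.unknown_pairs()
    pool = pool[pool[:, 0] != i]
    _, scores = _pipeline_scores(
        masked,
        SDM_aligned,
        config,
        query,
        negative_pool=pool,
        seed=derive_seed(config.seed, i),
    )
    labels = ((assoc.diseases[i], assoc.microbes[j]) for j in range(assoc.n_microbes))
    return PredictionTable.from_scores(labels, scores)
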