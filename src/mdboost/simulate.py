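"""Seeded synthetic data with planted block structure.

Emulates the shape of a curated microbe-disease association list plus a
symptom-based disease similarity matrix: diseases and microbes are
partitioned round-robin into co-association blocks; a pair inside a shared
block is associated with probability ``density_in``, any other pair with
``density_out``. The paired symptom matrix is block-consistent (0.8 within
a disease block, 0.1 across) with additive uniform noise, so it carries
signal about the planted structure independently of the adjacency matrix —
the property that makes new-disease prediction possible.

Defaults (20 diseases x 60 microbes, 4 blocks, density 0.5/0.02) yield
roughly 170 known associations. Sparser settings leave most microbes with
a single association, and leave-one-out evaluation of such a pair is a
pure microbe cold start that no learner can rank from these features; the
default density keeps the typical microbe's profile informative after one
association is masked, while the matrix stays >85% unknown pairs and full
leave-one-out runs stay in the minutes range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import AssociationMatrix, SimilarityMatrix

__all__ = [
    "SimulationConfig",
    "block_assignment",
    "generate_association_matrix",
    "generate_symptom_similarity",
    "generate_dataset",
    "permute_associations",
]

_BASE_IN = 0.8  # symptom similarity within a disease block
_BASE_OUT = 0.1  # symptom similarity across blocks


@dataclass(frozen=True)
class SimulationConfig:
    n_diseases: int = 20
    n_microbes: int = 60
    n_blocks: int = 4
    density_in: float = 0.5
    density_out: float = 0.02
    symptom_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diseases < 1 or self.n_microbes < 1:
            raise ValueError("matrix dimensions must be positive")
        if self.n_blocks < 1 or self.n_blocks > min(self.n_diseases, self.n_microbes):
            raise ValueError("n_blocks must lie in [1, min(nd, nm)]")
        if not 0 <= self.density_out < self.density_in <= 1:
            raise ValueError("need 0 <= density_out < density_in <= 1")
        if self.symptom_noise < 0:
            raise ValueError("symptom_noise must be >= 0")


def block_assignment(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Round-robin block ids for diseases and microbes."""
    d_blocks = np.arange(config.n_diseases) % config.n_blocks
    m_blocks = np.arange(config.n_microbes) % config.n_blocks
    return d_blocks, m_blocks


def generate_association_matrix(config: SimulationConfig) -> AssociationMatrix:
    """Draw a planted-block bipartite adjacency matrix.

    Any all-zero row or column receives one forced in-block association so
    every interaction profile is non-degenerate.
    """
    rng = np.random.default_rng(config.seed)
    d_blocks, m_blocks = block_assignment(config)
    same_block = d_blocks[:, None] == m_blocks[None, :]
    prob = np.where(same_block, config.density_in, config.density_out)
    A = (rng.random(prob.shape) < prob).astype(np.int8)
    for i in np.flatnonzero(A.sum(axis=1) == 0):
        A[i, rng.choice(np.flatnonzero(same_block[i]))] = 1
    for j in np.flatnonzero(A.sum(axis=0) == 0):
        A[rng.choice(np.flatnonzero(same_block[:, j])), j] = 1
    diseases = [f"D{i:03d}" for i in range(config.n_diseases)]
    microbes = [f"M{j:03d}" for j in range(config.n_microbes)]
    return AssociationMatrix(A, diseases, microbes)


def generate_symptom_similarity(
    config: SimulationConfig, d_blocks: np.ndarray | None = None
) -> SimilarityMatrix:
    """Noisy block-consistent disease-disease similarity, unit diagonal."""
    if d_blocks is None:
        d_blocks = block_assignment(config)[0]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    base = np.where(d_blocks[:, None] == d_blocks[None, :], _BASE_IN, _BASE_OUT)
    if config.symptom_noise > 0:
        noise = rng.uniform(
            -config.symptom_noise, config.symptom_noise, size=base.shape
        )
        base = base + (noise + noise.T) / 2.0
    base = np.clip(base, 0.0, 1.0)
    base = (base + base.T) / 2.0
    np.fill_diagonal(base, 1.0)
    labels = [f"D{i:03d}" for i in range(config.n_diseases)]
    return SimilarityMatrix(base, labels, kind="SDM")


def generate_dataset(
    config: SimulationConfig,
) -> tuple[AssociationMatrix, SimilarityMatrix, tuple[np.ndarray, np.ndarray]]:
    """Association matrix, symptom similarity and the true block assignment."""
    assoc = generate_association_matrix(config)
    d_blocks, m_blocks = block_assignment(config)
    sdm = generate_symptom_similarity(config, d_blocks)
    return assoc, sdm, (d_blocks, m_blocks)


def random_pair_matrix(
    n_diseases: int, n_microbes: int, n_pairs: int, seed: int
) -> AssociationMatrix:
    """Random adjacency with an exact pair count and full entity coverage.

    Emulates a curated database export at a prescribed scale: exactly
    ``n_pairs`` distinct associations, with every disease and every microbe
    appearing at least once (so the catalogs have the nominal sizes).
    Synthetic stand-in for a real curated pair list.
    """
    if n_pairs < max(n_diseases, n_microbes):
        raise ValueError("need at least max(nd, nm) pairs to cover all entities")
    if n_pairs > n_diseases * n_microbes:
        raise ValueError("more pairs than matrix cells")
    rng = np.random.default_rng(seed)
    A = np.zeros((n_diseases, n_microbes), dtype=np.int8)
    # cover every microbe once, spreading diseases round-robin then randomly
    for j in range(n_microbes):
        i = j % n_diseases if j < n_diseases else rng.integers(n_diseases)
        A[i, j] = 1
    while A.sum() < n_pairs:
        missing = n_pairs - int(A.sum())
        zeros = np.flatnonzero(A == 0)
        pick = rng.choice(zeros, size=min(missing, len(zeros)), replace=False)
        A.flat[pick] = 1
    diseases = [f"disease {i:02d}" for i in range(n_diseases)]
    microbes = [f"microbe {j:03d}" for j in range(n_microbes)]
    return AssociationMatrix(A, diseases, microbes)


def permute_associations(assoc: AssociationMatrix, seed: int) -> AssociationMatrix:
    """Null control: re-place the same number of 1s uniformly at random.

    Destroys the planted block correspondence while preserving the overall
    association density; empty rows/columns get one forced 1 so the
    kernels stay defined.
    """
    rng = np.random.default_rng(seed)
    nd, nm = assoc.A.shape
    n_ones = int(assoc.A.sum())
    flat = rng.choice(nd * nm, size=n_ones, replace=False)
    A = np.zeros(nd * nm, dtype=np.int8)
    A[flat] = 1
    A = A.reshape(nd, nm)
    for i in np.flatnonzero(A.sum(axis=1) == 0):
        A[i, rng.integers(nm)] = 1
    for j in np.flatnonzero(A.sum(axis=0) == 0):
        A[rng.integers(nd), j] = 1
    return AssociationMatrix(A, list(assoc.diseases), list(assoc.microbes))
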