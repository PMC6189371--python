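"""Gaussian interaction-profile (GIP) kernel similarity and fusion.

Each disease's interaction profile IP(d(i)) is row i of the binary
adjacency matrix A (each microbe's profile is a column). The GIP kernel
similarity between two entities is

    K(i, j) = exp(-gamma * ||IP(i) - IP(j)||^2)

with bandwidth gamma = gamma' / mean_i ||IP(i)||^2, i.e. the nominal
bandwidth gamma' (default 1) normalized by the average number of known
associations per entity. For binary profiles the squared Euclidean
distance equals the Hamming distance, so squared norms are exact integer
popcounts — no float accumulation enters before the final division.

The disease kernel KD is fused with an externally supplied symptom-based
disease similarity SDM by the elementwise mean SD = (KD + SDM) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import AssociationMatrix, SimilarityMatrix

__all__ = [
    "KernelConfig",
    "gip_bandwidth",
    "gip_kernel",
    "integrate_disease_similarity",
    "align_similarity",
]


@dataclass(frozen=True)
class KernelConfig:
    """Nominal bandwidths gamma' for the disease and microbe kernels."""

    gamma_prime_disease: float = 1.0
    gamma_prime_microbe: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma_prime_disease <= 0 or self.gamma_prime_microbe <= 0:
            raise ValueError("gamma' must be strictly positive")


def gip_bandwidth(profiles: np.ndarray, gamma_prime: float = 1.0) -> float:
    """Bandwidth gamma = gamma' / mean squared profile norm.

    ``profiles`` holds one binary interaction profile per row; the squared
    norm of a binary row is its popcount.
    """
    profiles = np.asarray(profiles)
    if gamma_prime <= 0:
        raise ValueError("gamma' must be strictly positive")
    norms = profiles.astype(np.int64).sum(axis=1)
    total = int(norms.sum())
    if total == 0:
        raise ValueError("empty interaction profiles")
    return gamma_prime * profiles.shape[0] / total


def gip_kernel(
    assoc: AssociationMatrix,
    axis: str,
    config: KernelConfig | None = None,
) -> SimilarityMatrix:
    """GIP kernel similarity over diseases (rows of A) or microbes (columns)."""
    config = config or KernelConfig()
    if axis == "disease":
        profiles = assoc.A
        labels = assoc.diseases
        gamma_prime = config.gamma_prime_disease
        kind = "KD"
    elif axis == "microbe":
        profiles = assoc.A.T
        labels = assoc.microbes
        gamma_prime = config.gamma_prime_microbe
        kind = "KM"
    else:
        raise ValueError("axis must be 'disease' or 'microbe'")
    gamma = gip_bandwidth(profiles, gamma_prime)
    p = profiles.astype(np.int64)
    norms = p.sum(axis=1)
    # Hamming distance between binary rows: n_i + n_j - 2 <x_i, x_j>
    dist = norms[:, None] + norms[None, :] - 2 * (p @ p.T)
    K = np.exp(-gamma * dist.astype(float))
    np.fill_diagonal(K, 1.0)
    K = (K + K.T) / 2.0
    return SimilarityMatrix(K, list(labels), kind=kind)


def integrate_disease_similarity(
    KD: SimilarityMatrix, SDM: SimilarityMatrix
) -> SimilarityMatrix:
    """Elementwise mean of kernel and symptom disease similarity.

    Labels must match in the same order; use :func:`align_similarity` first
    if the symptom matrix covers a different disease set.
    """
    if KD.labels != SDM.labels:
        raise ValueError("disease label mismatch between KD and SDM")
    return SimilarityMatrix((KD.values + SDM.values) / 2.0, list(KD.labels), kind="SD")


def align_similarity(
    SDM: SimilarityMatrix,
    target_labels: list[str],
    fill_value: float = 0.0,
) -> SimilarityMatrix:
    """Reorder a similarity matrix onto ``target_labels``.

    Diseases absent from ``SDM`` get off-diagonal ``fill_value`` (default 0,
    i.e. maximally uninformative) and a unit diagonal.
    """
    if not 0.0 <= fill_value <= 1.0:
        raise ValueError("fill_value must lie in [0, 1]")
    n = len(target_labels)
    out = np.full((n, n), fill_value, dtype=float)
    index = {lab: i for i, lab in enumerate(SDM.labels)}
    present = [(k, index[lab]) for k, lab in enumerate(target_labels) if lab in index]
    if present:
        rows = np.array([k for k, _ in present])
        src = np.array([i for _, i in present])
        out[np.ix_(rows, rows)] = SDM.values[np.ix_(src, src)]
    np.fill_diagonal(out, 1.0)
    return SimilarityMatrix(out, list(target_labels), kind=SDM.kind or "SDM")
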