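"""Data containers and TSV input/output.

The pipeline is driven by three plain-text artifacts:

* an association pair list (``disease<TAB>microbe[<TAB>evidence]``), in the
  style of curated microbe-disease databases such as HMDAD;
* a square symptom-based disease-disease similarity matrix with labels in
  the first row and column, in the style of the symptom disease network;
* a ranked prediction table (``disease/microbe/score/rank``).

Labels are normalized by trimming and collapsing internal whitespace runs;
matching is case-sensitive, since curated names distinguish taxa by case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "PredictionRecord",
    "PredictionTable",
    "normalize_label",
    "read_association_pairs",
    "read_similarity_matrix",
    "write_association_pairs",
    "write_similarity_matrix",
    "write_predictions",
    "read_predictions",
]

_SCORE_FMT = "%.6f"  # fixed 6-decimal serialization for bit-stable diffs


def normalize_label(label: str) -> str:
    """Trim and collapse internal whitespace runs; case is preserved."""
    return " ".join(str(label).split())


def _check_unique(labels: Sequence[str], kind: str) -> None:
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate {kind} labels")


@dataclass
class AssociationMatrix:
    """Binary disease-by-microbe adjacency matrix with entity catalogs.

    ``A[i, j] == 1`` iff disease ``diseases[i]`` has a recorded association
    with microbe ``microbes[j]``.
    """

    A: np.ndarray
    diseases: list[str]
    microbes: list[str]

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        if self.A.ndim != 2:
            raise ValueError("A must be a 2-D matrix")
        if self.A.shape != (len(self.diseases), len(self.microbes)):
            raise ValueError("A shape does not match entity catalogs")
        if self.A.size == 0:
            raise ValueError("A must have at least one disease and microbe")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("A entries must be 0 or 1")
        self.A = self.A.astype(np.int8)
        _check_unique(self.diseases, "disease")
        _check_unique(self.microbes, "microbe")
        for lab in (*self.diseases, *self.microbes):
            if not normalize_label(lab):
                raise ValueError("empty entity label")

    @property
    def n_diseases(self) -> int:
        return self.A.shape[0]

    @property
    def n_microbes(self) -> int:
        return self.A.shape[1]

    def positive_pairs(self) -> np.ndarray:
        """Index pairs (i, j) of known associations, row-major order."""
        return np.argwhere(self.A == 1)

    def unknown_pairs(self) -> np.ndarray:
        """Index pairs (i, j) of unknown (zero) entries, row-major order."""
        return np.argwhere(self.A == 0)

    def disease_index(self, label: str) -> int:
        try:
            return self.diseases.index(normalize_label(label))
        except ValueError:
            raise KeyError(f"unknown disease label: {label!r}") from None

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            self.A.copy(), list(self.diseases), list(self.microbes)
        )


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over named entities.

    Entries lie in [0, 1], the diagonal is 1 and symmetry holds to 1e-12.
    ``kind`` tags the semantic flavor: "KD"/"KM" (interaction-profile
    kernels), "SDM" (symptom similarity) or "SD" (integrated).
    """

    values: np.ndarray
    labels: list[str]
    kind: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square over labels")
        if n == 0:
            raise ValueError("similarity matrix must be non-empty")
        _check_unique(self.labels, "similarity")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0.0):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12, rtol=0.0):
            raise ValueError("similarity diagonal must be 1")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.labels)


class PredictionRecord(NamedTuple):
    disease: str
    microbe: str
    score: float
    rank: int


@dataclass
class PredictionTable:
    """Ranked disease-microbe predictions, ranks 1..N without gaps."""

    records: list[PredictionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ranks = [r.rank for r in self.records]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError("ranks must be 1..N without gaps, in order")
        scores = [r.score for r in self.records]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("scores must be non-increasing with rank")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_scores(
        cls,
        pairs: Iterable[tuple[str, str]],
        scores: Iterable[float],
    ) -> "PredictionTable":
        """Rank pairs by score; ties broken by (disease, microbe) labels."""
        rows = [(d, m, float(s)) for (d, m), s in zip(pairs, scores)]
        rows.sort(key=lambda r: (-r[2], r[0], r[1]))
        return cls(
            [PredictionRecord(d, m, s, k + 1) for k, (d, m, s) in enumerate(rows)]
        )


def read_association_pairs(
    path: str | Path,
    *,
    header_token: str = "disease",
    sort_labels: bool = False,
) -> AssociationMatrix:
    """Read a TSV pair list into a binary adjacency matrix.

    Each line carries at least two tab-separated fields (disease, microbe);
    extra fields (e.g. evidence) are ignored. Duplicate pairs collapse to a
    single 1. A leading header line is skipped when its first field equals
    ``header_token`` (case-insensitive). Entity order is first appearance
    unless ``sort_labels`` requests lexicographic order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"association file not found: {path}")
    diseases: dict[str, int] = {}
    microbes: dict[str, int] = {}
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and normalize_label(fields[0]).lower() == header_token.lower():
                continue
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected >=2 tab-separated fields"
                )
            d, m = normalize_label(fields[0]), normalize_label(fields[1])
            if not d or not m:
                raise ValueError(f"{path}:{lineno}: empty disease or microbe label")
            diseases.setdefault(d, len(diseases))
            microbes.setdefault(m, len(microbes))
            pairs.add((d, m))
    if not pairs:
        raise ValueError(f"{path}: no valid association records")
    d_labels = sorted(diseases) if sort_labels else list(diseases)
    m_labels = sorted(microbes) if sort_labels else list(microbes)
    d_idx = {lab: i for i, lab in enumerate(d_labels)}
    m_idx = {lab: j for j, lab in enumerate(m_labels)}
    A = np.zeros((len(d_labels), len(m_labels)), dtype=np.int8)
    for d, m in pairs:
        A[d_idx[d], m_idx[m]] = 1
    return AssociationMatrix(A, d_labels, m_labels)


def write_association_pairs(assoc: AssociationMatrix, path: str | Path) -> None:
    """Write the known pairs as a headered TSV (disease, microbe)."""
    with open(path, "w") as fh:
        fh.write("disease\tmicrobe\n")
        for i, j in assoc.positive_pairs():
            fh.write(f"{assoc.diseases[i]}\t{assoc.microbes[j]}\n")


def read_similarity_matrix(path: str | Path, *, kind: str = "SDM") -> SimilarityMatrix:
    """Read a labeled square TSV similarity matrix.

    The matrix is symmetrized as (M + M^T)/2, the diagonal is forced to 1
    and values are clipped to [0, 1] (with a warning when clipping occurs).
    Row and column label sets must coincide; columns are reindexed to the
    row order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"similarity file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [normalize_label(x) for x in df.index]
    df.columns = [normalize_label(x) for x in df.columns]
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: similarity matrix is not square")
    if set(df.index) != set(df.columns):
        raise ValueError(f"{path}: row and column label sets differ")
    df = df.loc[:, list(df.index)]
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric similarity cell: {exc}") from None
    if np.isnan(values).any():
        raise ValueError(f"{path}: missing similarity cell")
    values = (values + values.T) / 2.0
    if values.min() < 0 or values.max() > 1:
        warnings.warn(f"{path}: similarity values clipped to [0, 1]", stacklevel=2)
        values = np.clip(values, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, list(df.index), kind=kind)


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(sim.values, index=sim.labels, columns=sim.labels)
    df.to_csv(path, sep="\t", float_format=_SCORE_FMT)


def write_predictions(table: PredictionTable, path: str | Path) -> None:
    """Write a prediction table as rank-ordered TSV, scores to 6 decimals."""
    with open(path, "w") as fh:
        fh.write("disease\tmicrobe\tscore\trank\n")
        for rec in table.records:
            fh.write(f"{rec.disease}\t{rec.microbe}\t{rec.score:.6f}\t{rec.rank}\n")


def read_predictions(path: str | Path) -> PredictionTable:
    records: list[PredictionRecord] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("disease\tmicrobe\tscore\trank"):
            raise ValueError(f"{path}: not a prediction table")
        for raw in fh:
            if not raw.strip():
                continue
            d, m, s, r = raw.rstrip("\n").split("\t")
            records.append(PredictionRecord(d, m, float(s), int(r)))
    return PredictionTable(records)
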