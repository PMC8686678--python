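"""Shared domain types for the annotation pipeline.

All containers are thin dataclasses around numpy arrays with eager validation:
an invalid object is never constructed, so downstream code can assume the
invariants (non-negative expression values, unique identifiers, one-hot label
columns, column-stochastic probabilities) without re-checking them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np


class CallrError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(CallrError):
    """A file could not be parsed in the declared format."""


class ValidationError(CallrError):
    """Parsed or computed data violates a domain invariant."""


def _find_duplicates(items) -> list[str]:
    return sorted(name for name, c in Counter(items).items() if c > 1)


@dataclass
class ExpressionMatrix:
    """A genes x cells expression matrix with identifiers.

    ``values`` holds non-negative reals (raw or size-factor-normalized
    counts), shape ``(m, n)`` with ``m`` genes in rows and ``n`` cells in
    columns. Cell order defines the coordinate system for every index used
    downstream (labeled-cell indices, graph nodes).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        m, n = self.values.shape
        if m < 1:
            raise ValidationError("expression matrix needs at least 1 gene")
        if n < 2:
            raise ValidationError("expression matrix needs at least 2 cells")
        if len(self.gene_ids) != m:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {m} matrix rows"
            )
        if len(self.cell_ids) != n:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n} matrix columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values contain non-finite entries")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be non-negative")
        dup = _find_duplicates(self.gene_ids)
        if dup:
            raise ValidationError(f"duplicate gene ids: {', '.join(dup)}")
        dup = _find_duplicates(self.cell_ids)
        if dup:
            raise ValidationError(f"duplicate cell ids: {', '.join(dup)}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class MarkerSet:
    """Cell type -> marker gene ids, in file order.

    A gene may mark more than one type; ambiguity is resolved later by the
    representative-selection rule (cells scoring high for exactly one type).
    """

    markers: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValidationError("marker set is empty")
        for type_name, genes in self.markers.items():
            if not genes:
                raise ValidationError(f"cell type {type_name!r} has no marker genes")

    @property
    def k_types(self) -> int:
        return len(self.markers)

    @property
    def type_names(self) -> list[str]:
        return list(self.markers)


@dataclass
class LabelSet:
    """Partial annotation: the labeled cell subset Z and its type labels.

    ``labeled_indices`` are positions in the expression matrix's cell order;
    ``type_universe`` is the ordered list of the K known cell types, every one
    of which must occur among the labels (K is read off the annotated subset).
    """

    labeled_indices: np.ndarray
    labels: list[str]
    type_universe: list[str]
    n_cells: int

    def __post_init__(self) -> None:
        self.labeled_indices = np.asarray(self.labeled_indices, dtype=np.intp)
        self.labels = [str(l) for l in self.labels]
        self.type_universe = [str(t) for t in self.type_universe]
        if self.labeled_indices.size == 0:
            raise ValidationError("no labeled cells")
        if self.labeled_indices.size != len(self.labels):
            raise ValidationError("labeled_indices and labels length mismatch")
        if len(set(self.labeled_indices.tolist())) != self.labeled_indices.size:
            raise ValidationError("labeled_indices contains duplicates")
        if self.labeled_indices.min() < 0 or self.labeled_indices.max() >= self.n_cells:
            raise ValidationError(
                f"labeled index out of range for {self.n_cells} cells"
            )
        dup = _find_duplicates(self.type_universe)
        if dup:
            raise ValidationError(f"duplicate types in universe: {', '.join(dup)}")
        universe = set(self.type_universe)
        unknown = sorted(set(self.labels) - universe)
        if unknown:
            raise ValidationError(f"labels outside type universe: {', '.join(unknown)}")
        missing = sorted(universe - set(self.labels))
        if missing:
            raise ValidationError(
                f"types with no labeled cell: {', '.join(missing)}"
            )
        if len(self.type_universe) < 2:
            raise ValidationError("K must be >= 2 (need at least two cell types)")

    @property
    def k_types(self) -> int:
        return len(self.type_universe)

    @property
    def n_labeled(self) -> int:
        return int(self.labeled_indices.size)

    def unlabeled_indices(self) -> np.ndarray:
        mask = np.ones(self.n_cells, dtype=bool)
        mask[self.labeled_indices] = False
        return np.flatnonzero(mask)

    def label_codes(self) -> np.ndarray:
        """Labels as integer codes into ``type_universe`` order."""
        code = {t: k for k, t in enumerate(self.type_universe)}
        return np.array([code[l] for l in self.labels], dtype=np.intp)


@dataclass
class SizeFactors:
    """Per-cell library-size factors; dividing by them equalizes column sums."""

    factors: np.ndarray
    reference: float

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=np.float64)
        if np.any(self.factors <= 0):
            raise ValidationError("size factors must be strictly positive")


@dataclass
class CellGraph:
    """Mutual k-NN adjacency, kernel similarity and Laplacian over n cells."""

    adjacency: np.ndarray
    similarity: np.ndarray
    laplacian: np.ndarray
    k_neighbors: int = 17
    kernel_variance: float = 1.0

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class TfidfMatrix:
    """Gene x cell TF-IDF weights, with optional per-gene cutoffs applied."""

    values: np.ndarray
    cutoffs: np.ndarray | None = None
    cutoff_percentile: float = 95.0
    cutoff_factor: float = 0.25

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValidationError("TF-IDF values must be non-negative")


@dataclass
class MarkerScoreTable:
    """Per-type, per-cell marker scores S[c, j]."""

    scores: np.ndarray
    type_names: list[str]
    selection_percentile: float = 85.0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape[0] != len(self.type_names):
            raise ValidationError("score rows must match type names")
        if np.any(self.scores < 0):
            raise ValidationError("marker scores must be non-negative")


@dataclass
class ProbMatrix:
    """Column-stochastic K x n class-probability matrix with a positive floor.

    Probabilities are clamped below at ``floor`` before any logarithm, then
    columns are renormalized; the floor guards the log-likelihood terms
    against -inf when a classifier assigns an exact zero.
    """

    probs: np.ndarray
    floor: float = 1e-10

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)

    @classmethod
    def from_raw(cls, raw: np.ndarray, floor: float = 1e-10) -> "ProbMatrix":
        raw = np.asarray(raw, dtype=np.float64)
        if np.any(~np.isfinite(raw)) or np.any(raw < -1e-9):
            raise ValidationError("raw probabilities must be finite and >= 0")
        colsums = raw.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-6):
            raise ValidationError("probability columns must sum to 1")
        clipped = np.clip(raw, floor, 1.0)
        clipped /= clipped.sum(axis=0, keepdims=True)
        clipped = np.clip(clipped, floor, 1.0)
        return cls(probs=clipped, floor=floor)

    def log(self) -> np.ndarray:
        return np.log(np.clip(self.probs, self.floor, 1.0))

    @property
    def k_types(self) -> int:
        return self.probs.shape[0]

    @property
    def n_cells(self) -> int:
        return self.probs.shape[1]


@dataclass
class AnnotationMatrix:
    """One-hot K x n label matrix U; labeled columns are frozen to Z's labels."""

    u: np.ndarray
    frozen_columns: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        self.frozen_columns = np.asarray(self.frozen_columns, dtype=np.intp)
        if not is_one_hot(self.u):
            raise ValidationError("annotation matrix columns must be one-hot")

    def labels(self) -> np.ndarray:
        """Per-cell integer labels (row index of the 1 in each column)."""
        return np.argmax(self.u, axis=0)


def is_one_hot(u: np.ndarray) -> bool:
    u = np.asarray(u)
    if u.ndim != 2:
        return False
    binary = np.all((u == 0.0) | (u == 1.0))
    return bool(binary and np.all(u.sum(axis=0) == 1.0))


def one_hot(codes: np.ndarray, k: int) -> np.ndarray:
    """K x n one-hot matrix from integer codes."""
    codes = np.asarray(codes, dtype=np.intp)
    u = np.zeros((k, codes.size), dtype=np.float64)
    u[codes, np.arange(codes.size)] = 1.0
    return u
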