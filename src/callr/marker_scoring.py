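"""Representative-cell selection from marker genes.

Bootstraps the labeled subset when no manual annotation is available, using
the marker-scoring scheme popularized by Garnett:

1. TF-IDF transform of the normalized expression matrix:
   ``T[i, j] = (X[i, j] / colsum_j) * (1 + n / rowsum_i)`` — a gene's share of
   its cell's library, up-weighted when the gene is rare across cells.
2. Per-gene cutoff ``C_i = factor * q_i`` with ``q_i`` the (default 95th)
   percentile of gene i's TF-IDF row; entries below C_i are zeroed.
3. Marker score ``S[c, j] = sum over markers g of type c of T_cut[g, j]``.
4. Cells at or above the (default 85th) percentile of S[c, .] for exactly one
   type c become representatives of that type.

Percentiles use linear interpolation between order statistics over all n
cells (zeros included); ties at a threshold count as selected.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import (
    ExpressionMatrix,
    LabelSet,
    MarkerScoreTable,
    MarkerSet,
    TfidfMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)


def tfidf(x: ExpressionMatrix) -> TfidfMatrix:
    """TF-IDF weights of a normalized matrix with no all-zero genes or cells."""
    colsums = x.values.sum(axis=0)
    rowsums = x.values.sum(axis=1)
    if np.any(rowsums <= 0):
        raise ValidationError("TF-IDF input has all-zero genes; filter first")
    if np.any(colsums <= 0):
        raise ValidationError("TF-IDF input has all-zero cells")
    n = x.n_cells
    values = (x.values / colsums[np.newaxis, :]) * (1.0 + n / rowsums[:, np.newaxis])
    return TfidfMatrix(values=values)


def apply_cutoff(
    t: TfidfMatrix, percentile: float = 95.0, factor: float = 0.25
) -> TfidfMatrix:
    """Zero out entries below the per-gene cutoff C_i = factor * q_i."""
    if not (0.0 < percentile <= 100.0):
        raise ValidationError("cutoff percentile must lie in (0, 100]")
    q = np.percentile(t.values, percentile, axis=1)
    cutoffs = factor * q
    values = np.where(t.values < cutoffs[:, np.newaxis], 0.0, t.values)
    return TfidfMatrix(
        values=values,
        cutoffs=cutoffs,
        cutoff_percentile=percentile,
        cutoff_factor=factor,
    )


def resolve_markers(
    markers: MarkerSet, gene_ids: list[str]
) -> dict[str, list[int]]:
    """Map marker gene ids to row indices; absent genes dropped with a warning."""
    index = {g: i for i, g in enumerate(gene_ids)}
    resolved: dict[str, list[int]] = {}
    for type_name, genes in markers.markers.items():
        rows = [index[g] for g in genes if g in index]
        missing = [g for g in genes if g not in index]
        if missing:
            logger.warning(
                "type %r: %d marker gene(s) absent from the matrix: %s",
                type_name,
                len(missing),
                ", ".join(missing),
            )
        if not rows:
            raise ValidationError(
                f"all marker genes of type {type_name!r} are absent from the matrix"
            )
        resolved[type_name] = rows
    return resolved


def marker_scores(
    t_cut: TfidfMatrix, markers: MarkerSet, gene_ids: list[str]
) -> MarkerScoreTable:
    """Per-type, per-cell sums of cutoff TF-IDF over each type's marker genes."""
    resolved = resolve_markers(markers, gene_ids)
    scores = np.vstack(
        [t_cut.values[rows, :].sum(axis=0) for rows in resolved.values()]
    )
    return MarkerScoreTable(scores=scores, type_names=list(resolved))


def select_representatives(
    scores: MarkerScoreTable,
    percentile: float = 85.0,
    n_cells: int | None = None,
    on_empty_type: str = "error",
) -> LabelSet:
    """Cells at/above the per-type score percentile for exactly one type.

    ``on_empty_type`` controls what happens when some type ends with zero
    representatives: ``"error"`` raises (the downstream fit needs every type
    seeded), ``"drop"`` removes the type with a warning.
    """
    if on_empty_type not in ("error", "drop"):
        raise ValidationError("on_empty_type must be 'error' or 'drop'")
    s = scores.scores
    k, n = s.shape
    thresholds = np.percentile(s, percentile, axis=1)
    above = s >= thresholds[:, np.newaxis]          # threshold pass
    unique = above.sum(axis=0) == 1                 # "only one cell type" pass
    selected = np.flatnonzero(unique)
    winner = np.argmax(above[:, selected], axis=0) if selected.size else np.empty(0, int)

    counts = np.bincount(winner, minlength=k)
    empty = [scores.type_names[c] for c in range(k) if counts[c] == 0]
    if empty:
        msg = f"types with zero representatives: {', '.join(empty)}"
        if on_empty_type == "error":
            raise ValidationError(msg)
        logger.warning("%s; dropping them", msg)

    keep_types = [t for c, t in enumerate(scores.type_names) if counts[c] > 0]
    labels = [scores.type_names[c] for c in winner]
    if n_cells is None:
        n_cells = n
    return LabelSet(
        labeled_indices=selected,
        labels=labels,
        type_universe=keep_types,
        n_cells=n_cells,
    )


def representatives_from_markers(
    x_normalized: ExpressionMatrix,
    markers: MarkerSet,
    cutoff_percentile: float = 95.0,
    cutoff_factor: float = 0.25,
    selection_percentile: float = 85.0,
    on_empty_type: str = "error",
) -> LabelSet:
    """Full bootstrap: TF-IDF -> cutoff -> marker scores -> representatives."""
    t = tfidf(x_normalized)
    t_cut = apply_cutoff(t, percentile=cutoff_percentile, factor=cutoff_factor)
    table = marker_scores(t_cut, markers, x_normalized.gene_ids)
    return select_representatives(
        table,
        percentile=selection_percentile,
        n_cells=x_normalized.n_cells,
        on_empty_type=on_empty_type,
    )
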