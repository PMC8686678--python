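"""Readers and writers for the formats the tool touches.

Expression matrices come in as 10X-style Matrix Market directories
(``matrix.mtx`` plus ``genes.tsv``/``barcodes.tsv`` sidecars) or as dense
CSV/TSV with gene rows and a header of cell ids. Marker files use a minimal
hand-writable dialect, one cell type per line::

    T cell: CD3D, CD3E
    B cell: MS4A1

Label files are two-column TSV (cell_id <tab> type). Cell order is defined by
the expression file and is the coordinate system for all indices.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    ExpressionMatrix,
    FormatError,
    LabelSet,
    MarkerSet,
    ValidationError,
)

logger = logging.getLogger(__name__)

_MTX_NAMES = ("matrix.mtx", "expression.mtx")
_GENE_NAMES = ("genes.tsv", "features.tsv", "genes.txt")
_BARCODE_NAMES = ("barcodes.tsv", "barcodes.txt")


def _find_sidecar(directory: Path, candidates) -> Path:
    for name in candidates:
        p = directory / name
        if p.exists():
            return p
    raise FormatError(
        f"none of {', '.join(candidates)} found in {directory}"
    )


def _read_id_column(path: Path) -> list[str]:
    # 10X gene sidecars may carry two columns (id, symbol); take the first.
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            ids.append(line.split("\t")[0].strip())
    return ids


def infer_format(path) -> str:
    p = Path(path)
    if p.is_dir():
        return "mtx_dir"
    suffix = p.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    raise FormatError(f"cannot infer expression format from {path}")


def read_expression(path, fmt: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix, normalizing orientation to genes x cells.

    For ``mtx_dir`` inputs stored cells x genes (row count matches the
    barcode count and not the gene count) the matrix is transposed.
    """
    if fmt is None:
        fmt = infer_format(path)
    if fmt == "mtx_dir":
        directory = Path(path)
        mtx_path = _find_sidecar(directory, _MTX_NAMES)
        gene_ids = _read_id_column(_find_sidecar(directory, _GENE_NAMES))
        cell_ids = _read_id_column(_find_sidecar(directory, _BARCODE_NAMES))
        try:
            mat = scipy.io.mmread(os.fspath(mtx_path))
        except ValueError as exc:
            raise FormatError(f"malformed Matrix Market file {mtx_path}: {exc}") from exc
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=np.float64
        )
        if values.shape[0] != len(gene_ids):
            if values.shape[0] == len(cell_ids) and values.shape[1] == len(gene_ids):
                logger.info("matrix stored cells x genes; transposing")
                values = values.T
            else:
                raise ValidationError(
                    f"matrix shape {values.shape} matches neither "
                    f"{len(gene_ids)} genes x {len(cell_ids)} cells nor its transpose"
                )
        return ExpressionMatrix(values=values, gene_ids=gene_ids, cell_ids=cell_ids)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise FormatError(f"malformed {fmt} file {path}: {exc}") from exc
        return ExpressionMatrix(
            values=df.to_numpy(dtype=np.float64),
            gene_ids=[str(g) for g in df.index],
            cell_ids=[str(c) for c in df.columns],
        )
    raise FormatError(f"unknown expression format {fmt!r}")


def write_expression(x: ExpressionMatrix, path, fmt: str | None = None) -> None:
    if fmt is None:
        fmt = infer_format(path)
    if fmt == "mtx_dir":
        directory = Path(path)
        directory.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(
            os.fspath(directory / "matrix.mtx"),
            scipy.sparse.coo_matrix(x.values),
        )
        (directory / "genes.tsv").write_text("".join(g + "\n" for g in x.gene_ids))
        (directory / "barcodes.tsv").write_text("".join(c + "\n" for c in x.cell_ids))
        return
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.DataFrame(x.values, index=x.gene_ids, columns=x.cell_ids)
        df.to_csv(path, sep=sep)
        return
    raise FormatError(f"unknown expression format {fmt!r}")


def read_markers(path) -> MarkerSet:
    """Parse a ``type: gene, gene, ...`` marker file into a MarkerSet."""
    markers: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise FormatError(
                    f"{path}:{lineno}: expected 'type: gene, gene, ...'"
                )
            type_name, _, rest = line.partition(":")
            type_name = type_name.strip()
            genes = [g.strip() for g in rest.split(",")]
            genes = [g for g in genes if g]
            if not type_name:
                raise FormatError(f"{path}:{lineno}: empty cell-type name")
            if not genes:
                raise ValidationError(
                    f"{path}:{lineno}: cell type {type_name!r} has no marker genes"
                )
            if type_name in markers:
                raise ValidationError(
                    f"{path}:{lineno}: repeated cell type {type_name!r}"
                )
            markers[type_name] = genes
    if not markers:
        raise ValidationError(f"{path}: no marker records")
    return MarkerSet(markers=markers)


def write_markers(markers: MarkerSet, path) -> None:
    with open(path, "w") as fh:
        for type_name, genes in markers.markers.items():
            fh.write(f"{type_name}: {', '.join(genes)}\n")


def read_labels(path, cell_ids: list[str]) -> LabelSet:
    """Read a (cell_id, type) TSV and resolve indices against ``cell_ids``."""
    index = {c: i for i, c in enumerate(cell_ids)}
    seen: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 'cell_id<TAB>type'"
                )
            cell_id, type_name = parts[0].strip(), parts[1].strip()
            if cell_id not in index:
                raise ValidationError(f"{path}:{lineno}: unknown cell id {cell_id!r}")
            if cell_id in seen:
                if seen[cell_id] != type_name:
                    raise ValidationError(
                        f"{path}:{lineno}: cell {cell_id!r} labeled both "
                        f"{seen[cell_id]!r} and {type_name!r}"
                    )
                continue
            seen[cell_id] = type_name
    if not seen:
        raise ValidationError(f"{path}: no labeled cells")
    cells = sorted(seen, key=lambda c: index[c])
    return LabelSet(
        labeled_indices=np.array([index[c] for c in cells], dtype=np.intp),
        labels=[seen[c] for c in cells],
        type_universe=sorted(set(seen.values())),
        n_cells=len(cell_ids),
    )


def write_labels(labels: LabelSet, cell_ids: list[str], path) -> None:
    """Write the labeled subset back out as (cell_id, type) TSV."""
    with open(path, "w") as fh:
        for idx, type_name in zip(labels.labeled_indices, labels.labels):
            fh.write(f"{cell_ids[idx]}\t{type_name}\n")


def write_predictions(
    cell_ids: list[str],
    predicted: list[str],
    labeled_indices: np.ndarray,
    path,
) -> None:
    """Write the full annotation as CSV (cell_id, predicted_type, was_labeled)."""
    was_labeled = np.zeros(len(cell_ids), dtype=bool)
    was_labeled[np.asarray(labeled_indices, dtype=np.intp)] = True
    df = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "predicted_type": predicted,
            "was_labeled": was_labeled.astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str, "predicted_type": str})
    required = {"cell_id", "predicted_type", "was_labeled"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df
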