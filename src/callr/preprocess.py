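"""Gene filtering and size-factor normalization.

Applied, in this order, before graph construction, regression and TF-IDF
scoring: (1) drop genes with zero expression across all cells; (2) divide
each cell by its library-size factor s_j = colsum_j / median(colsums), so
that every cell's total count equals the median library size. No log
transform is applied anywhere in the pipeline.
"""

from __future__ import annotations

import numpy as np

from .datatypes import ExpressionMatrix, SizeFactors, ValidationError


def filter_zero_genes(x: ExpressionMatrix) -> ExpressionMatrix:
    """Keep exactly the genes with positive total expression, order preserved."""
    row_sums = x.values.sum(axis=1)
    keep = row_sums > 0
    if not np.any(keep):
        raise ValidationError("all genes have zero expression across all cells")
    if np.all(keep):
        return x
    return ExpressionMatrix(
        values=x.values[keep],
        gene_ids=[g for g, k in zip(x.gene_ids, keep) if k],
        cell_ids=list(x.cell_ids),
    )


def size_factor_normalize(x: ExpressionMatrix) -> tuple[ExpressionMatrix, SizeFactors]:
    """Equalize library sizes: s_j = colsum_j / median(colsums), X'_j = X_j / s_j.

    After normalization every cell column sums to the median of the original
    column sums (the reference).
    """
    colsums = x.values.sum(axis=0)
    zero = np.flatnonzero(colsums <= 0)
    if zero.size:
        names = ", ".join(x.cell_ids[j] for j in zero[:10])
        raise ValidationError(f"cells with zero total expression: {names}")
    reference = float(np.median(colsums))
    factors = colsums / reference
    normalized = ExpressionMatrix(
        values=x.values / factors[np.newaxis, :],
        gene_ids=list(x.gene_ids),
        cell_ids=list(x.cell_ids),
    )
    return normalized, SizeFactors(factors=factors, reference=reference)
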