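"""Partition-agreement metrics: ARI, NMI and classification accuracy.

ARI and NMI are computed from the contingency table n_ij between two
partitions of the same n items:

    RI  = sum_ij C(n_ij, 2) / C(n, 2)
    ARI = (RI - E[RI]) / (max(RI) - E[RI])        (permutation-model E and max)
    NMI = 2 I(A, B) / (H(A) + H(B))               (natural log; base cancels)

Both are symmetric and invariant to relabeling of either partition.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import comb

from .datatypes import ValidationError

logger = logging.getLogger(__name__)


def contingency_table(a, b) -> np.ndarray:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("partitions must be 1-D vectors of equal length")
    return pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()


def ari(a, b) -> float:
    """Adjusted Rand index between two partitions of the same items."""
    table = contingency_table(a, b)
    n = table.sum()
    if n < 2:
        raise ValidationError("ARI needs at least 2 items")
    sum_ij = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    maximum = 0.5 * (sum_a + sum_b)
    if maximum == expected:
        # Both partitions all-singletons or a single cluster: chance model
        # degenerates; identical partitions score 1, anything else 0.
        identical = bool(np.array_equal(*(_canonical(v) for v in (a, b))))
        return 1.0 if identical else 0.0
    return float((sum_ij - expected) / (maximum - expected))


def nmi(a, b) -> float:
    """Normalized mutual information, 2 I/(H_A + H_B), in [0, 1]."""
    table = contingency_table(a, b).astype(np.float64)
    n = table.sum()
    pa = table.sum(axis=1) / n
    pb = table.sum(axis=0) / n
    h_a = -np.sum(pa * np.log(pa, where=pa > 0, out=np.zeros_like(pa)))
    h_b = -np.sum(pb * np.log(pb, where=pb > 0, out=np.zeros_like(pb)))
    if h_a + h_b == 0.0:
        logger.info("both partitions are a single cluster; NMI = 1 by convention")
        return 1.0
    pij = table / n
    outer = pa[:, None] * pb[None, :]
    mask = pij > 0
    mi = float(np.sum(pij[mask] * np.log(pij[mask] / outer[mask])))
    return float(2.0 * mi / (h_a + h_b))


def accuracy(y_true, y_pred, subset=None) -> float:
    """Fraction of exact matches, optionally restricted to ``subset`` indices.

    In the annotation setting the subset defaults to the unlabeled cells Z',
    supplied by the caller.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("prediction and truth must have equal length")
    if subset is not None:
        subset = np.asarray(subset, dtype=np.intp)
        if subset.size == 0:
            raise ValidationError("accuracy over an empty subset is undefined")
        y_true = y_true[subset]
        y_pred = y_pred[subset]
    return float(np.mean(y_true == y_pred))


def _canonical(v) -> np.ndarray:
    """Relabel a partition by order of first appearance (for identity checks)."""
    v = np.asarray(v)
    seen: dict = {}
    out = np.empty(v.shape[0], dtype=np.intp)
    for i, item in enumerate(v):
        out[i] = seen.setdefault(item, len(seen))
    return out
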