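"""Mutual k-NN graph, adaptive Gaussian kernel weights and graph Laplacian.

Cells are nodes; an (undirected, unweighted) edge exists only when each cell
lies within the other's k nearest Euclidean neighbors, computed on the
normalized expression matrix over all genes. Edge weights use a locally
adaptive Gaussian kernel: the scale of edge (i, j) blends the mean
neighbor distances of both endpoints with the edge length itself,
eps_ij = (mu_i + mu_j + d_ij) / 3, and

    S_ij = exp(-d_ij^2 / (2 * variance * eps_ij^2)) / (eps_ij * sqrt(2 pi variance))

with a global variance multiplier of 1 by default. The Laplacian is the
unnormalized L = D - S of spectral clustering (symmetric-normalized variant
available), whose quadratic form tr(U L U^T) equals the weighted cut of a
label assignment U.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .datatypes import CellGraph, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

_EPS_FLOOR = 1e-12


def _distance_matrix(x: ExpressionMatrix) -> np.ndarray:
    return squareform(pdist(x.values.T, metric="euclidean"))


def _knn_index_matrix(dist: np.ndarray, k: int) -> np.ndarray:
    """Indices of each cell's k nearest neighbors (self excluded).

    Ties at the k-th distance break by cell index (lower index wins): the
    stable argsort on (distance, index) keys makes the graph deterministic.
    """
    n = dist.shape[0]
    d = dist.copy()
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


def knn_adjacency(x: ExpressionMatrix, k: int) -> np.ndarray:
    """Binary mutual k-NN adjacency: A_ij = 1 iff i and j are in each other's k-NN."""
    n = x.n_cells
    if not (1 <= k <= n - 1):
        raise ValidationError(f"k must satisfy 1 <= k <= n-1 = {n - 1}, got {k}")
    dist = _distance_matrix(x)
    return _mutual_adjacency(dist, k)


def _mutual_adjacency(dist: np.ndarray, k: int) -> np.ndarray:
    n = dist.shape[0]
    nn = _knn_index_matrix(dist, k)
    directed = np.zeros((n, n), dtype=np.float64)
    rows = np.repeat(np.arange(n), k)
    directed[rows, nn.ravel()] = 1.0
    adjacency = directed * directed.T    # mutual rule
    np.fill_diagonal(adjacency, 0.0)
    return adjacency


def kernel_weights(
    x: ExpressionMatrix,
    adjacency: np.ndarray,
    k: int,
    variance: float = 1.0,
) -> np.ndarray:
    """Adaptive Gaussian kernel similarities on the edges of ``adjacency``."""
    if variance <= 0:
        raise ValidationError("kernel variance must be positive")
    dist = _distance_matrix(x)
    return _kernel_from_distances(dist, adjacency, k, variance)


def _kernel_from_distances(
    dist: np.ndarray, adjacency: np.ndarray, k: int, variance: float
) -> np.ndarray:
    nn = _knn_index_matrix(dist, k)
    mu = np.take_along_axis(dist, nn, axis=1).mean(axis=1)   # mean k-NN distance
    eps = (mu[:, None] + mu[None, :] + dist) / 3.0
    tiny = eps < _EPS_FLOOR
    if np.any(tiny & (adjacency > 0)):
        logger.warning(
            "kernel scale collapsed to 0 on %d edges; clamping to %g",
            int((tiny & (adjacency > 0)).sum()) // 2,
            _EPS_FLOOR,
        )
    eps = np.maximum(eps, _EPS_FLOOR)
    s = np.exp(-(dist**2) / (2.0 * variance * eps**2)) / (
        eps * np.sqrt(2.0 * np.pi * variance)
    )
    s = s * (adjacency > 0)
    return (s + s.T) / 2.0   # enforce exact symmetry against fp noise


def laplacian(similarity: np.ndarray, kind: str = "unnormalized") -> np.ndarray:
    """Graph Laplacian of a symmetric non-negative similarity matrix."""
    similarity = np.asarray(similarity, dtype=np.float64)
    if similarity.shape[0] != similarity.shape[1] or not np.allclose(
        similarity, similarity.T, atol=1e-12
    ):
        raise ValidationError("similarity matrix must be square and symmetric")
    if np.any(similarity < 0):
        raise ValidationError("similarity matrix must be non-negative")
    degrees = similarity.sum(axis=1)
    lap = np.diag(degrees) - similarity
    if kind == "unnormalized":
        return lap
    if kind == "symmetric":
        with np.errstate(divide="ignore"):
            inv_sqrt = np.where(degrees > 0, 1.0 / np.sqrt(np.maximum(degrees, 1e-300)), 0.0)
        return inv_sqrt[:, None] * lap * inv_sqrt[None, :]
    raise ValidationError(f"unknown laplacian kind {kind!r}")


def build_cell_graph(
    x: ExpressionMatrix,
    k: int = 17,
    variance: float = 1.0,
    laplacian_kind: str = "unnormalized",
) -> CellGraph:
    """Full graph construction: distances computed once, shared by all steps."""
    n = x.n_cells
    if not (1 <= k <= n - 1):
        raise ValidationError(f"k must satisfy 1 <= k <= n-1 = {n - 1}, got {k}")
    if variance <= 0:
        raise ValidationError("kernel variance must be positive")
    dist = _distance_matrix(x)
    adjacency = _mutual_adjacency(dist, k)
    similarity = _kernel_from_distances(dist, adjacency, k, variance)
    lap = laplacian(similarity, kind=laplacian_kind)
    return CellGraph(
        adjacency=adjacency,
        similarity=similarity,
        laplacian=lap,
        k_neighbors=k,
        kernel_variance=variance,
    )
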