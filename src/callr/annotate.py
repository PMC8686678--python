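"""The core semi-supervised annotation optimizer.

The method labels the unlabeled cells of a dataset by minimizing, over
one-hot label matrices U (K types x n cells),

    -sum_{i in Z} log P(g_i | x_i) - sum_{i in Z'} sum_k u_ki log P(k | x_i)
        + lambda1 * tr(U L U^T) + lambda2 * sum_k ||beta_k||_1

where Z is the labeled subset, L the graph Laplacian over all cells and
P(k | x) a multinomial logistic model with L1-penalized coefficients beta.
The two blocks are optimized alternately:

* Step 1 (U-update): with the classifier fixed, run projected gradient
  descent on the relaxed problem over the product of probability simplices,
  ``V <- Pi_simplex(V + dt * (-V L + mu * log P))`` with ``mu = 1/lambda1``,
  then threshold each column to its nearest simplex vertex (the argmax).
  Keeping the iterate on the continuous simplex and thresholding at the end
  is the diffuse-then-threshold scheme of graph-MBO methods; thresholding
  every step would pin the iterate to its starting vertex because a single
  step of size dt cannot overcome a one-hot gap of 1.
* Step 2 (classifier update): with U fixed, refit the L1 multinomial
  logistic regression on all cells using the current labels.

Labeled columns are clamped to their given one-hot values throughout; they
pull on their neighbors through L but never move. The outer loop stops when
the label vector of two consecutive rounds is identical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV

from .cellgraph import build_cell_graph
from .config import FitConfig
from .datatypes import (
    AnnotationMatrix,
    CellGraph,
    ExpressionMatrix,
    LabelSet,
    MarkerSet,
    ProbMatrix,
    ValidationError,
    one_hot,
)
from .marker_scoring import representatives_from_markers
from .preprocess import filter_zero_genes, size_factor_normalize

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Simplex projections


def project_columns_to_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of each column onto the probability simplex.

    Sort-based water-filling: with u the descending sort of a column and
    css its cumulative sum, the threshold is lam = (css_rho - 1)/rho for the
    largest rho with u_rho > (css_rho - 1)/rho, and the projection is
    max(v - lam, 0).
    """
    v = np.asarray(v, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValidationError("cannot project non-finite values onto the simplex")
    k = v.shape[0]
    u = -np.sort(-v, axis=0)
    css = np.cumsum(u, axis=0) - 1.0
    ks = np.arange(1, k + 1, dtype=np.float64)[:, np.newaxis]
    rho = np.count_nonzero(u - css / ks > 0, axis=0)
    lam = css[rho - 1, np.arange(v.shape[1])] / rho
    return np.maximum(v - lam[np.newaxis, :], 0.0)


def project_to_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of a single vector onto the probability simplex."""
    v = np.asarray(v, dtype=np.float64)
    return project_columns_to_simplex(v[:, np.newaxis])[:, 0]


def project_to_vertex(v: np.ndarray) -> np.ndarray:
    """Nearest standard unit vector: one-hot at the argmax, ties to lowest index."""
    v = np.asarray(v, dtype=np.float64)
    out = np.zeros_like(v)
    out[np.argmax(v)] = 1.0
    return out


# ---------------------------------------------------------------------------
# Step 2: sparse multinomial logistic regression


@dataclass
class RegressionModel:
    """L1-penalized multinomial logistic model over genes.

    The documented contract is the reference-class parametrization
    log(P(k|x)/P(K|x)) = alpha_k + beta_k^T x for k < K; the fitted estimator
    uses the symmetric softmax form, so ``intercepts``/``coefficients``
    report differences against the last class. Predicted probabilities are
    the exposed surface.
    """

    estimator: LogisticRegression
    penalty: float
    k_types: int
    floor: float = 1e-10

    @property
    def intercepts(self) -> np.ndarray:
        """alpha: length K-1, reference class = last."""
        a = self.estimator.intercept_
        if a.shape[0] == 1 and self.k_types == 2:
            return a.copy()       # binary model is already in reference form
        return a[:-1] - a[-1]

    @property
    def coefficients(self) -> np.ndarray:
        """beta: m x (K-1), reference class = last."""
        b = self.estimator.coef_
        if b.shape[0] == 1 and self.k_types == 2:
            return b.T.copy()
        return (b[:-1] - b[-1]).T

    def predict_proba(self, x: ExpressionMatrix) -> ProbMatrix:
        raw = self.estimator.predict_proba(x.values.T).T  # K x n
        return ProbMatrix.from_raw(raw, floor=self.floor)


def fit_sparse_multinomial(
    x: ExpressionMatrix,
    y: np.ndarray,
    lambda2: float = 0.004,
    *,
    k_types: int | None = None,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-3,
    floor: float = 1e-10,
    warm_model: RegressionModel | None = None,
) -> RegressionModel:
    """Fit the L1 multinomial logistic regression of Step 2.

    ``y`` are integer class codes for every cell (column) of ``x``; all
    classes 0..K-1 must be present. The penalty follows the per-observation
    loss scaling (1/n) * loglik + lambda2 * ||beta||_1, i.e. C = 1/(n * lambda2).
    """
    y = np.asarray(y, dtype=np.intp)
    n = x.n_cells
    if y.shape[0] != n:
        raise ValidationError("label vector length must equal the number of cells")
    present = np.unique(y)
    if k_types is None:
        k_types = int(present.max()) + 1
    missing = sorted(set(range(k_types)) - set(present.tolist()))
    if missing:
        raise ValidationError(f"classes absent from labels: {missing}")
    if lambda2 <= 0:
        raise ValidationError("lambda2 must be positive")

    c = 1.0 / (n * lambda2)
    if warm_model is not None and warm_model.estimator.C == c:
        est = warm_model.estimator
    else:
        est = LogisticRegression(
            l1_ratio=1.0,   # pure lasso penalty
            C=c,
            solver="saga",
            max_iter=max_iter,
            tol=tol,
            random_state=seed,
            warm_start=True,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(x.values.T, y)
    n_iter = int(np.max(est.n_iter_))
    if n_iter >= max_iter:
        logger.warning(
            "sparse logistic regression hit max_iter=%d without reaching tol=%g",
            max_iter,
            tol,
        )
    return RegressionModel(estimator=est, penalty=lambda2, k_types=k_types, floor=floor)


# ---------------------------------------------------------------------------
# Step 1: projected-gradient label update


def u_update(
    u: np.ndarray,
    lap: np.ndarray,
    p: ProbMatrix,
    labels: LabelSet,
    cfg: FitConfig,
) -> tuple[np.ndarray, int, bool]:
    """One Step-1 solve: relaxed projected gradient descent, then threshold.

    Returns ``(u_new, n_inner, converged)`` with ``u_new`` one-hot and the
    labeled columns clamped to their given values.
    """
    u = np.asarray(u, dtype=np.float64)
    k, n = u.shape
    if lap.shape != (n, n):
        raise ValidationError("Laplacian shape must match the number of cells")
    if p.probs.shape != (k, n):
        raise ValidationError("probability matrix shape must match U")
    logp = p.log()
    if not np.all(np.isfinite(logp)):
        raise ValidationError("log-probabilities are non-finite; floor was bypassed")
    z = labels.labeled_indices
    u_z = one_hot(labels.label_codes(), k)

    v = u.copy()
    v[:, z] = u_z
    drift = cfg.mu * logp
    converged = False
    n_inner = 0
    stable = 0
    readout = np.argmax(v, axis=0)
    for n_inner in range(1, cfg.max_inner + 1):
        v_new = project_columns_to_simplex(v + cfg.step_size * (-(v @ lap) + drift))
        v_new[:, z] = u_z
        delta = float(np.max(np.abs(v_new - v)))
        v = v_new
        new_readout = np.argmax(v, axis=0)
        # The consumed quantity is the thresholded (one-hot) readout; declare
        # convergence when it has not changed over a patience window, or when
        # the continuous iterate itself has stopped moving.
        stable = stable + 1 if np.array_equal(new_readout, readout) else 0
        readout = new_readout
        if delta <= cfg.eps_inner or stable >= cfg.inner_patience:
            converged = True
            break

    codes = readout                    # vertex thresholding (order-preserving)
    u_out = one_hot(codes, k)
    u_out[:, z] = u_z
    return u_out, n_inner, converged


def objective_value(
    u: np.ndarray,
    p: ProbMatrix,
    lap: np.ndarray,
    labels: LabelSet,
    mu: float,
) -> float:
    """The tracked Step-1 objective: -mu * sum_{i in Z'} u_i . log P_i + tr(U L U^T).

    Diagnostics only — the thresholding step does not guarantee monotone
    descent of this quantity.
    """
    u = np.asarray(u, dtype=np.float64)
    logp = p.log()
    unlabeled = labels.unlabeled_indices()
    log_term = -mu * float(np.sum(u[:, unlabeled] * logp[:, unlabeled]))
    cut_term = float(np.sum((u @ lap) * u))
    return log_term + cut_term


# ---------------------------------------------------------------------------
# Full alternating fit


@dataclass
class CallrResult:
    """Outcome of a full annotation fit."""

    predicted_types: list[str]
    codes: np.ndarray
    annotation: AnnotationMatrix
    labels: LabelSet
    converged: bool
    n_outer: int
    inner_iterations: list[int] = field(default_factory=list)
    objective_trace: list[float] = field(default_factory=list)
    labels_changed: list[int] = field(default_factory=list)
    initial_codes: np.ndarray | None = None
    graph: CellGraph | None = None
    model: RegressionModel | None = None
    lap_spectral_norm: float = 0.0

    def diagnostics(self) -> dict:
        return {
            "converged": self.converged,
            "n_outer": self.n_outer,
            "inner_iterations": list(self.inner_iterations),
            "objective_trace": [float(v) for v in self.objective_trace],
            "labels_changed": list(self.labels_changed),
            "lap_spectral_norm": float(self.lap_spectral_norm),
            "per_type_labeled_counts": {
                t: int(c)
                for t, c in zip(
                    self.labels.type_universe,
                    np.bincount(
                        self.labels.label_codes(), minlength=self.labels.k_types
                    ),
                )
            },
        }


def _choose_lambda2_cv(x_z: np.ndarray, y_z: np.ndarray, seed: int) -> float:
    """Pick lambda2 by cross-validation on the labeled cells (optional path)."""
    counts = np.bincount(y_z)
    cv = int(min(3, counts[counts > 0].min()))
    if cv < 2:
        raise ValidationError("lambda2 cross-validation needs >= 2 cells per type")
    est = LogisticRegressionCV(
        l1_ratios=[1.0], penalty="elasticnet", solver="saga", Cs=10, cv=cv,
        max_iter=200, tol=1e-3, random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(x_z, y_z)
    c = float(np.mean(est.C_))
    return 1.0 / (c * x_z.shape[0])


def callr_fit(
    x: ExpressionMatrix,
    labels: LabelSet | None = None,
    markers: MarkerSet | None = None,
    cfg: FitConfig | None = None,
    lambda2_cv: bool = False,
) -> CallrResult:
    """Run the full pipeline: preprocess, graph, initialize, alternate, label.

    Either ``labels`` (a partial annotation) or ``markers`` (from which
    representatives are selected) must be given. Labeled cells keep their
    given types in the output.
    """
    cfg = cfg or FitConfig()
    if labels is None and markers is None:
        raise ValidationError("either labels or markers must be provided")

    x = filter_zero_genes(x)
    if cfg.normalize:
        x, _ = size_factor_normalize(x)

    if labels is None:
        labels = representatives_from_markers(
            x,
            markers,
            cutoff_percentile=cfg.cutoff_percentile,
            cutoff_factor=cfg.cutoff_factor,
            selection_percentile=cfg.selection_percentile,
        )
    if labels.n_cells != x.n_cells:
        raise ValidationError("label set does not match the expression matrix size")
    k = labels.k_types
    n = x.n_cells
    if n < k:
        raise ValidationError("need at least as many cells as types")

    graph = build_cell_graph(
        x, k=cfg.k_neighbors, variance=cfg.kernel_variance,
        laplacian_kind=cfg.laplacian,
    )
    lap = graph.laplacian
    lap_norm = float(np.max(np.abs(np.linalg.eigvalsh(lap))))
    if cfg.step_size > 1.0 / max(lap_norm, 1e-300):
        logger.info(
            "step size %g exceeds 1/||L|| = %g (smoothness bound); proceeding",
            cfg.step_size,
            1.0 / max(lap_norm, 1e-300),
        )

    z = labels.labeled_indices
    codes_z = labels.label_codes()
    rng = np.random.default_rng(cfg.seed)

    lam2 = cfg.lambda2
    if lambda2_cv:
        lam2 = _choose_lambda2_cv(x.values[:, z].T, codes_z, cfg.seed)
        logger.info("lambda2 selected by CV: %g", lam2)

    # Initialization: regression on the labeled cells, predict everything.
    x_z = ExpressionMatrix(
        values=x.values[:, z],
        gene_ids=list(x.gene_ids),
        cell_ids=[x.cell_ids[i] for i in z],
    )
    # The labeled subset is small; give its solver generous iterations.
    model = fit_sparse_multinomial(
        x_z, codes_z, lam2, k_types=k, seed=cfg.seed,
        max_iter=max(cfg.solver_max_iter, 1000), tol=cfg.solver_tol,
        floor=cfg.prob_floor,
    )
    p = model.predict_proba(x)
    if cfg.init == "regression":
        codes = np.argmax(p.probs, axis=0)
    else:
        codes = rng.integers(0, k, size=n)
    codes[z] = codes_z
    u = one_hot(codes, k)
    initial_codes = codes.copy()

    inner_counts: list[int] = []
    trace: list[float] = []
    changed_log: list[int] = []
    converged = False
    n_outer = 1
    if z.size == n:
        # Every cell is labeled: nothing to infer.
        converged = True
        trace.append(objective_value(u, p, lap, labels, cfg.mu))
    else:
        # Alternate Step 1 and Step 2 until the Step-1 output repeats. The
        # refit on all cells runs every round (the zero-initialized U_old of
        # the algorithm guarantees at least one), so self-training from the
        # propagated labels always takes effect.
        prev_codes: np.ndarray | None = None
        full_model: RegressionModel | None = None
        for n_outer in range(1, cfg.max_outer + 1):
            u, n_inner, _ = u_update(u, lap, p, labels, cfg)
            new_codes = np.argmax(u, axis=0)
            inner_counts.append(n_inner)
            trace.append(objective_value(u, p, lap, labels, cfg.mu))
            changed = int(np.sum(new_codes != codes))
            changed_log.append(changed)
            logger.info(
                "outer %d: %d inner iterations, %d labels changed",
                n_outer, n_inner, changed,
            )
            codes = new_codes
            full_model = fit_sparse_multinomial(
                x, codes, lam2, k_types=k, seed=cfg.seed,
                max_iter=cfg.solver_max_iter, tol=cfg.solver_tol,
                floor=cfg.prob_floor, warm_model=full_model,
            )
            model = full_model
            p = model.predict_proba(x)
            if prev_codes is not None and np.array_equal(new_codes, prev_codes):
                converged = True
                break
            prev_codes = new_codes

    predicted = [labels.type_universe[c] for c in codes]
    return CallrResult(
        predicted_types=predicted,
        codes=codes,
        annotation=AnnotationMatrix(u=u, frozen_columns=z),
        labels=labels,
        converged=converged,
        n_outer=n_outer,
        inner_iterations=inner_counts,
        objective_trace=trace,
        labels_changed=changed_log,
        initial_codes=initial_codes,
        graph=graph,
        model=model,
        lap_spectral_norm=lap_norm,
    )
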