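"""Synthetic scRNA-seq data with planted cell types and marker genes.

The generator draws counts from a negative binomial (mean mu, dispersion
theta, variance mu + mu^2/theta) with per-cell log-normal library-size
factors — the minimal model exhibiting the overdispersion and read-depth
variation the size-factor step exists to remove. Each type t owns a block of
``markers_per_type`` genes whose mean is elevated by exp(log_fold_change) in
cells of type t. Ground-truth labels, the planted MarkerSet and a stratified
partial LabelSet (the "revealed" fraction r, at least one cell per type) are
returned alongside the matrix, so every pipeline stage is testable without
external datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import FitConfig, SynthConfig
from .datatypes import ExpressionMatrix, LabelSet, MarkerSet, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SynthData:
    expression: ExpressionMatrix
    true_types: list[str]
    markers: MarkerSet
    labels: LabelSet

    @property
    def true_codes(self) -> np.ndarray:
        code = {t: i for i, t in enumerate(self.labels.type_universe)}
        return np.array([code[t] for t in self.true_types], dtype=np.intp)


def _stratified_labeled_indices(
    true_codes: np.ndarray, k: int, ratio: float, rng: np.random.Generator
) -> np.ndarray:
    """ceil(r*n) labeled cells, allocated to types by largest remainder, >= 1 each."""
    n = true_codes.size
    total = int(np.ceil(ratio * n))
    total = max(total, k)
    counts = np.bincount(true_codes, minlength=k)
    quota = total * counts / n
    alloc = np.maximum(np.floor(quota).astype(int), 1)
    alloc = np.minimum(alloc, counts)
    remainder = quota - np.floor(quota)
    while alloc.sum() < total:
        room = alloc < counts
        if not room.any():
            break
        pick = np.argmax(np.where(room, remainder, -1.0))
        alloc[pick] += 1
        remainder[pick] = -1.0
    while alloc.sum() > total:
        pick = np.argmax(np.where(alloc > 1, alloc, -1))
        alloc[pick] -= 1
    chosen = []
    for t in range(k):
        members = np.flatnonzero(true_codes == t)
        chosen.append(rng.choice(members, size=alloc[t], replace=False))
    return np.sort(np.concatenate(chosen))


def simulate(cfg: SynthConfig) -> SynthData:
    """Generate one synthetic dataset; bit-reproducible for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    k, n, m = cfg.k_types, cfg.n_cells, cfg.m_genes
    type_names = [f"type_{t}" for t in range(k)]
    true_codes = rng.choice(k, size=n, p=cfg.proportions)
    counts_per_type = np.bincount(true_codes, minlength=k)
    empty = [type_names[t] for t in range(k) if counts_per_type[t] == 0]
    if empty:
        raise ValidationError(
            f"types received zero cells from the proportions: {', '.join(empty)}"
        )

    marker_rows = {
        type_names[t]: list(range(t * cfg.markers_per_type, (t + 1) * cfg.markers_per_type))
        for t in range(k)
    }
    gene_ids = [f"gene_{g:04d}" for g in range(m)]
    cell_ids = [f"cell_{j:04d}" for j in range(n)]

    mean = np.full((m, n), cfg.baseline_mean)
    for t in range(k):
        rows = marker_rows[type_names[t]]
        cols = true_codes == t
        mean[np.ix_(rows, cols)] *= np.exp(cfg.log_fold_change)
    libsize = rng.lognormal(mean=0.0, sigma=cfg.libsize_sigma, size=n)
    mean = mean * libsize[np.newaxis, :]

    theta = cfg.dispersion
    # NB(mean mu, dispersion theta) via numpy's (n, p) parametrization.
    values = rng.negative_binomial(theta, theta / (theta + mean)).astype(np.float64)

    expression = ExpressionMatrix(values=values, gene_ids=gene_ids, cell_ids=cell_ids)
    markers = MarkerSet(
        markers={t: [gene_ids[g] for g in rows] for t, rows in marker_rows.items()}
    )
    labeled = _stratified_labeled_indices(true_codes, k, cfg.labeled_ratio, rng)
    labels = LabelSet(
        labeled_indices=labeled,
        labels=[type_names[true_codes[i]] for i in labeled],
        type_universe=type_names,
        n_cells=n,
    )
    return SynthData(
        expression=expression,
        true_types=[type_names[c] for c in true_codes],
        markers=markers,
        labels=labels,
    )


def resample_labels(
    data: SynthData, ratio: float, seed: int
) -> LabelSet:
    """A fresh stratified labeled subset over an existing dataset."""
    rng = np.random.default_rng(seed)
    k = len(data.labels.type_universe)
    labeled = _stratified_labeled_indices(data.true_codes, k, ratio, rng)
    return LabelSet(
        labeled_indices=labeled,
        labels=[data.true_types[i] for i in labeled],
        type_universe=list(data.labels.type_universe),
        n_cells=data.labels.n_cells,
    )


def labeled_ratio_sweep(
    cfg: SynthConfig,
    r_values,
    repeats: int = 10,
    fit_cfg: FitConfig | None = None,
) -> pd.DataFrame:
    """Accuracy of the fit across labeled-cell ratios, fresh subsets per repeat.

    Returns one row per r with the mean and standard deviation of
    unlabeled-cell accuracy across ``repeats`` fresh labeled subsets of one
    simulated dataset. Fit failures are recorded in the ``errors`` column,
    not raised.
    """
    from .annotate import callr_fit
    from .metrics import accuracy

    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    r_values = list(r_values)
    if any(not (0.0 < r < 1.0) for r in r_values):
        raise ValidationError("all r values must lie in (0, 1)")
    data = simulate(cfg)
    fit_cfg = fit_cfg or FitConfig()
    rows = []
    for r in r_values:
        accs: list[float] = []
        errors = 0
        for rep in range(repeats):
            seed = (cfg.seed * 1000 + rep * 37 + int(r * 1e6)) % (2**31)
            labels = resample_labels(data, r, seed)
            try:
                cfg_rep = FitConfig(**{**fit_cfg.to_dict(), "seed": seed})
                result = callr_fit(data.expression, labels=labels, cfg=cfg_rep)
                accs.append(
                    accuracy(
                        data.true_types,
                        result.predicted_types,
                        subset=labels.unlabeled_indices(),
                    )
                )
            except Exception as exc:   # recorded, not raised
                logger.warning("fit failed at r=%g repeat %d: %s", r, rep, exc)
                errors += 1
        mean = float(np.mean(accs)) if accs else np.nan
        sd = float(np.std(accs, ddof=1)) if len(accs) > 1 else np.nan
        rows.append(
            {
                "r": r,
                "mean_accuracy": mean,
                "sd_accuracy": sd,
                "n_ok": len(accs),
                "errors": errors,
            }
        )
    return pd.DataFrame(rows)
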