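"""Run configuration objects and YAML loading.

Defaults follow the method's published operating point: graph of 17 mutual
nearest neighbors with an adaptive Gaussian kernel (variance multiplier 1),
projected-gradient step size 0.005, label/graph trade-off mu = 0.3, lasso
penalty lambda2 = 0.004, TF-IDF cutoff at 0.25 x the 95th row percentile, and
representative selection at the 85th score percentile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Any

import yaml

from .datatypes import ValidationError


def _from_mapping(cls, data: dict[str, Any]):
    known = {f.name for f in fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValidationError(
            f"unknown {cls.__name__} keys: {', '.join(unknown)}"
        )
    return cls(**data)


@dataclass
class FitConfig:
    """Parameters of the annotation fit.

    mu is the weight of the log-probability (classifier) term relative to the
    graph-cut term in the label update (mu = 1/lambda1 of the underlying
    objective); step_size is the projected-gradient step; lambda2 the L1
    penalty of the multinomial regression; eps_inner the max-norm change at
    which the inner simplex iteration is declared converged.
    """

    mu: float = 0.3
    step_size: float = 0.005
    lambda2: float = 0.004
    k_neighbors: int = 17
    kernel_variance: float = 1.0
    laplacian: str = "symmetric"      # or "unnormalized"
    prob_floor: float = 1e-10
    eps_inner: float = 1e-7
    inner_patience: int = 1000
    max_outer: int = 50
    max_inner: int = 4000
    seed: int = 0
    normalize: bool = True
    init: str = "regression"          # or "random"
    standardize: bool = False
    solver_max_iter: int = 200
    solver_tol: float = 1e-3
    cutoff_percentile: float = 95.0
    cutoff_factor: float = 0.25
    selection_percentile: float = 85.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.step_size <= 0 or self.lambda2 <= 0:
            raise ValidationError("mu, step_size and lambda2 must be positive")
        if self.max_outer < 1 or self.max_inner < 1:
            raise ValidationError("iteration caps must be >= 1")
        if self.laplacian not in ("unnormalized", "symmetric"):
            raise ValidationError("laplacian must be 'unnormalized' or 'symmetric'")
        if self.init not in ("regression", "random"):
            raise ValidationError("init must be 'regression' or 'random'")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "FitConfig":
        return _from_mapping(cls, data)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class SynthConfig:
    """Parameters of the synthetic scRNA-seq generator.

    Counts are negative-binomial with per-cell log-normal library sizes;
    markers of a cell's own type have their mean multiplied by
    exp(log_fold_change). labeled_ratio r is the fraction of cells whose true
    label is revealed (stratified by type, at least one per type).
    """

    n_cells: int = 600
    m_genes: int = 200
    k_types: int = 4
    markers_per_type: int = 10
    log_fold_change: float = 2.0
    baseline_mean: float = 1.0
    dispersion: float = 0.5
    libsize_sigma: float = 0.3
    type_proportions: list[float] | None = None
    labeled_ratio: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2 or self.m_genes < 1 or self.k_types < 2:
            raise ValidationError("need n_cells >= 2, m_genes >= 1, k_types >= 2")
        if self.markers_per_type * self.k_types > self.m_genes:
            raise ValidationError("markers_per_type * k_types exceeds m_genes")
        if not (0.0 < self.labeled_ratio < 1.0):
            raise ValidationError("labeled_ratio must lie in (0, 1)")
        if self.type_proportions is not None:
            p = list(self.type_proportions)
            if len(p) != self.k_types:
                raise ValidationError("type_proportions length must equal k_types")
            if any(x <= 0 for x in p) or abs(sum(p) - 1.0) > 1e-8:
                raise ValidationError("type_proportions must be positive and sum to 1")
        if self.baseline_mean <= 0 or self.dispersion <= 0 or self.log_fold_change <= 0:
            raise ValidationError(
                "baseline_mean, dispersion and log_fold_change must be positive"
            )

    @property
    def proportions(self) -> list[float]:
        if self.type_proportions is None:
            return [1.0 / self.k_types] * self.k_types
        return list(self.type_proportions)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SynthConfig":
        return _from_mapping(cls, data)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def load_yaml_config(path, cls):
    """Load a FitConfig or SynthConfig from a YAML mapping; unknown keys rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"config file {path} must contain a mapping")
    return _from_mapping(cls, data)
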