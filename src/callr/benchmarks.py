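"""Synthetic-benchmark harnesses used by the validation suite and scripts.

The standard benchmark is 4 planted cell types, 600 cells, 200 genes,
marker elevation exp(2), 5% of cells labeled — small enough to run on one
CPU in seconds per fit, large enough for the graph term to matter. Each
experiment reports unlabeled-cell accuracy of the full fit next to the
initialization-only classifier (the regression trained on the labeled
subset alone), the quantity the semi-supervised machinery must beat.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotate import callr_fit
from .config import FitConfig, SynthConfig
from .metrics import accuracy, ari, nmi
from .synth import simulate


def semi_supervised_benchmark(
    seeds=range(10),
    synth_cfg: SynthConfig | None = None,
    fit_cfg: FitConfig | None = None,
) -> pd.DataFrame:
    """Fit the benchmark for each seed; one row per seed.

    Columns: seed, init_accuracy, callr_accuracy (both on unlabeled cells),
    ari, nmi (all cells), converged, n_outer.
    """
    base_synth = (synth_cfg or SynthConfig()).to_dict()
    base_fit = (fit_cfg or FitConfig()).to_dict()
    rows = []
    for seed in seeds:
        seed = int(seed) % (2**31)
        data = simulate(SynthConfig(**{**base_synth, "seed": seed}))
        result = callr_fit(
            data.expression,
            labels=data.labels,
            cfg=FitConfig(**{**base_fit, "seed": seed}),
        )
        unlabeled = data.labels.unlabeled_indices()
        init_types = [data.labels.type_universe[c] for c in result.initial_codes]
        rows.append(
            {
                "seed": seed,
                "init_accuracy": accuracy(data.true_types, init_types, unlabeled),
                "callr_accuracy": accuracy(
                    data.true_types, result.predicted_types, unlabeled
                ),
                "ari": ari(data.true_types, result.predicted_types),
                "nmi": nmi(data.true_types, result.predicted_types),
                "converged": result.converged,
                "n_outer": result.n_outer,
            }
        )
    return pd.DataFrame(rows)


def mu_robustness(
    mu_values=(0.1, 0.3, 1.0),
    seeds=range(3),
    synth_cfg: SynthConfig | None = None,
) -> pd.DataFrame:
    """Mean benchmark accuracy for each label/graph trade-off value mu."""
    base_synth = (synth_cfg or SynthConfig()).to_dict()
    rows = []
    for mu in mu_values:
        accs = []
        for seed in seeds:
            seed = int(seed) % (2**31)
            data = simulate(SynthConfig(**{**base_synth, "seed": seed}))
            result = callr_fit(
                data.expression, labels=data.labels, cfg=FitConfig(seed=seed, mu=mu)
            )
            accs.append(
                accuracy(
                    data.true_types,
                    result.predicted_types,
                    data.labels.unlabeled_indices(),
                )
            )
        rows.append(
            {"mu": mu, "mean_accuracy": float(np.mean(accs)), "n_seeds": len(accs)}
        )
    return pd.DataFrame(rows)
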