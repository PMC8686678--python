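import logging
import warnings

import numpy as np
import pytest

from callr import ExpressionMatrix, FitConfig, SynthConfig, simulate

# Solver non-convergence warnings are expected at loose tolerances and are
# logged by the package itself; keep test output readable.
logging.getLogger("callr").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", message=".*ConvergenceWarning.*")


@pytest.fixture(scope="session")
def small_synth():
    """A small, well-separated synthetic dataset shared across tests."""
    return simulate(
        SynthConfig(
            n_cells=120,
            m_genes=60,
            k_types=3,
            markers_per_type=6,
            log_fold_change=2.0,
            labeled_ratio=0.1,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def bench_cfg():
    """The benchmark generator conditions (4 types, 600 cells, 200 genes)."""
    return SynthConfig(seed=0)


@pytest.fixture()
def fast_fit_cfg():
    return FitConfig(seed=0)


@pytest.fixture()
def tiny_expr():
    values = np.array([[5.0, 0.0], [0.0, 3.0], [1.0, 2.0]])
    return ExpressionMatrix(
        values=values, gene_ids=["g1", "g2", "g3"], cell_ids=["c1", "c2"]
    )


def random_expression(rng, m=20, n=10):
    values = rng.poisson(3.0, size=(m, n)).astype(float)
    values[0] += 1.0  # avoid an all-zero first gene
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(m)],
        cell_ids=[f"c{j}" for j in range(n)],
    )
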