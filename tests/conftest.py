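"""Shared fixtures: small hand-checkable objects and the benchmark scenario.

The expensive baseline benchmark (1,652-gene panel, 17 cell types, 200
samples) is session-scoped so the deconvolution acceptance checks and the
shrinkage/robustness property tests all reuse one simulation.
"""

import numpy as np
import pandas as pd
import pytest

from ebdeconv import ReferencePanel, BulkMatrix
from ebdeconv.benchmark import baseline_benchmark

BENCH_SEED = 20250930


@pytest.fixture
def small_panel() -> ReferencePanel:
    """4 genes x 2 cell types with distinct signatures."""
    return ReferencePanel(
        pd.DataFrame(
            {"neuron": [5.0, 1.0, 0.5, 2.0], "glia": [0.5, 4.0, 3.0, 1.0]},
            index=["g1", "g2", "g3", "g4"],
        )
    )


@pytest.fixture
def random_panel() -> ReferencePanel:
    """50 genes x 3 cell types, well-conditioned, reproducible."""
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.lognormal(0, 1, size=(50, 3)),
        index=[f"g{i}" for i in range(50)],
        columns=["A", "B", "C"],
    )
    return ReferencePanel(data)


@pytest.fixture
def mixture_bulk(random_panel) -> tuple[BulkMatrix, np.ndarray]:
    """Noiseless mixtures of random_panel columns; returns (bulk, true W)."""
    rng = np.random.default_rng(11)
    w = rng.dirichlet(np.ones(3), size=10)
    values = random_panel.values @ w.T
    bulk = BulkMatrix(
        pd.DataFrame(values, index=random_panel.gene_ids,
                     columns=[f"s{i}" for i in range(10)])
    )
    return bulk, w


@pytest.fixture(scope="session")
def bench_seed() -> int:
    return BENCH_SEED


@pytest.fixture(scope="session")
def baseline():
    """The headline artificial-bulk scenario, estimated and scored."""
    return baseline_benchmark(BENCH_SEED)
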