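import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import agep
from agep.synthetic import benchmark_spec, generate_reference

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def benchmark():
    """The shipped synthetic benchmark: matrix, ground truth, built model."""
    matrix, truth = generate_reference(benchmark_spec(1))
    model = agep.build_reference(matrix)
    return matrix, truth, model


@pytest.fixture(scope="session")
def benchmark_loocv(benchmark):
    """LOOCV report for the shipped benchmark (computed once per session)."""
    matrix, _, _ = benchmark
    return agep.loocv(matrix)


@pytest.fixture(scope="session")
def small_matrix():
    """Tiny separable reference: 3 tissues x 8 samples x 12 genes."""
    rng = np.random.default_rng(42)
    tissues = ["brain", "liver", "muscle"]
    genes = [f"g{i}" for i in range(12)]
    cols, labels = [], {}
    blocks = []
    for ti, t in enumerate(tissues):
        for j in range(8):
            sid = f"{t}{j}"
            cols.append(sid)
            labels[sid] = t
        # genes 4*ti .. 4*ti+3 are shifted up in tissue ti
        mean = np.full(12, 100.0)
        mean[4 * ti : 4 * ti + 4] = 400.0
        blocks.append(rng.normal(mean[:, None], 15.0, size=(12, 8)))
    values = np.clip(np.concatenate(blocks, axis=1), 0, None)
    return agep.ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=cols),
        pd.Series(labels, name="tissue"),
    )


@pytest.fixture(scope="session")
def small_model(small_matrix):
    return agep.build_reference(small_matrix)
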