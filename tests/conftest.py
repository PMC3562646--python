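import numpy as np
import pytest

from metasig.io import ExpressionDataset


def make_dataset(values, n_normal, n_tumor, name="test", genes=None, missing=None):
    """Small ExpressionDataset builder used across the suite."""
    values = np.asarray(values, dtype=float)
    G, S = values.shape
    assert S == n_normal + n_tumor
    genes = genes or [f"g{i}" for i in range(1, G + 1)]
    samples = [f"n{i}" for i in range(1, n_normal + 1)] + [
        f"t{i}" for i in range(1, n_tumor + 1)
    ]
    labels = {s: ("normal" if s.startswith("n") else "tumor") for s in samples}
    if missing is None:
        missing = np.isnan(values)
    return ExpressionDataset(
        name=name, genes=genes, samples=samples, values=values,
        missing_mask=np.asarray(missing, dtype=bool), labels=labels,
    )


@pytest.fixture
def tiny_dataset():
    """3 genes x 4 samples, 2 normal / 2 tumor, no missing values."""
    return make_dataset(
        [[1.0, 2.0, 8.0, 9.0], [5.0, 5.1, 4.9, 5.2], [0.0, 1.0, 2.0, 3.0]],
        n_normal=2, n_tumor=2,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20251002)
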