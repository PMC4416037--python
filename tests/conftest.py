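import numpy as np
import pandas as pd
import pytest

from vipselect.preprocess import FeatureTable
from vipselect.synthetic import SyntheticSpec, generate, planted_shifts
from vipselect.preprocess import log_center_scale


def make_table(values, labels, state="raw", sample_ids=None, names=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    names = names or [f"f{j}" for j in range(p)]
    meta = pd.DataFrame({"technique": ["unknown"] * p}, index=names)
    return FeatureTable(sample_ids, list(labels), values, meta, state)


@pytest.fixture
def small_raw_table():
    """3 samples x 2 features, positive abundances."""
    return make_table([[1.0, 2.0], [np.e, 5.0], [np.e**2, 9.0]], ["A", "A", "B"])


@pytest.fixture
def planted_table():
    """Scaled synthetic table with 10 planted features of 200 (2.5 SD)."""
    spec = SyntheticSpec(
        n_features=200, informative=planted_shifts(10, 2.5), seed=42
    )
    table, truth = generate(spec)
    return log_center_scale(table), truth


@pytest.fixture
def tiny_scaled_table():
    """Small scaled table (12 samples, 25 features, 3 classes, planted)."""
    spec = SyntheticSpec(
        n_features=25,
        class_names=("a", "b", "c"),
        samples_per_class=(4, 4, 4),
        informative={j: tuple(2.5 if k == j % 3 else 0.0 for k in range(3))
                     for j in range(4)},
        seed=7,
    )
    table, truth = generate(spec)
    return log_center_scale(table), truth
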