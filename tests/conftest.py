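import numpy as np
import pytest

import cpannet as cp
from cpannet.preprocess import autoscale


@pytest.fixture(scope="session")
def small_dataset() -> cp.LabeledDescriptorTable:
    """Imbalanced three-class table with every descriptor kind present."""
    spec = cp.SyntheticSpec(
        n_per_class=(118, 48, 86), n_informative=8, n_noise=10, n_redundant=4,
        n_constant=3, separation=3.0, seed=11,
    )
    return cp.generate_dataset(spec)


@pytest.fixture(scope="session")
def separable_run(small_dataset):
    """A trained CP-ANN on well-separated data plus its split — shared by the
    classifier, domain and metrics integration tests."""
    table, _ = cp.filter_low_variance(small_dataset.table)
    table, _ = cp.filter_correlated(table)
    scaled, params = autoscale(table)
    split = cp.som_split(
        cp.LabeledDescriptorTable(scaled, small_dataset.labels),
        cp.SOMConfig(rows=10, cols=10, t_max=30, seed=5),
        (0.711, 0.136, 0.153),
    )
    model = cp.train_cpann(
        scaled.loc[split.tr], small_dataset.labels.loc[split.tr],
        cp.SOMConfig(rows=12, cols=12, t_max=100, a_max=0.6, a_min=0.001, seed=7),
        scaling=params,
    )
    return {
        "data": small_dataset, "table": table, "scaled": scaled, "params": params,
        "split": split, "model": model,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture()
def random_labels(rng):
    classes = np.asarray(cp.CLASS_NAMES)
    y_true = classes[rng.integers(0, 3, 200)]
    y_pred = classes[rng.integers(0, 3, 200)]
    return list(y_true), list(y_pred)
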