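import numpy as np
import pytest

from ploidyml.preprocess import PloidyDataset


@pytest.fixture()
def three_cluster_dataset() -> PloidyDataset:
    """Three tight, widely separated clusters, one per ploidy class.

    Inter-cluster distance (~20) dwarfs intra-cluster spread (~0.1), so any
    sane classifier reaches training accuracy 1.0 and LOO accuracy 1.0.
    """
    rng = np.random.default_rng(12345)
    centers = {"diploid": (0.0, 0.0), "mixoploid": (20.0, 0.0), "tetraploid": (10.0, 17.0)}
    X, y = [], []
    for label, c in centers.items():
        X.append(np.asarray(c) + 0.1 * rng.standard_normal((8, 2)))
        y.extend([label] * 8)
    return PloidyDataset(np.vstack(X), np.asarray(y, dtype=object))


@pytest.fixture()
def balanced_72_dataset() -> PloidyDataset:
    """Default-shaped 72-row balanced dataset from the simulator."""
    from ploidyml.synthetic import assemble_balanced_dataset, simulate_experiment

    records = simulate_experiment(seed=2024)
    return assemble_balanced_dataset(records, per_class=24, seed=2024)
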