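import numpy as np
import pytest

from fcselect.data import (FeatureDataset, SyntheticSpec, edge_index_for,
                           synthesize_dataset)


@pytest.fixture(scope="session")
def planted_cohort():
    """Default surrogate cohort: N=20 (q=190), 5 planted edges at 5-sigma."""
    ds, planted = synthesize_dataset(SyntheticSpec(seed=11))
    return ds, planted


@pytest.fixture()
def tiny_dataset():
    """N=3 (q=3) hand-sized dataset with one informative edge."""
    rng = np.random.default_rng(0)
    feats = rng.normal(0, 0.3, size=(20, 3))
    labels = np.array([0] * 10 + [1] * 10)
    feats[:10, 0] += 1.5
    return FeatureDataset(feats, labels, edge_index_for(3), 3)


def make_separable(n_per_class=30, k_signal=5, n_rois=5, delta=1.0, noise=0.4, seed=0):
    """Separable cohort whose SVM margin is tight enough that the weight
    vector has per-coordinate magnitudes of order 1 (used by the
    counterfactual sweeps)."""
    rng = np.random.default_rng(seed)
    q = n_rois * (n_rois - 1) // 2
    feats = rng.normal(0, noise, size=(2 * n_per_class, q))
    feats[:n_per_class, :k_signal] += delta
    labels = np.array([0] * n_per_class + [1] * n_per_class)
    return FeatureDataset(feats, labels, edge_index_for(n_rois), n_rois)
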