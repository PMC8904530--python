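import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import pvpstack as pv

#: Small single-point grids so tuned families fit once per fold in tests.
REDUCED_GRIDS = {
    "RF": {"n_estimators": [50]},
    "ET": {"n_estimators": [50]},
    "SVM": {"C": [1.0]},
    "LR": {"C": [1.0]},
    "MLP": {"hidden_layer_sizes": [(16,)], "max_iter": [150]},
    "XGB": {"n_estimators": [50], "max_depth": [3]},
}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_dataset():
    """40 separable synthetic records (delta 0.15) with synthetic profiles."""
    cfg = pv.SyntheticConfig(
        n_pos=20, n_neg=20, length_range=(30, 80), delta=0.15, seed=11
    )
    records = pv.generate_labeled_sequences(cfg)
    profiles = pv.generate_profiles(records, seed=11)
    return records, profiles


@pytest.fixture(scope="session")
def small_pool(small_dataset):
    """Reduced pool (3 descriptors x 10 algorithms) on the small dataset."""
    records, profiles = small_dataset
    labels = [r.label for r in records]
    feats = pv.encode_all(records, profiles, ["AAC", "CTDC", "PSSM_AAC"])
    pool = pv.train_pool(feats, labels, seed=11, folds=5, grids=REDUCED_GRIDS)
    return pool, feats, labels
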