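import numpy as np
import pytest

from nichesig import build_feature_matrix, default_config, default_index_table, generate_dataset


@pytest.fixture(scope="session")
def index_table():
    return default_index_table()


@pytest.fixture(scope="session")
def small_halo_dataset():
    """Desk-scale two-class halophilicity dataset: 8 organisms per class,
    60 proteins each, planted acidic-residue signal."""
    cfg = default_config("halophilicity", seed=11, proteins_per_organism=60, n_per_class=8)
    records, manifest, truth = generate_dataset(cfg)
    return records, manifest, truth


@pytest.fixture(scope="session")
def small_halo_features(small_halo_dataset, index_table):
    records, manifest, truth = small_halo_dataset
    return build_feature_matrix(records, index_table), manifest, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
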