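import numpy as np
import pytest

import ppgarr as pa
from ppgarr.io import dataset_to_arrays


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but class-complete synthetic dataset shared across tests."""
    cfg = pa.SimulationConfig(n_nsr_subjects=3, n_af_subjects=2,
                              n_pacpvc_subjects=2, segments_per_subject=4,
                              rng_seed=99)
    records, manifest = pa.generate_dataset(cfg)
    return cfg, records, manifest


@pytest.fixture(scope="session")
def small_arrays(small_dataset):
    _, records, _ = small_dataset
    dataset, rejected = dataset_to_arrays(records)
    assert not rejected
    return dataset
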