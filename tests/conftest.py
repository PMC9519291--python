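import numpy as np
import pytest

from cariesctx.synthetic import SyntheticConfig, generate_records


@pytest.fixture(scope="session")
def small_cohort():
    """12 pseudo-radiographs with defaults scaled down for unit tests."""
    cfg = SyntheticConfig(n_radiographs=12, crop_side_range=(32, 48), seed=11)
    records, label_maps = generate_records(cfg)
    return cfg, records, label_maps


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
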