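import logging

import pytest
from hypothesis import settings

from metoxkit import io, synthetic

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# the generator logs every protein without an eligible Met; keep test output quiet
logging.getLogger("metoxkit.synthetic").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size synthetic dataset at the default study conditions, seed 1."""
    config = synthetic.GeneratorConfig(seed=1)
    proteome, sites, pairs = synthetic.generate_dataset(config)
    return config, proteome, sites, pairs


@pytest.fixture(scope="session")
def default_groups(default_dataset):
    _, proteome, _, _ = default_dataset
    return io.split_groups(proteome)


@pytest.fixture(scope="session")
def small_null_dataset():
    """A small dataset with every planted effect switched off."""
    config = synthetic.null_config(
        n_ex_vivo=60, n_in_vitro=30, n_background=300,
        coreg_pair_count=800, seed=11,
    )
    proteome, sites, pairs = synthetic.generate_dataset(config)
    return config, proteome, sites, pairs
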