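import numpy as np
import pytest

from chromstage.hmm import decode_states, fit_common_model
from chromstage.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default 27-line synthetic study (24 normal + 3 cancer)."""
    return simulate_dataset(SimConfig(seed=0))


@pytest.fixture(scope="session")
def common_model(default_dataset):
    ds = default_dataset
    return fit_common_model(ds.gene_scores, ds.annotation, training_chrom="chr1", seed=0)


@pytest.fixture(scope="session")
def decoded_states(default_dataset, common_model):
    ds = default_dataset
    return decode_states(common_model, ds.gene_scores, ds.annotation)


@pytest.fixture(scope="session")
def normal_lines(default_dataset):
    meta = default_dataset.metadata
    return meta[meta["label"] != "C"]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def small_config(**kw):
    """A tiny SimConfig that fits planted structures into few genes."""
    defaults = dict(n_genes=200, n_chromosomes=2, domain_spec=[],
                    module_size=10, n_cancer_private=10, hotspot_fraction=0.2,
                    seed=0)
    defaults.update(kw)
    return SimConfig(**defaults)
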