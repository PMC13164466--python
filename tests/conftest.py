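import pytest

from cwqsar.optimizer import OptimizerConfig, optimize
from cwqsar.splitting import SplitSpec, random_split
from cwqsar.synthetic_data import GeneratorConfig, gen_smiles, generate_dataset


@pytest.fixture(scope="session")
def corpus():
    """300 generated SMILES strings covering branches, rings, stereo."""
    return gen_smiles(GeneratorConfig(n_compounds=300, seed=5))


@pytest.fixture(scope="session")
def small_dataset():
    """60 synthetic compounds with planted linear signal, noise sd 0.1."""
    return generate_dataset(GeneratorConfig(n_compounds=60, seed=42))


@pytest.fixture(scope="session")
def small_split(small_dataset):
    return random_split(small_dataset.ids, SplitSpec(seed=7))


@pytest.fixture(scope="session")
def trained_small(small_dataset, small_split):
    cfg = OptimizerConfig(tf_kind="cii", epochs_n=8, seed=3)
    return optimize(small_dataset, small_split, cfg)
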