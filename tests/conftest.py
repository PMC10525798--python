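import numpy as np
import pytest

from adverseg.critic import CriticConfig, build_critic
from adverseg.generator import GeneratorConfig, build_generator
from adverseg.phantom import PhantomSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """32×32 phantom spec for fast tests."""
    return PhantomSpec.default_for(32, 32)


@pytest.fixture
def default_spec():
    return PhantomSpec()


@pytest.fixture
def tiny_generator():
    cfg = GeneratorConfig(base_filters=4, depth=2, se_reduction=2)
    return build_generator(cfg, seed=0)


@pytest.fixture
def tiny_critic():
    cfg = CriticConfig(in_channels=5, base_filters=4, stages=2, input_side=32)
    return build_critic(cfg, seed=0)


@pytest.fixture
def tiny_dataset(tmp_path, small_spec):
    """12 phantoms at 32×32 with a manifest, written under tmp_path."""
    return generate_dataset(12, small_spec, jitter=0.1, seed=7, out_dir=str(tmp_path / "ds"))
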