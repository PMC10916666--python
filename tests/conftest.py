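import numpy as np
import pytest

from noch.generator import GeneratorConfig, ResnetGenerator
from noch.synthdata import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One 256-px phantom triplet, misregistration off."""
    return generate_phantom(PhantomParams(image_size=256, seed=7))


@pytest.fixture(scope="session")
def phantom_batch():
    """Four tiny phantoms across stages for training tests."""
    out = []
    for s, stage in enumerate(["normal", "IA", "IIC", "IIIC"]):
        out.append(generate_phantom(
            PhantomParams(image_size=96, seed=s, stage=stage)))
    return out


@pytest.fixture(scope="session")
def tiny_generator():
    return ResnetGenerator(GeneratorConfig(
        in_channels=3, base_width=8, n_res_blocks=2, seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
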