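import pytest

from hsigan import gan_core, synthetic_data as sd


@pytest.fixture(scope="session")
def tiny_params():
    """Small phantom geometry used throughout the unit tests."""
    return sd.PhantomParams(height=16, width=16, bands=16, seed=11)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_params):
    return sd.make_dataset(tiny_params, 8, 8)


@pytest.fixture
def tiny_gen_spec():
    return gan_core.GeneratorSpec(out_height=16, out_width=16, out_channels=9,
                                  base_channels=32)


@pytest.fixture
def tiny_disc_spec():
    return gan_core.DiscriminatorSpec(in_height=16, in_width=16, in_channels=9,
                                      base_channels=8)
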