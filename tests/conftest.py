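import numpy as np
import pytest

from agrinet import DeepAgriNet, FixtureSpec, NetworkConfig
from agrinet.synthetic_fixtures import generate_ds_like


def small_network_config(**overrides) -> NetworkConfig:
    """Reduced-width configuration used for fast functional tests; the
    architecture (stages, ASPP, CBAM, decoder wiring) is identical to the
    default, only widths and repeats shrink."""
    kwargs = dict(encoder_width_scale=0.5, stage_repeats=(2, 4),
                  aspp_out_channels=64, deep_refine_channels=64,
                  cbam_reduction=8, skip_reduce_channels_low=24,
                  skip_reduce_channels_mid=24, refine_channels_mid=48,
                  refine_channels_low=48, seed=1)
    kwargs.update(overrides)
    return NetworkConfig(**kwargs)


def smoke_fixture_spec(seed: int = 7) -> FixtureSpec:
    """Scene geometry scaled so 64 px tiles see several fields and roads."""
    return FixtureSpec(scene_hw=(320, 320), field_size_px=(48, 96),
                       road_width_px=3, seed=seed)


@pytest.fixture(scope="session")
def small_model():
    model = DeepAgriNet(small_network_config())
    model.eval()
    return model


@pytest.fixture(scope="session")
def tiny_dataset():
    """12 easy 64x64 tiles with a 7:3 manifest."""
    return generate_ds_like(smoke_fixture_spec(seed=11), 12, tile_size=64)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
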