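import numpy as np
import pytest

from malnut import synthetic


@pytest.fixture(scope="session")
def small_cfg():
    """Small but structurally complete generator configuration."""
    return synthetic.GenConfig(
        n_children_per_wave=800,
        n_districts=4,
        jp_district_ids={0, 1},
        raster_extent=(-9.5, -8.5, 124.0, 126.0),
        resolution_arcsec=600,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return synthetic.generate_bundle(small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
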