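import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20231108)


@pytest.fixture(scope="session")
def small_timelapse():
    """One 9-colony stack shared across imaging tests (expensive to render)."""
    from fitflow import simulate

    return simulate.gen_timelapse(
        n_colonies=9,
        image_shape=(1000, 1000),
        final_area_px=4000.0,
        seed=101,
    )
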