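import numpy as np
import pytest

import flimsort as fs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def table2_ranges():
    """BP-filter calibration windows for HDPE (3.52±0.21) and spruce (1.40±0.12)."""
    return [
        fs.material_range(fs.GaussianFit(3.52, 0.21, 1_000_000), name="HDPE"),
        fs.material_range(fs.GaussianFit(1.40, 0.12, 1_000_000), name="spruce"),
    ]


@pytest.fixture
def small_scene():
    """A 220x240 two-material chip scene on soil; fast enough for unit tests."""
    return fs.SceneSpec(
        shape=(220, 240),
        regions=[
            fs.Region("HDPE", origin=(20, 30), size=(60, 80)),
            fs.Region("spruce", origin=(120, 120), size=(70, 90)),
        ],
        magnification=2.0,
        seed=7,
    )


@pytest.fixture
def small_stack(small_scene):
    return fs.render_stack(small_scene)
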