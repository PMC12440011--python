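import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from organoidquant import SegmentationParams
from organoidquant.synthetic import ImageSpec, make_organoid_image

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def seg_params() -> SegmentationParams:
    # offset tuned to the generator's default intensities (foreground 100
    # over background 20, noise sd 10)
    return SegmentationParams(threshold_offset=60)


@pytest.fixture
def default_image():
    spec = ImageSpec(seed=42)
    return make_organoid_image(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
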