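import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from octfuse import (
    LabeledFeatureMatrix,
    MockExtractorSpec,
    SyntheticSpec,
    build_dataset,
    make_dataset,
    make_extractor,
)


@pytest.fixture(scope="session")
def small_images():
    """3-class synthetic dataset at the default study conditions."""
    return make_dataset(SyntheticSpec(n_classes=3, n_per_class=30, seed=1))


@pytest.fixture(scope="session")
def informative_extractor():
    return make_extractor(MockExtractorSpec(kind="informative", D=16, seed=0))


@pytest.fixture(scope="session")
def noise_extractor():
    return make_extractor(MockExtractorSpec(kind="noise", D=16, seed=0))


@pytest.fixture(scope="session")
def informative_matrix(small_images, informative_extractor):
    images, labels = small_images
    return build_dataset(informative_extractor, images, labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_matrix():
    """The hand-checkable single-feature four-instance two-class matrix."""
    return LabeledFeatureMatrix(
        X=np.array([[0.0], [0.1], [1.0], [0.9]]),
        y=np.array(["A", "A", "B", "B"]),
    )
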