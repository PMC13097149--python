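import numpy as np
import pytest

from lesionnet.classifier import train_classifier
from lesionnet.config import ClsTrainConfig, SegTrainConfig
from lesionnet.data import default_class_specs, derive_seed, generate_sample
from lesionnet.segmentation import train_segmenter


@pytest.fixture(scope="session")
def class_specs():
    return default_class_specs(3)


@pytest.fixture(scope="session")
def small_samples(class_specs):
    """72 synthetic samples (24 per class) at the working resolution."""
    return [
        generate_sample(class_specs[i % 3], 64, derive_seed(1234, i))
        for i in range(72)
    ]


@pytest.fixture(scope="session")
def trained_segmenter(small_samples):
    model, _ = train_segmenter(
        small_samples, SegTrainConfig.desk(epochs=3), seed=5)
    return model


@pytest.fixture(scope="session")
def trained_pipeline(small_samples, trained_segmenter):
    """A lightly trained full pipeline for behavioural (not accuracy) tests."""
    pipe, _ = train_classifier(
        small_samples, trained_segmenter,
        ClsTrainConfig.desk(epochs=4, patience=4), seed=6)
    return pipe
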