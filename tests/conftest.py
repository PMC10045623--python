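import logging

import numpy as np
import pytest

from roacnn import cnn, features, preprocess, synthetic

logging.getLogger("roacnn").setLevel(logging.ERROR)
logging.getLogger("roacnn.cnn").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def feature_clusters():
    """Four well-separated 14-dim Gaussian clusters, 50 items each."""
    rng = np.random.default_rng(0)
    centers = rng.normal(size=(4, 14)) * 5.0
    items = np.vstack([c + rng.normal(scale=0.3, size=(50, 14)) for c in centers])
    labels = np.repeat(np.arange(4), 50)
    return cnn.LabeledDataset(items, labels)


@pytest.fixture(scope="session")
def small_phantom_dataset():
    """Small synthetic phantom set shared across tests (25 images/class)."""
    return synthetic.generate_dataset(synthetic.SynthConfig(images_per_class=25, seed=1))


@pytest.fixture(scope="session")
def small_phantom_features(small_phantom_dataset):
    """Preprocessed feature table of the small phantom set."""
    vecs = []
    for img in small_phantom_dataset.items:
        im = preprocess.remove_impulse_noise(img.astype(np.uint8))
        im = preprocess.adaptive_hist_eq(im)
        vecs.append(features.extract_feature_vector(im).as_array())
    return cnn.LabeledDataset(np.asarray(vecs), small_phantom_dataset.labels)
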