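import numpy as np
import pytest

import cryextract as ce


@pytest.fixture(scope="session")
def training_clips():
    """Segmentation-derived labelled clips from synthetic scenes."""
    return ce.gen_training_segments(n_cry=40, n_per_other=20, seed=7)


@pytest.fixture(scope="session")
def training_matrix(training_clips):
    return ce.build_feature_matrix(training_clips)


@pytest.fixture(scope="session")
def trained_model(training_matrix):
    """A KNN cry detector tuned for precision on the synthetic corpus."""
    protocol = ce.TrainingProtocol(strategy="precision", seed=0)
    model, _ = ce.train_cry_model(training_matrix, "knn", protocol, final=True)
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
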