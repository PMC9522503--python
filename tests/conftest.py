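import numpy as np
import pytest

from sleepstager.simulate import default_markov_model, default_templates, generate_dataset

# Confusion matrices published for a single-channel EEG sleep-staging model
# (rows = expert label, columns = model output; order W, N1, N2, N3, REM).
# Used as fixed inputs for the metrics engine.
CONFUSION_SLEEP_EDF_2013 = np.array(
    [
        [7427, 426, 194, 18, 220],
        [358, 903, 748, 15, 780],
        [425, 220, 15531, 843, 780],
        [59, 1, 577, 5065, 1],
        [226, 230, 555, 4, 6702],
    ]
)

CONFUSION_SLEEP_EDF_2018 = np.array(
    [
        [62184, 4395, 885, 69, 1212],
        [3045, 8879, 6256, 128, 3214],
        [404, 4629, 57308, 3655, 3136],
        [13, 4, 2043, 10953, 26],
        [356, 2110, 2019, 136, 21214],
    ]
)

CONFUSION_CROSS_DATASET = np.array(
    [
        [7119, 498, 179, 17, 472],
        [216, 618, 755, 13, 1202],
        [39, 235, 15613, 999, 913],
        [21, 2, 490, 5173, 17],
        [36, 98, 953, 3, 6627],
    ]
)


@pytest.fixture(scope="session")
def markov_model():
    return default_markov_model()


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def small_dataset():
    """6 recordings x 60 epochs: enough structure for wiring tests."""
    return generate_dataset(n_recordings=6, epochs_per_recording=60, seed=7)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study-scale synthetic dataset: 20 recordings x 200 epochs."""
    return generate_dataset(n_recordings=20, epochs_per_recording=200, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
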