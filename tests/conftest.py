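import numpy as np
import pytest

from auda.synthetic import SyntheticConfig, trapezoid_profile
from auda.types import CANONICAL_AU_NAMES, N_AU


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def single_trapezoid():
    """Noiseless 4 s smile at 50 fps with ground-truth breakpoints."""
    return trapezoid_profile(
        fps=50.0, onset_s=1.0, apex_s=2.0, offset_s=1.0, lead_s=0.5, tail_s=0.5
    )


@pytest.fixture()
def smile_frame_data(rng):
    """Separable smile / non-smile AU frames.

    Smile frames sit near a prototype with high AU6/AU12 intensity;
    non-smile frames near a neutral baseline.
    """
    proto_smile = np.full(N_AU, 0.1)
    proto_smile[CANONICAL_AU_NAMES.index("AU06")] = 0.8
    proto_smile[CANONICAL_AU_NAMES.index("AU12")] = 0.9
    proto_neutral = np.full(N_AU, 0.1)
    n = 150
    smiles = np.clip(proto_smile + rng.normal(0, 0.05, size=(n, N_AU)), 0, 1)
    neutrals = np.clip(proto_neutral + rng.normal(0, 0.05, size=(n, N_AU)), 0, 1)
    frames = np.vstack([smiles, neutrals])
    labels = np.array([1] * n + [0] * n)
    return frames, labels, proto_smile, proto_neutral


@pytest.fixture(scope="session")
def small_dataset():
    """Seeded 40-sequence synthetic dataset shared across tests."""
    from auda.synthetic import generate_dataset

    cfg = SyntheticConfig(n_sequences=40)
    return generate_dataset(cfg, seed=7)


@pytest.fixture(scope="session")
def small_feature_data(small_dataset):
    from auda.pipeline import dataset_feature_sets

    sequences, labels, subjects = small_dataset
    feature_sets, fallback = dataset_feature_sets(sequences)
    return feature_sets, labels, subjects, fallback
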