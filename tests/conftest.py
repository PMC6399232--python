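import numpy as np
import pytest

import sleepstates as ss
from sleepstates.preprocess import preprocess_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """3 participants x 200 samples x 8 regions, 3 well-separated states."""
    spec = ss.default_spec(n_participants=3, n_samples=200, n_regions=8,
                           K_true=3, seed=1)
    return ss.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """PCA reduction + fitted 3-state model on the small cohort."""
    red = preprocess_cohort(small_cohort.data, n_components=6)
    model = ss.GaussianHMM(red.Y, red.participant_index, n_states=3)
    results = model.fit(n_init=2, seed=0)
    return small_cohort, red, model, results


@pytest.fixture
def toy_path_stages():
    """Hand-enumerable toy sequence: states (0-based) against two stages."""
    path = np.array([1, 1, 2, 2, 1, 1, 2, 2, 2, 2]) - 1
    stages = np.array(["W"] * 4 + ["N1"] * 6, dtype=object)
    return path, stages
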