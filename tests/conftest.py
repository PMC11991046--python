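import numpy as np
import pytest

from fallaug.config import RunConfig
from fallaug.preprocessing import windows_from_recordings
from fallaug.synthetic import SynthParams, generate_cohort, tiny_params


@pytest.fixture(scope="session")
def tiny_cohort():
    """8-subject scaled-down cohort used by the pipeline-level tests."""
    recs = generate_cohort(tiny_params(seed=1, n_subjects=8))
    return windows_from_recordings(recs, seed=1)


@pytest.fixture(scope="session")
def default_cohort():
    """Full 17-subject cohort at the default study conditions."""
    recs = generate_cohort(SynthParams(seed=0))
    return windows_from_recordings(recs, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def tiny_config():
    return RunConfig(seed=7).with_tiny_profile()
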