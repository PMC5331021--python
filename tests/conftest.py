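import numpy as np
import pandas as pd
import pytest

from actiphase.actigraphy_io import MinuteSeries


@pytest.fixture
def rng():
    return np.random.default_rng(2017)


@pytest.fixture
def make_series():
    """Factory for quick MinuteSeries construction."""

    def _make(counts, start="2017-01-02 12:00", subject_id="S001"):
        return MinuteSeries(subject_id, pd.Timestamp(start), np.asarray(counts, dtype=np.int64))

    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject synthetic cohort shared by the slower tests."""
    from actiphase.synthetic_cohort import GeneratorConfig, default_profiles, generate_cohort

    config = GeneratorConfig(n_subjects=12, seed=99, phase_profiles=default_profiles())
    return generate_cohort(config)
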