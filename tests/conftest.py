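import numpy as np
import pytest

from neuroload.pipeline import extract_subject, preprocess_subject
from neuroload.simulate import SubjectParams, simulate_subject
from neuroload.types import ProtocolSpec


@pytest.fixture(scope="session")
def short_spec():
    """One session per condition: 4 sessions, ~5 minutes of recording."""
    return ProtocolSpec(sessions_per_condition=1)


@pytest.fixture(scope="session")
def short_subject(short_spec):
    return simulate_subject(seed=7, params=SubjectParams(), spec=short_spec)


@pytest.fixture(scope="session")
def short_pre(short_subject):
    return preprocess_subject(short_subject.events, short_subject.eeg,
                              short_subject.fnirs)


@pytest.fixture(scope="session")
def short_table(short_pre):
    """Hybrid feature table of the short subject at 25 s windows."""
    return extract_subject(short_pre, window_len=25.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
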