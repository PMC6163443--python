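import numpy as np
import pytest

from gaitshift import RunConfig, SynthSubjectConfig, make_subject
from gaitshift.pipeline import segment_session
from gaitshift.segment import concat_sessions

SUBJECT_SEED = 11


@pytest.fixture(scope="session")
def default_subject():
    """One default synthetic subject (no intervention effect), generated once."""
    cfg = SynthSubjectConfig(seed=SUBJECT_SEED)
    sessions, koos, truth = make_subject(cfg)
    return cfg, sessions, koos, truth


@pytest.fixture(scope="session")
def segmented_subject(default_subject):
    """The default subject's cycle matrices and combined baseline matrix."""
    _, sessions, _, _ = default_subject
    cfg = RunConfig()
    matrices = {kind: segment_session(sessions[kind], cfg) for kind in sessions}
    baseline = concat_sessions(matrices["baseline1"], matrices["baseline2"])
    return matrices, baseline


@pytest.fixture
def rng():
    return np.random.default_rng(0)
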