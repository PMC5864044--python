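import numpy as np
import pytest

from tirisk.eam_processing import ParticipantSummary


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def worked_classification_set():
    """10 participants: 6 positives with probs {0.9 x4, 0.3 x2}, 4 negatives
    with probs {0.2 x3, 0.8 x1}.  At cut 0.5: sens 4/6, spec 3/4, acc 7/10."""
    probs = [0.9, 0.9, 0.9, 0.9, 0.3, 0.3, 0.2, 0.2, 0.2, 0.8]
    outcomes = [1, 1, 1, 1, 1, 1, 0, 0, 0, 0]
    return probs, outcomes


def make_summary(pid, adherence, interrupted, max_run=0):
    return ParticipantSummary(
        participant_id=pid,
        average_adherence=adherence,
        interrupted=interrupted,
        max_miss_run=max_run,
    )
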