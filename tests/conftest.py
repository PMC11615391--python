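import numpy as np
import pytest

from narrec.corpus_io import transcript_from_text
from narrec.synthetic_data import RecallBehaviorParams, gen_recalls, gen_story


@pytest.fixture(scope="session")
def story6():
    """Well-separated 6-event synthetic story."""
    return gen_story(n_events=6, words_per_event_range=(80, 120), topic_concentration=0.02, seed=11)


@pytest.fixture(scope="session")
def story6_transcript(story6):
    return transcript_from_text(story6.text(), "story6")


@pytest.fixture(scope="session")
def recalls6(story6):
    params = RecallBehaviorParams(p_recall=0.6, contiguity=0.7, p_first_is_first=0.5)
    return gen_recalls(story6, params, n_participants=40, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
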