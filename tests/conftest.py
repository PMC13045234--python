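import numpy as np
import pytest

from throatsense import io as tio
from throatsense import synthgen


@pytest.fixture(scope="session")
def mini_corpus():
    """2 subjects x 6 emotions x 5 sentences x 2 reps = 120 recordings."""
    recordings, manifest = synthgen.generate_corpus(
        n_subjects=2, reps_per_cell=2, master_seed=42
    )
    return recordings, manifest


@pytest.fixture(scope="session")
def mini_dataset(mini_corpus):
    recordings, manifest = mini_corpus
    return tio.build_feature_dataset(recordings, manifest), manifest


@pytest.fixture(scope="session")
def one_recording():
    profile = synthgen.make_emotion_profile("Neutral")
    sentence = synthgen.make_sentence_template(1)
    subject = synthgen.make_subject_model(0)
    return synthgen.synthesize_recording(profile, sentence, subject, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
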