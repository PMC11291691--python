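import numpy as np
import pytest

from qcla.semantic import SemanticSpace
from qcla.synthetic import SyntheticConfig, generate_study, records_to_frame


@pytest.fixture(scope="session")
def orthonormal_space():
    """Hand-built space with orthonormal word vectors for exact arithmetic."""
    words = ["calm", "happy", "sad", "worried", "content", "gloomy"]
    return SemanticSpace(
        vocabulary=words,
        vectors=np.eye(6),
        singular_values=np.linspace(6, 1, 6),
        k=6,
        word_frequency={w: i + 1 for i, w in enumerate(words)},
    )


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study shared across the slower tests."""
    cfg = SyntheticConfig(
        n_phase1=60,
        n_phase2=120,
        n_corpus_responses=1200,
        vocab_per_emotion=60,
        seed=7,
    )
    corpus, phase1, phase2 = generate_study(cfg)
    return cfg, corpus, records_to_frame(phase1, phase2)


@pytest.fixture(scope="session")
def small_space(small_study):
    from qcla.semantic import build_space_from_corpus

    _, corpus, _ = small_study
    return build_space_from_corpus(corpus, k=60)
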