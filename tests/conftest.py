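import warnings

import numpy as np
import pytest

from chordexpect import pipeline, synthetic
from chordexpect.bayes.model import ConvergenceWarning

# smoke-budget fits legitimately trip the strict R-hat threshold
warnings.simplefilter("ignore", ConvergenceWarning)


@pytest.fixture(scope="session")
def toy_sequences():
    """A 5-symbol, 30-event corpus for exhaustive PPM checks."""
    rng = np.random.default_rng(7)
    vocab = ["C:maj", "G:maj", "A:min", "F:maj", "D:min7"]
    return [[vocab[i] for i in rng.integers(0, 5, size=15)] for _ in range(2)], vocab


@pytest.fixture(scope="session")
def small_corpus():
    return synthetic.generate_corpus(
        synthetic.CorpusSpec(n_songs=14, vocabulary_size=8, seed=3))


@pytest.fixture(scope="session")
def study():
    """One full synthetic study (latent path, desk-scale corpus)."""
    return pipeline.run_synthetic_study(
        seed=11, render_sliders=False,
        corpus_spec=synthetic.CorpusSpec(n_songs=50, seed=11))


@pytest.fixture(scope="session")
def small_fit(study):
    """A smoke-budget additive fit on a 12-song subset, reused across tests."""
    from chordexpect import ExpectancyRegression
    from chordexpect.behavior import standardize

    songs = sorted(study.analysis["song_id"].unique())[:12]
    sub = study.analysis[study.analysis["song_id"].isin(songs)].copy()
    cols = ["rating", "ic", "entropy", "tonal_dissimilarity", "spectral_distance",
            "valence", "arousal", "musicianship"]
    sub, _ = standardize(sub, cols)
    model = ExpectancyRegression.from_preset(sub, "exp1_additive")
    return model.fit(chains=2, warmup=250, draws=250, seed=5)
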