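import numpy as np
import pandas as pd
import pytest

from chordexpect.behavior import extract_chord_rating
from chordexpect.synthetic import (CorpusSpec, HarmonicMarkovChain, RaterSpec,
                                   generate_corpus, generate_stimulus_set,
                                   render_slider_traces, simulate_covariates,
                                   simulate_ratings)


# ---------------------------------------------------------------- corpus

def test_corpus_honours_spec_and_seed():
    spec = CorpusSpec(n_songs=9, length_range=(5, 8), vocabulary_size=6, seed=4)
    corpus = generate_corpus(spec)
    assert len(corpus) == 9
    assert all(5 <= len(s) <= 8 for s in corpus.sequences)
    assert set(corpus.vocabulary) <= set(HarmonicMarkovChain.from_spec(spec).tokens)
    again = generate_corpus(spec)
    assert [s.tokens for s in again.sequences] == [s.tokens for s in corpus.sequences]


def test_empirical_transitions_match_chain():
    """Law of large numbers: ~1e5 events pin each transition cell to 0.02."""
    spec = CorpusSpec(n_songs=500, length_range=(200, 200), vocabulary_size=5,
                      transition_concentration=1.0, seed=5)
    chain = HarmonicMarkovChain.from_spec(spec)
    corpus = generate_corpus(spec)
    idx = {t: i for i, t in enumerate(chain.tokens)}
    counts = np.zeros((5, 5))
    for s in corpus.sequences:
        toks = [idx[t] for t in s.tokens]
        for a, b in zip(toks[:-1], toks[1:]):
            counts[a, b] += 1
    rows = counts.sum(axis=1, keepdims=True)
    emp = counts / np.where(rows == 0, 1, rows)
    assert np.max(np.abs(emp - chain.transition)) < 0.02


def test_high_concentration_approaches_uniform_usage():
    spec = CorpusSpec(n_songs=60, vocabulary_size=6,
                      transition_concentration=1e6, seed=6)
    corpus = generate_corpus(spec)
    chain = HarmonicMarkovChain.from_spec(spec)
    assert np.max(np.abs(chain.transition - 1 / 6)) < 0.01
    usage = pd.Series([t for s in corpus.sequences for t in s.tokens]).value_counts(
        normalize=True)
    assert usage.max() - usage.min() < 0.05


# ---------------------------------------------------------------- stimuli

def test_stimulus_set_constrained_total():
    chain = HarmonicMarkovChain.from_spec(CorpusSpec(seed=7))
    stims = generate_stimulus_set(chain, n=30, seed=7, total_chords=1039)
    lengths = [len(s) for s in stims]
    assert sum(lengths) == 1039
    assert all(30 <= L <= 38 for L in lengths)
    again = generate_stimulus_set(chain, n=30, seed=7, total_chords=1039)
    assert [s.tokens for s in again] == [s.tokens for s in stims]
    with pytest.raises(ValueError):
        generate_stimulus_set(chain, n=30, seed=7, total_chords=5000)


# ---------------------------------------------------------------- covariates

def test_covariates_independent_by_default():
    n = 10_000
    frame = pd.DataFrame({"song_id": np.repeat([f"s{i}" for i in range(100)], 100),
                          "position": np.tile(np.arange(1, 101), 100),
                          "tonal_dissimilarity": np.random.default_rng(1)
                          .standard_normal(n)})
    out = simulate_covariates(frame, seed=2)
    for col in ("dissonance", "spectral_centroid", "spectral_complexity"):
        assert abs(np.corrcoef(out[col], out["tonal_dissimilarity"])[0, 1]) < 0.05
        assert abs(out[col].mean()) < 0.05 and abs(out[col].std() - 1) < 0.05
    # valence/arousal constant within song (rated once per stimulus)
    assert (out.groupby("song_id")["valence"].nunique() == 1).all()
    again = simulate_covariates(frame, seed=2)
    pd.testing.assert_frame_equal(out, again)


def test_covariate_correlation_control():
    n = 10_000
    frame = pd.DataFrame({"song_id": ["s"] * n, "position": np.arange(1, n + 1),
                          "tonal_dissimilarity": np.random.default_rng(1)
                          .standard_normal(n)})
    out = simulate_covariates(frame, seed=3,
                              correlations={"dissonance": ("tonal_dissimilarity", 0.4)})
    got = np.corrcoef(out["dissonance"], out["tonal_dissimilarity"])[0, 1]
    assert got == pytest.approx(0.4, abs=0.05)


# ---------------------------------------------------------------- raters

def _predictors(n_songs=40, length=30, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_songs):
        for pos in range(1, length + 1):
            rows.append({"song_id": f"s{s:02d}", "position": pos})
    df = pd.DataFrame(rows)
    for col in ("ic", "entropy", "tonal_dissimilarity", "valence", "arousal"):
        x = rng.standard_normal(len(df))
        df[col] = (x - x.mean()) / x.std()
    return df


def test_null_betas_give_uncorrelated_white_ratings():
    spec = RaterSpec(betas={}, n_subjects=(1, 1), song_effect_scale=0.0,
                     ar1_rho=0.0, innovation_sd=1.0, seed=1)
    lat = simulate_ratings(_predictors(), spec)
    merged = lat.merge(_predictors(), on=["song_id", "position"])
    assert abs(np.corrcoef(merged["latent"], merged["ic"])[0, 1]) < 0.05
    x = merged["latent"].to_numpy()
    assert abs(np.corrcoef(x[:-1], x[1:])[0, 1]) < 0.05


def test_residual_lag1_autocorrelation_matches_rho():
    spec = RaterSpec(betas={}, n_subjects=(1, 0), song_effect_scale=0.0,
                     ar1_rho=0.45, innovation_sd=1.0, seed=2)
    preds = _predictors(n_songs=20, length=500)
    lat = simulate_ratings(preds, spec)
    acs = []
    for _, g in lat.groupby("song_id"):
        x = g["latent"].to_numpy()
        acs.append(np.corrcoef(x[:-1], x[1:])[0, 1])
    assert np.mean(acs) == pytest.approx(0.45, abs=0.05)


def test_beta_scaling_is_exact_under_shared_seed():
    preds = _predictors()
    base = dict(betas={("ic",): 0.3}, n_subjects=(1, 0), song_effect_scale=0.0,
                ar1_rho=0.2, innovation_sd=0.8, seed=3)
    r1 = simulate_ratings(preds, RaterSpec(**base))
    base["betas"] = {("ic",): 0.6}
    r2 = simulate_ratings(preds, RaterSpec(**base))
    merged = r1.merge(preds, on=["song_id", "position"])
    # same seed, same noise: the latent difference is exactly 0.3 * ic
    assert np.allclose(r2["latent"] - r1["latent"], 0.3 * merged["ic"], atol=1e-12)


def test_missing_predictor_raises():
    with pytest.raises(Exception, match="missing"):
        simulate_ratings(pd.DataFrame({"song_id": ["a"], "position": [1]}),
                         RaterSpec(seed=0))


# ---------------------------------------------------------------- slider rendering

def test_traces_start_at_zero_and_stay_in_range():
    preds = _predictors(n_songs=3, length=10)
    spec = RaterSpec(n_subjects=(1, 1), seed=4)
    lat = simulate_ratings(preds, spec)
    traces = render_slider_traces(lat, spec)
    assert len(traces) == 2 * 3
    for tr in traces:
        assert tr.value[0] == 0
        assert tr.value.min() >= 0 and tr.value.max() <= 1023


def test_zero_jitter_roundtrip_recovers_discretized_latents():
    preds = _predictors(n_songs=2, length=12)
    spec = RaterSpec(n_subjects=(1, 0), jitter_sd=0.0, seed=5)
    lat = simulate_ratings(preds, spec)
    traces = render_slider_traces(lat, spec)
    for tr in traces:
        g = lat[(lat["subject_id"] == tr.subject_id)
                & (lat["song_id"] == tr.song_id)].sort_values("position")
        targets = np.clip(np.round(spec.slider_center
                                   + spec.slider_gain * g["latent"].to_numpy()),
                          0, 1023).astype(int)
        onsets = (g["position"].to_numpy() - 1) * 2.4
        got = extract_chord_rating(tr, onsets, 2.4, delay=1.0)
        assert np.array_equal(got[1:], targets[1:])   # first chord discarded anyway
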