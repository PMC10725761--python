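"""End-to-end synthetic study assembly.

Glues the generator, the expectancy models and the behavioural pipeline
into one analysis-ready table: corpus -> stimuli -> symbolic + sensory
predictors -> simulated raters -> slider traces -> per-chord group-averaged
standardized ratings, merged with standardized predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior, sensory, symbolic, synthetic
from .chords import ChordSequence, Corpus

__all__ = ["StudyData", "build_predictors", "run_synthetic_study"]

PREDICTOR_COLS = ["ic", "entropy", "tonal_dissimilarity", "spectral_distance",
                  "valence", "arousal", "dissonance", "spectral_centroid",
                  "spectral_complexity"]


@dataclass
class StudyData:
    """Everything one synthetic study produces."""

    corpus: Corpus
    stimuli: list[ChordSequence]
    predictors: pd.DataFrame        # per-chord, standardized
    latents: pd.DataFrame           # per-subject latent ratings
    ratings: pd.DataFrame           # group-averaged standardized RatingTable
    analysis: pd.DataFrame          # ratings merged with predictors
    counts: dict = field(default_factory=dict)


def build_predictors(stimuli: list[ChordSequence], corpus: Corpus, seed: int,
                     symbolic_config: symbolic.SymbolicConfig | None = None,
                     pp_config: sensory.PPConfig | None = None) -> pd.DataFrame:
    """Per-chord expectancy predictors for held-out stimuli.

    Symbolic IC/entropy from an LTM trained on the corpus (stimuli are not
    part of it) plus the online STM; sensory columns from the
    periodicity-pitch memory model and spectral distance; acoustic and
    affect covariates simulated.  All predictor columns are standardized
    over the analysed rows (positions >= 2); first-chord rows, whose
    sensory predictors are undefined, are mean-imputed after scaling.
    """
    sym_cfg = symbolic_config or symbolic.SymbolicConfig(seed=seed)
    pp_cfg = pp_config or sensory.PPConfig()
    frame = symbolic.expectancy_for_sequences(stimuli, corpus, sym_cfg)
    frame = frame.rename(columns={"ic_bits": "ic", "entropy_bits": "entropy"})
    td, sd = [], []
    for seq in stimuli:
        td.append(sensory.pp_sequence(seq, config=pp_cfg))
        sd.append(sensory.sd_sequence(seq))
    frame["tonal_dissimilarity"] = np.concatenate(td)
    frame["spectral_distance"] = np.concatenate(sd)
    frame = synthetic.simulate_covariates(frame, seed=seed)
    scored = frame["position"] >= 2
    for col in PREDICTOR_COLS:
        x = frame.loc[scored, col].to_numpy(dtype=float)
        frame[col] = (frame[col] - x.mean()) / x.std(ddof=0)
    return frame.fillna({c: 0.0 for c in PREDICTOR_COLS})


def run_synthetic_study(corpus_spec: synthetic.CorpusSpec | None = None,
                        rater_spec: synthetic.RaterSpec | None = None,
                        seed: int = 0, n_stimuli: int = 30,
                        total_chords: int | None = 1039,
                        render_sliders: bool = True) -> StudyData:
    """Generate a full synthetic study and assemble the analysis table.

    With ``render_sliders`` the latent ratings go through the slider
    rendering + preprocessing chain (median filter, windowed mode, first
    chord discard, group averaging, standardization); otherwise the latents
    are averaged directly, which is faster and bypasses discretization.
    """
    cspec = corpus_spec or synthetic.CorpusSpec(seed=seed)
    rspec = rater_spec or synthetic.RaterSpec(seed=seed)
    corpus = synthetic.generate_corpus(cspec)
    chain = synthetic.HarmonicMarkovChain.from_spec(cspec)
    stimuli = synthetic.generate_stimulus_set(chain, n=n_stimuli,
                                              length_range=cspec.length_range,
                                              seed=seed, total_chords=total_chords)
    predictors = build_predictors(stimuli, corpus, seed=seed)
    latents = synthetic.simulate_ratings(predictors, rspec)

    if render_sliders:
        traces = synthetic.render_slider_traces(latents, rspec)
        onsets = {s.song_id: np.asarray(s.onsets) for s in stimuli}
        groups = latents.drop_duplicates("subject_id").set_index("subject_id")["group"]
        ratings, _ = behavior.preprocess_traces(
            traces, onsets, chord_duration=stimuli[0].chord_duration,
            group_of_subject=groups.to_dict(), window_delay=rspec.reaction_delay)
    else:
        tab = latents.rename(columns={"latent": "rating"})
        ratings = behavior.discard_first_and_average(tab)
        ratings, _ = behavior.standardize(ratings, ["rating"])

    analysis = ratings.merge(predictors.drop(columns=["token"]),
                             on=["song_id", "position"], how="left")
    mus = (analysis["group"] == "musician").astype(float)
    analysis["musicianship"] = (mus - mus.mean()) / mus.std(ddof=0)

    counts = {
        "n_stimuli": len(stimuli),
        "total_chords": int(sum(len(s) for s in stimuli)),
        "mean_length": float(np.mean([len(s) for s in stimuli])),
        "rating_rows": int(len(ratings)),
        "rating_rows_per_group": int(len(ratings) // ratings["group"].nunique()),
    }
    return StudyData(corpus, stimuli, predictors, latents, ratings, analysis, counts)
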