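"""Synthetic chord corpora, stimuli, covariates and simulated raters.

The generator mirrors the statistical structure the analysis assumes: a
skewed first-order Markov chord chain (so that information content has a
long right tail over a low-IC bulk), 30 stimulus progressions of 30--38
chords at 2.4 s per chord, and ratings built as standardized linear
combinations of expectancy predictors with song-level random effects, a
musician/non-musician slope difference, and AR(1) residual chains, rendered
to 0--1023 slider traces at 20 Hz.

Every operation is a pure function of its inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import DataError, SliderTrace
from .chords import ChordSequence, Corpus, parse_chord_label

__all__ = [
    "CorpusSpec",
    "RaterSpec",
    "HarmonicMarkovChain",
    "generate_corpus",
    "generate_stimulus_set",
    "simulate_covariates",
    "simulate_ratings",
    "render_slider_traces",
    "DEFAULT_BETAS",
]

_QUALITY_ORDER = ["maj", "min", "dom7", "maj7", "min7", "dim", "aug", "sus", "other"]
_NOTE_ORDER = ["C", "G", "F", "D", "A", "E", "B", "F#", "C#", "G#", "D#", "A#"]


@dataclass(frozen=True)
class CorpusSpec:
    """Generating conditions for a Billboard-like training corpus.

    ``transition_concentration`` is the per-cell Dirichlet parameter of the
    generating first-order chain: small values give sparse rows, hence the
    left-dominated IC density with a heavy right tail; as it grows the chain
    tends to uniform and the skew vanishes.
    """

    n_songs: int = 120
    length_range: tuple[int, int] = (30, 38)
    vocabulary_size: int = 24
    transition_concentration: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vocabulary_size < 2:
            raise ValueError("vocabulary_size must be >= 2")
        lo, hi = self.length_range
        if not (2 <= lo <= hi):
            raise ValueError("invalid length_range")


def _vocabulary(size: int) -> list[str]:
    toks = [f"{n}:{q}" for q in _QUALITY_ORDER for n in _NOTE_ORDER]
    if size > len(toks):
        raise ValueError(f"vocabulary_size capped at {len(toks)}")
    return toks[:size]


@dataclass
class HarmonicMarkovChain:
    """A first-order chord chain with chord-token states."""

    tokens: list[str]
    transition: np.ndarray
    initial: np.ndarray

    @classmethod
    def from_spec(cls, spec: CorpusSpec) -> "HarmonicMarkovChain":
        rng = np.random.default_rng([spec.seed, 11])
        v = spec.vocabulary_size
        alpha = np.full(v, spec.transition_concentration)
        transition = rng.dirichlet(alpha, size=v)
        initial = rng.dirichlet(np.full(v, 1.0))
        return cls(_vocabulary(v), transition, initial)

    def sample_tokens(self, length: int, rng: np.random.Generator) -> list[str]:
        v = len(self.tokens)
        states = np.empty(length, dtype=int)
        states[0] = rng.choice(v, p=self.initial)
        for i in range(1, length):
            states[i] = rng.choice(v, p=self.transition[states[i - 1]])
        return [self.tokens[s] for s in states]

    def sample_sequence(self, song_id: str, length: int,
                        rng: np.random.Generator) -> ChordSequence:
        chords = [parse_chord_label(t) for t in self.sample_tokens(length, rng)]
        return ChordSequence(song_id, chords)


def generate_corpus(spec: CorpusSpec) -> Corpus:
    """Sample a training corpus from the seeded chain; same seed, same corpus."""
    chain = HarmonicMarkovChain.from_spec(spec)
    rng = np.random.default_rng([spec.seed, 12])
    lo, hi = spec.length_range
    seqs = [chain.sample_sequence(f"song{i:04d}", int(rng.integers(lo, hi + 1)), rng)
            for i in range(spec.n_songs)]
    return Corpus(seqs)


def generate_stimulus_set(chain: HarmonicMarkovChain, n: int = 30,
                          length_range: tuple[int, int] = (30, 38),
                          seed: int = 0,
                          total_chords: int | None = None) -> list[ChordSequence]:
    """Sample stimulus progressions; optionally constrain the total length.

    With ``total_chords`` given, lengths are adjusted within the range until
    they sum exactly to the target (e.g. 30 progressions totalling 1039).
    """
    rng = np.random.default_rng([seed, 13])
    lo, hi = length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    if total_chords is not None:
        if not (n * lo <= total_chords <= n * hi):
            raise ValueError(f"total_chords {total_chords} unreachable with "
                             f"{n} lengths in [{lo}, {hi}]")
        while lengths.sum() != total_chords:
            i = int(rng.integers(n))
            step = 1 if lengths.sum() < total_chords else -1
            lengths[i] = np.clip(lengths[i] + step, lo, hi)
    return [chain.sample_sequence(f"stim{i:02d}", int(L), rng)
            for i, L in enumerate(lengths)]


def simulate_covariates(frame: pd.DataFrame, seed: int = 0,
                        correlations: dict[str, tuple[str, float]] | None = None
                        ) -> pd.DataFrame:
    """Add valence/arousal (per song) and per-chord acoustic covariates.

    Columns are unit Gaussians; ``correlations`` maps a new column to
    (existing column, rho) to induce a target correlation, e.g.
    ``{"dissonance": ("tonal_dissimilarity", 0.3)}``.  Defaults to
    independent covariates.
    """
    out = frame.copy()
    rng = np.random.default_rng([seed, 14])
    songs = out["song_id"].unique()
    for col in ("valence", "arousal"):
        per_song = dict(zip(songs, rng.standard_normal(len(songs))))
        out[col] = out["song_id"].map(per_song)
    n = len(out)
    for col in ("dissonance", "spectral_centroid", "spectral_complexity"):
        eps = rng.standard_normal(n)
        if correlations and col in correlations:
            target, rho = correlations[col]
            x = out[target].to_numpy(dtype=float)
            z = (x - np.nanmean(x)) / np.nanstd(x)
            z = np.where(np.isfinite(z), z, 0.0)
            out[col] = rho * z + np.sqrt(1 - rho ** 2) * eps
        else:
            out[col] = eps
    return out


#: Default standardized effect sizes; the musicianship column is the
#: standardized binary group code (+1 musician / -1 non-musician with equal
#: groups), so group-specific slopes are beta_main +/- beta_interaction.
DEFAULT_BETAS: dict[tuple[str, ...], float] = {
    ("musicianship",): -0.140,
    ("valence",): 0.029,
    ("arousal",): 0.177,
    ("ic",): 0.412,
    ("ic", "musicianship"): 0.107,
    ("tonal_dissimilarity",): 0.179,
    ("tonal_dissimilarity", "musicianship"): 0.009,
}


@dataclass
class RaterSpec:
    """Generative conditions for the simulated listeners.

    ``betas`` are on the standardized scale; ``innovation_sd`` is the
    AR(1) innovation scale of a *single subject's* residual chain (group
    averaging shrinks it by 1/sqrt(n_subjects) while preserving rho).
    Slider rendering: 20 Hz sampling, reaction delay before the knob moves,
    per-sample jitter in slider units.
    """

    betas: dict[tuple[str, ...], float] = field(
        default_factory=lambda: dict(DEFAULT_BETAS))
    n_subjects: tuple[int, int] = (13, 12)
    song_effect_scale: float = 0.1
    ar1_rho: float = 0.3
    innovation_sd: float = 2.5
    reaction_delay: float = 1.0
    jitter_sd: float = 2.0
    sample_rate: float = 20.0
    slider_center: float = 512.0
    slider_gain: float = 180.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1 < self.ar1_rho < 1):
            raise ValueError("ar1_rho must lie in (-1, 1)")
        if self.innovation_sd <= 0 or self.song_effect_scale < 0:
            raise ValueError("scales must be positive")
        self.betas = {((k,) if isinstance(k, str) else tuple(k)): float(v)
                      for k, v in self.betas.items()}


def _ar1_chain(n: int, rho: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd / np.sqrt(1 - rho ** 2))
    for i in range(1, n):
        e[i] = rho * e[i - 1] + rng.normal(0.0, sd)
    return e


def simulate_ratings(predictors: pd.DataFrame, spec: RaterSpec) -> pd.DataFrame:
    """Per-subject latent chord ratings from the generative regression.

    ``predictors`` has one row per (song_id, position) with standardized
    predictor columns.  Each subject contributes, per song, the shared
    linear predictor (population betas plus seeded song-level effects,
    musicianship coded +/-1 by group) plus an independent AR(1) residual
    chain.  Returns rows (subject_id, group, song_id, position, latent).
    """
    needed = {c for term in spec.betas for c in term if c != "musicianship"}
    missing = needed - set(predictors.columns)
    if missing:
        raise DataError(f"missing predictor columns: {sorted(missing)}")
    rng = np.random.default_rng([spec.seed, 15])
    pred = predictors.sort_values(["song_id", "position"], ignore_index=True)
    songs = list(pred["song_id"].unique())
    terms = [("intercept",)] + list(spec.betas)
    b_song = {s: {t: rng.normal(0.0, spec.song_effect_scale) for t in terms}
              for s in songs}

    def term_x(g: pd.DataFrame, term: tuple[str, ...], mcode: float) -> np.ndarray:
        x = np.ones(len(g))
        for c in term:
            if c == "intercept":
                continue
            x = x * (mcode if c == "musicianship" else g[c].to_numpy(dtype=float))
        return x

    rows = []
    subj_id = 0
    for gi, (gname, mcode) in enumerate([("musician", 1.0), ("non-musician", -1.0)]):
        for _ in range(spec.n_subjects[gi]):
            subj_id += 1
            sid = f"sub{subj_id:02d}"
            for s in songs:
                g = pred[pred["song_id"] == s]
                mu = np.zeros(len(g))
                for term in terms:
                    beta = spec.betas.get(term, 0.0) + b_song[s][term]
                    mu += beta * term_x(g, term, mcode)
                latent = mu + _ar1_chain(len(g), spec.ar1_rho, spec.innovation_sd, rng)
                rows.append(pd.DataFrame({
                    "subject_id": sid, "group": gname, "song_id": s,
                    "position": g["position"].to_numpy(), "latent": latent}))
    return pd.concat(rows, ignore_index=True)


def render_slider_traces(latents: pd.DataFrame, spec: RaterSpec,
                         chord_duration: float = 2.4) -> list[SliderTrace]:
    """Render latent per-chord ratings to 20 Hz slider traces.

    Each trace starts at 0 (the slider is reset before the trial); after
    each chord onset plus the reaction delay the knob jumps to the chord's
    target position (affine map of the latent value, clipped to 0--1023),
    holding until the next move, with optional per-sample jitter.
    """
    rng = np.random.default_rng([spec.seed, 16])
    dt = 1.0 / spec.sample_rate
    traces = []
    for (sid, song), g in latents.groupby(["subject_id", "song_id"], sort=True):
        g = g.sort_values("position")
        n_chords = len(g)
        t = np.arange(0.0, n_chords * chord_duration - dt / 2, dt)
        targets = spec.slider_center + spec.slider_gain * g["latent"].to_numpy()
        value = np.zeros(len(t))
        for i, target in enumerate(targets):
            start = i * chord_duration + spec.reaction_delay
            value[t >= start - 1e-9] = target
        if spec.jitter_sd > 0:
            value += rng.normal(0.0, spec.jitter_sd, size=len(t))
        value = np.clip(np.round(value), 0, 1023).astype(int)
        traces.append(SliderTrace(str(sid), str(song), t, value))
    return traces
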