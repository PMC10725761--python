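"""Cognitive expectancy: a variable-order Markov (PPM) chord model.

Two n-gram components are maintained: a long-term model (LTM) trained on a
corpus, and a short-term model (STM) trained online on the current song's
prefix.  Their predictive distributions are combined by a renormalized
geometric mean, and each chord receives an information content
(IC = -log2 p) and an entropy (expected IC over all continuations).

Order blending follows the escape-probability family of the PPM algorithm:
the reference configuration uses interpolated smoothing with escape method
"C" (Witten-Bell-style escape mass t/(n+t)) and no update exclusion, with a
uniform distribution over the training vocabulary as the order-(-1) floor.
The recursion starts at the longest context suffix that has been observed.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chords import ChordSequence, Corpus

__all__ = [
    "NgramStore",
    "PredictiveDistribution",
    "SymbolicConfig",
    "STMPredictor",
    "train_ltm",
    "ppm_predict",
    "combine_geometric",
    "information_content",
    "entropy",
    "sequence_expectancy",
    "cross_validated_expectancy",
    "bigram_variant",
]


@dataclass
class SymbolicConfig:
    """Configuration of the symbolic expectancy model.

    ``stm_max_order=None`` means unbounded: the STM context grows with the
    song prefix.  ``folds`` controls cross-validated corpus training.
    """

    ltm_max_order: int = 10
    stm_max_order: int | None = None
    escape_method: str = "c"
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ltm_max_order < 1:
            raise ValueError("ltm_max_order must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.escape_method not in ("a", "c"):
            raise ValueError("escape_method must be 'a' or 'c'")


class NgramStore:
    """Counts of (context, continuation) pairs for all orders 0..max_order."""

    def __init__(self, max_order: int):
        self.max_order = max_order
        self.counts: dict[tuple, dict[str, int]] = defaultdict(lambda: defaultdict(int))

    def add_event(self, history: list[str], token: str) -> None:
        """Record ``token`` after every context suffix of ``history``."""
        lo = max(0, len(history) - self.max_order)
        for j in range(lo, len(history) + 1):
            self.counts[tuple(history[j:])][token] += 1

    def add_sequence(self, tokens: list[str]) -> None:
        for i, tok in enumerate(tokens):
            self.add_event(tokens[:i], tok)

    def context_stats(self, context: tuple) -> tuple[dict[str, int], int, int]:
        """Return (continuation counts, total n, distinct types t)."""
        c = self.counts.get(context)
        if not c:
            return {}, 0, 0
        return c, sum(c.values()), len(c)


@dataclass
class PredictiveDistribution:
    """A strictly positive probability vector over an ordered vocabulary."""

    support: list[str]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if not np.all(p > 0):
            raise ValueError("predictive distribution must be strictly positive")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("predictive distribution must sum to 1")
        self.probabilities = p
        self._index = {s: i for i, s in enumerate(self.support)}

    def p(self, token: str) -> float:
        if token not in self._index:
            raise KeyError(f"token {token!r} outside support")
        return float(self.probabilities[self._index[token]])


def train_ltm(corpus: Corpus, config: SymbolicConfig) -> NgramStore:
    """Train the long-term model on every sequence of the corpus."""
    if len(corpus) == 0:
        raise ValueError("cannot train on an empty corpus")
    store = NgramStore(config.ltm_max_order)
    for seq in corpus.sequences:
        store.add_sequence(seq.tokens)
    return store


def _interp(store: NgramStore, context: tuple, vocab: list[str],
            escape: str) -> np.ndarray:
    """Interpolated escape recursion from ``context`` down to uniform."""
    if len(context) == 0:
        lower = np.full(len(vocab), 1.0 / len(vocab))
    else:
        lower = _interp(store, context[1:], vocab, escape)
    counts, n, t = store.context_stats(context)
    if n == 0:
        return lower
    vec = np.zeros(len(vocab))
    for i, s in enumerate(vocab):
        vec[i] = counts.get(s, 0)
    if escape == "c":
        esc = t / (n + t)
        vec = vec / (n + t)
    else:  # escape method "a"
        esc = 1.0 / (n + 1)
        vec = vec / (n + 1)
    return vec + esc * lower


def ppm_predict(store: NgramStore, context: tuple | list, vocabulary: list[str],
                escape_method: str = "c") -> PredictiveDistribution:
    """Predictive distribution over ``vocabulary`` given a context.

    The context is truncated to the store's max order; the recursion starts
    at the longest suffix that has been observed as a context.
    """
    if not vocabulary:
        raise ValueError("vocabulary must be non-empty")
    ctx = tuple(context)[max(0, len(context) - store.max_order):]
    while len(ctx) > 0 and store.context_stats(ctx)[1] == 0:
        ctx = ctx[1:]
    probs = _interp(store, ctx, list(vocabulary), escape_method)
    return PredictiveDistribution(list(vocabulary), probs / probs.sum())


class STMPredictor:
    """Online short-term model over the current song's prefix.

    ``predict_then_update`` returns the prediction for the next event
    *before* ingesting it; a fresh instance is used for every song.
    """

    def __init__(self, vocabulary: list[str], max_order: int | None = None,
                 escape_method: str = "c"):
        self.vocabulary = list(vocabulary)
        self.max_order = max_order
        self.escape_method = escape_method
        self.history: list[str] = []
        # unbounded order: grow the store's bound with the prefix
        self.store = NgramStore(10**9 if max_order is None else max_order)

    def predict_then_update(self, token: str) -> PredictiveDistribution:
        dist = ppm_predict(self.store, tuple(self.history), self.vocabulary,
                           self.escape_method)
        self.store.add_event(self.history, token)
        self.history.append(token)
        return dist


def combine_geometric(p_ltm: PredictiveDistribution,
                      p_stm: PredictiveDistribution) -> PredictiveDistribution:
    """Element-wise geometric mean of two distributions, renormalized."""
    if p_ltm.support != p_stm.support:
        raise ValueError("distributions must share the same support")
    g = np.sqrt(p_ltm.probabilities * p_stm.probabilities)
    return PredictiveDistribution(p_ltm.support, g / g.sum())


def information_content(dist: PredictiveDistribution, observed: str) -> float:
    """Surprise of the observed token: -log2 p, in bits."""
    return -float(np.log2(dist.p(observed)))


def entropy(dist: PredictiveDistribution) -> float:
    """Uncertainty of the prediction: -sum p log2 p, in bits."""
    p = dist.probabilities
    return float(-(p * np.log2(p)).sum())


def sequence_expectancy(seq: ChordSequence, ltm: NgramStore, vocabulary: list[str],
                        config: SymbolicConfig) -> pd.DataFrame:
    """Per-chord IC and entropy for one song under LTM (+ online STM)."""
    vocab = list(vocabulary)
    unseen = sorted(set(seq.tokens) - set(vocab))
    if unseen:
        warnings.warn(f"tokens {unseen} unseen in training; extending vocabulary")
        vocab = sorted(vocab + unseen)
    stm = STMPredictor(vocab, config.stm_max_order, config.escape_method)
    rows = []
    history: list[str] = []
    for i, tok in enumerate(seq.tokens):
        p_ltm = ppm_predict(ltm, tuple(history), vocab, config.escape_method)
        p_stm = stm.predict_then_update(tok)
        dist = combine_geometric(p_ltm, p_stm)
        rows.append({
            "song_id": seq.song_id, "position": i + 1, "token": tok,
            "ic_bits": information_content(dist, tok),
            "entropy_bits": entropy(dist),
        })
        history.append(tok)
    return pd.DataFrame(rows)


def expectancy_for_sequences(sequences: list[ChordSequence], training_corpus: Corpus,
                             config: SymbolicConfig) -> pd.DataFrame:
    """IC/entropy for held-out sequences, LTM trained on ``training_corpus``."""
    ltm = train_ltm(training_corpus, config)
    vocab = training_corpus.vocabulary
    return pd.concat([sequence_expectancy(s, ltm, vocab, config) for s in sequences],
                     ignore_index=True)


def cross_validated_expectancy(corpus: Corpus, config: SymbolicConfig) -> pd.DataFrame:
    """IC/entropy for every chord of every song, k-fold cross-validated.

    Songs are partitioned into ``config.folds`` folds by a seeded shuffle;
    each song is scored with an LTM trained on the other folds plus its own
    STM.  The fold assignment seed is recorded in ``DataFrame.attrs``.
    """
    n = len(corpus)
    if n < config.folds:
        raise ValueError(f"need at least {config.folds} songs, got {n}")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    folds = np.array_split(order, config.folds)
    frames = []
    for fold in folds:
        held = set(fold.tolist())
        train = Corpus([s for i, s in enumerate(corpus.sequences) if i not in held])
        ltm = train_ltm(train, config)
        vocab = train.vocabulary
        for i in sorted(held):
            frames.append(sequence_expectancy(corpus.sequences[i], ltm, vocab, config))
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["song_id", "position"], ignore_index=True)
    out.attrs["fold_seed"] = config.seed
    out.attrs["folds"] = config.folds
    return out


def bigram_variant(corpus: Corpus, config: SymbolicConfig | None = None) -> pd.DataFrame:
    """Cross-validated expectancy with context capped at a single chord."""
    base = config or SymbolicConfig()
    cfg = SymbolicConfig(ltm_max_order=1, stm_max_order=1,
                         escape_method=base.escape_method,
                         folds=base.folds, seed=base.seed)
    return cross_validated_expectancy(corpus, cfg)
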