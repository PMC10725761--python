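"""Chord symbols, sequences and corpora.

Chords are represented as a pitch-class root (0--11, C = 0) plus one of a
closed set of quality classes, serialized as Harte-style ``"root:quality"``
tokens.  Raw Harte annotations (as found in pop-chord corpora such as the
McGill Billboard transcriptions) carry a much richer quality grammar; here
every raw quality is reduced to one of nine classes so that the symbolic
vocabulary stays small and n-gram counts stay dense.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "ChordLabelError",
    "ChordSymbol",
    "ChordSequence",
    "Corpus",
    "VoicingPolicy",
    "NO_CHORD_TOKEN",
    "QUALITY_TEMPLATES",
    "parse_chord_label",
    "transpose_to_c",
    "chord_to_pitches",
    "read_corpus_csv",
    "write_corpus_csv",
]


class ChordLabelError(ValueError):
    """A chord label that cannot be parsed into the closed vocabulary."""


NOTE_TO_PC = {"C": 0, "D": 2, "E": 4, "F": 5, "G": 7, "A": 9, "B": 11}
PC_TO_NOTE = {0: "C", 1: "C#", 2: "D", 3: "D#", 4: "E", 5: "F",
              6: "F#", 7: "G", 8: "G#", 9: "A", 10: "A#", 11: "B"}

#: Interval templates (semitones above the root) for the nine quality classes.
#: "other" keeps only the root and fifth: the quality is unknown, the frame
#: tones are not.
QUALITY_TEMPLATES: dict[str, tuple[int, ...]] = {
    "maj": (0, 4, 7),
    "min": (0, 3, 7),
    "dom7": (0, 4, 7, 10),
    "maj7": (0, 4, 7, 11),
    "min7": (0, 3, 7, 10),
    "dim": (0, 3, 6),
    "aug": (0, 4, 8),
    "sus": (0, 5, 7),
    "other": (0, 7),
}

#: Reduction of raw Harte quality shorthands to the nine classes above.
HARTE_QUALITY_MAP: dict[str, str] = {
    "maj": "maj", "major": "maj", "": "maj",
    "min": "min", "minor": "min",
    "7": "dom7", "dom7": "dom7", "9": "dom7", "11": "dom7", "13": "dom7",
    "maj7": "maj7", "maj9": "maj7", "maj6": "maj7", "6": "maj7",
    "min7": "min7", "min9": "min7", "min6": "min7", "min11": "min7",
    "dim": "dim", "dim7": "dim", "hdim7": "dim", "hdim": "dim",
    "aug": "aug",
    "sus2": "sus", "sus4": "sus", "sus": "sus",
}

NO_CHORD_TOKEN = "N"

_LABEL_RE = re.compile(r"^([A-G])([#b]*)(?::([A-Za-z0-9]+))?$")


@dataclass(frozen=True)
class ChordSymbol:
    """A pitch-class root plus a quality class from the closed set."""

    root: int
    quality: str

    def __post_init__(self) -> None:
        if self.root not in range(12):
            raise ChordLabelError(f"root must be a pitch class 0..11, got {self.root!r}")
        if self.quality not in QUALITY_TEMPLATES:
            raise ChordLabelError(f"unknown quality {self.quality!r}")

    @property
    def token(self) -> str:
        return f"{PC_TO_NOTE[self.root]}:{self.quality}"

    @classmethod
    def from_token(cls, token: str) -> "ChordSymbol":
        return parse_chord_label(token)


def parse_chord_label(label: str) -> ChordSymbol | None:
    """Parse a Harte-style label into a :class:`ChordSymbol`.

    ``"N"`` (no-chord) returns ``None``; no-chord events are dropped before
    modelling.  Raw qualities are reduced via :data:`HARTE_QUALITY_MAP`;
    anything unrecognized but syntactically valid maps to ``"other"``.
    """
    label = label.strip()
    if label == NO_CHORD_TOKEN:
        return None
    m = _LABEL_RE.match(label)
    if not m:
        raise ChordLabelError(f"unparseable chord label {label!r}")
    note, accidentals, rawq = m.group(1), m.group(2), m.group(3) or ""
    pc = NOTE_TO_PC[note]
    for a in accidentals:
        pc += 1 if a == "#" else -1
    pc %= 12
    if rawq in QUALITY_TEMPLATES:
        quality = rawq
    elif rawq in HARTE_QUALITY_MAP:
        quality = HARTE_QUALITY_MAP[rawq]
    elif rawq and rawq[0].isalpha():
        quality = "other"
    else:
        raise ChordLabelError(f"unparseable chord quality in {label!r}")
    return ChordSymbol(pc, quality)


@dataclass
class ChordSequence:
    """One song's ordered chords with isochronous timing."""

    song_id: str
    chords: list[ChordSymbol]
    chord_duration: float = 2.4
    key_of_transcription: int = 0

    def __post_init__(self) -> None:
        if len(self.chords) < 2:
            raise ValueError(f"sequence {self.song_id!r} needs >= 2 chords")
        if self.chord_duration <= 0:
            raise ValueError("chord_duration must be positive")

    def __len__(self) -> int:
        return len(self.chords)

    @property
    def tokens(self) -> list[str]:
        return [c.token for c in self.chords]

    @property
    def onsets(self) -> list[float]:
        return [i * self.chord_duration for i in range(len(self.chords))]


@dataclass
class Corpus:
    """A collection of chord sequences plus the observed token vocabulary."""

    sequences: list[ChordSequence]

    @property
    def vocabulary(self) -> list[str]:
        """Sorted union of all tokens (deterministic support ordering)."""
        return sorted({t for s in self.sequences for t in s.tokens})

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class VoicingPolicy:
    """Deterministic symbolic voicing: which MIDI pitches realize a chord.

    The stimuli this emulates fixed their voicings in audio; symbolic
    models need an explicit, reproducible rule instead.
    """

    base_octave: int = 4
    arrangement: str = "root-position-closed"


def transpose_to_c(seq: ChordSequence, original_key: int | None = None) -> ChordSequence:
    """Shift every root by ``-original_key`` (mod 12), i.e. map the tonic to C."""
    key = seq.key_of_transcription if original_key is None else original_key
    if key not in range(12):
        raise ValueError(f"key must be a pitch class 0..11, got {key!r}")
    chords = [ChordSymbol((c.root - key) % 12, c.quality) for c in seq.chords]
    return replace(seq, chords=chords, key_of_transcription=0)


def chord_to_pitches(chord: ChordSymbol, policy: VoicingPolicy = VoicingPolicy()) -> set[int]:
    """Realize a chord as MIDI pitches, root-position closed voicing.

    The lowest pitch is the root in ``policy.base_octave`` (MIDI octave
    convention: C4 = 60); upper tones follow the quality template upwards.
    """
    if policy.arrangement != "root-position-closed":
        raise ValueError(f"unknown voicing arrangement {policy.arrangement!r}")
    base = 12 * (policy.base_octave + 1) + chord.root
    return {base + iv for iv in QUALITY_TEMPLATES[chord.quality]}


def read_corpus_csv(path) -> Corpus:
    """Read a corpus CSV (song_id, position, chord_label, key).

    Positions must be strictly increasing within each song.  No-chord rows
    are dropped; every sequence is transposed to C using its key column.
    """
    df = pd.read_csv(path, dtype={"song_id": str})
    required = {"song_id", "position", "chord_label", "key"}
    if not required.issubset(df.columns):
        raise ValueError(f"corpus CSV must have columns {sorted(required)}")
    sequences = []
    for song_id, g in df.groupby("song_id", sort=True):
        pos = g["position"].to_numpy()
        if not (pos[1:] > pos[:-1]).all():
            raise ValueError(f"positions not strictly increasing in song {song_id!r}")
        chords = [parse_chord_label(lbl) for lbl in g["chord_label"]]
        chords = [c for c in chords if c is not None]
        keys = g["key"].unique()
        if len(keys) != 1:
            raise ValueError(f"song {song_id!r} has inconsistent key annotations")
        seq = ChordSequence(str(song_id), chords, key_of_transcription=int(keys[0]))
        sequences.append(transpose_to_c(seq))
    return Corpus(sequences)


def write_corpus_csv(corpus: Corpus, path) -> None:
    rows = [
        {"song_id": s.song_id, "position": i + 1, "chord_label": c.token,
         "key": s.key_of_transcription}
        for s in corpus.sequences
        for i, c in enumerate(s.chords)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
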