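"""Sensory expectancy: spectral distance and the periodicity-pitch memory model.

Spectral distance (SD) renders each chord as a sum of weighted harmonic
overtones on a circular log-frequency (cents) pitch-class axis, applies
Gaussian smoothing for perceptual noise, and takes the cosine distance
between the smoothed spectra of adjacent chords.

The periodicity-pitch (PP) model keeps two leaky-integrated memory images
of the unfolding chord stream: a *global* image (slow decay, echoic-memory
context) and a *local* image (fast decay, the immediate chord).  Tonal
dissimilarity is the negated Fisher-z-transformed Pearson correlation
between the two images: large values mean the incoming chord mismatches its
context in auditory short-term memory.

The cochlear / inner-hair-cell / autocorrelation front end of the original
toolbox is deliberately replaced by an idealized periodicity image obtained
by subharmonic summation over the smoothed harmonic spectrum.  This keeps
the memory and contextuality mechanism while staying deterministic and
audio-free; see docs/methods.md for the consequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .chords import ChordSequence, ChordSymbol, VoicingPolicy, chord_to_pitches

__all__ = [
    "SpectralConfig",
    "PPConfig",
    "PitchImage",
    "harmonic_spectrum",
    "gaussian_smooth",
    "chord_spectrum",
    "spectral_distance",
    "periodicity_pitch_image",
    "leaky_integrate",
    "tonal_dissimilarity",
    "pp_sequence",
    "sd_sequence",
]


@dataclass(frozen=True)
class SpectralConfig:
    """Spectral representation: 12 overtones weighted i^-rolloff on a
    circular cents axis (1200 bins/octave), Gaussian-smoothed with
    sigma = 6.83 bins."""

    n_harmonics: int = 12
    rolloff_exponent: float = 0.75
    bins_per_octave: int = 1200
    smoothing_sigma: float = 6.83

    def __post_init__(self) -> None:
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")


@dataclass(frozen=True)
class PPConfig:
    """Periodicity-pitch memory parameters.

    Decay constants are in seconds; the grid explored is
    tau_global in {1.5, 2.5, 4.0} x tau_local in {0.1, 0.5}, with
    (4.0, 0.5) the selected pair.  ``subharmonic_decay`` is the classic
    per-subharmonic attenuation of subharmonic summation.
    """

    tau_global: float = 4.0
    tau_local: float = 0.5
    chord_duration: float = 2.4
    subharmonic_depth: int = 12
    subharmonic_decay: float = 0.84

    def __post_init__(self) -> None:
        if not (self.tau_global > self.tau_local > 0):
            raise ValueError("require tau_global > tau_local > 0")

    @classmethod
    def grid(cls) -> list["PPConfig"]:
        """The six (tau_global, tau_local) combinations explored."""
        return [cls(tau_global=g, tau_local=l)
                for g in (1.5, 2.5, 4.0) for l in (0.1, 0.5)]


@dataclass
class PitchImage:
    """A decaying memory vector over periodicity bins."""

    values: np.ndarray
    tau: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("pitch image must be finite and non-negative")
        self.values = v


def harmonic_spectrum(pitches: set[int], config: SpectralConfig = SpectralConfig()) -> np.ndarray:
    """Unsmoothed pitch-class spectrum of a set of MIDI pitches.

    For each chord tone and harmonic i = 1..n_harmonics, mass i^-rolloff is
    added at the harmonic's pitch-class bin (nearest bin on the cents grid).
    """
    if not pitches:
        raise ValueError("pitch set must be non-empty")
    bpo = config.bins_per_octave
    v = np.zeros(bpo)
    for p in pitches:
        for i in range(1, config.n_harmonics + 1):
            cents = (100.0 * p + 1200.0 * np.log2(i)) * bpo / 1200.0
            v[int(round(cents)) % bpo] += i ** (-config.rolloff_exponent)
    return v


def gaussian_smooth(v: np.ndarray, config: SpectralConfig = SpectralConfig()) -> np.ndarray:
    """Circular Gaussian smoothing; total mass is preserved."""
    return gaussian_filter1d(np.asarray(v, dtype=float), config.smoothing_sigma,
                             mode="wrap")


def chord_spectrum(chord: ChordSymbol, policy: VoicingPolicy = VoicingPolicy(),
                   config: SpectralConfig = SpectralConfig()) -> np.ndarray:
    """Smoothed spectral vector of a voiced chord."""
    return gaussian_smooth(harmonic_spectrum(chord_to_pitches(chord, policy), config),
                           config)


def spectral_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine distance in [0, 1]: 0 = identical direction, 1 = orthogonal."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("spectral distance undefined for a zero vector")
    return float(1.0 - (a @ b) / (na * nb))


def periodicity_pitch_image(pitches: set[int], config: PPConfig = PPConfig(),
                            spectral: SpectralConfig = SpectralConfig()) -> PitchImage:
    """Instantaneous periodicity image of a chord by subharmonic summation.

    Evidence for periodicity bin b sums the smoothed spectral energy at b's
    integer multiples (its harmonics, folded to the pitch-class axis),
    attenuated by ``subharmonic_decay ** (m - 1)`` for the m-th multiple.
    """
    spec = gaussian_smooth(harmonic_spectrum(pitches, spectral), spectral)
    bpo = spectral.bins_per_octave
    out = np.zeros(bpo)
    for m in range(1, config.subharmonic_depth + 1):
        shift = int(round(1200.0 * np.log2(m) * bpo / 1200.0)) % bpo
        out += config.subharmonic_decay ** (m - 1) * np.roll(spec, -shift)
    return PitchImage(out, tau=np.nan)


def leaky_integrate(previous: PitchImage, incoming: PitchImage, duration: float,
                    tau: float) -> PitchImage:
    """Exponential-decay memory update over ``duration`` seconds."""
    if previous.values.shape != incoming.values.shape:
        raise ValueError("pitch images must share the same bin layout")
    w = np.exp(-duration / tau)
    return PitchImage(w * previous.values + (1.0 - w) * incoming.values, tau=tau)


def tonal_dissimilarity(global_img: PitchImage, local_img: PitchImage) -> float:
    """Negated Fisher-z correlation between global and local images.

    The correlation is clamped to +/-(1 - 1e-6) so identical images give a
    large finite negative value (minimal dissimilarity).
    """
    g, l = global_img.values, local_img.values
    if g.std() == 0 or l.std() == 0:
        raise ValueError("tonal dissimilarity undefined for a zero-variance image")
    r = float(np.corrcoef(g, l)[0, 1])
    r = float(np.clip(r, -(1 - 1e-6), 1 - 1e-6))
    return float(-np.arctanh(r))


def pp_sequence(seq: ChordSequence, policy: VoicingPolicy = VoicingPolicy(),
                config: PPConfig = PPConfig(),
                spectral: SpectralConfig = SpectralConfig(),
                include_current_in_global: bool = False) -> np.ndarray:
    """Per-chord tonal dissimilarity along a progression (first chord NaN).

    Each chord's instantaneous image updates the local and global memories
    over the chord duration; by default the emitted value compares the
    current local image against the global image carried from the *end of
    the previous chord* (strict preceding context).
    """
    n_bins = spectral.bins_per_octave
    g = PitchImage(np.zeros(n_bins), config.tau_global)
    l = PitchImage(np.zeros(n_bins), config.tau_local)
    dur = seq.chord_duration
    out = np.full(len(seq), np.nan)
    for i, chord in enumerate(seq.chords):
        inst = periodicity_pitch_image(chord_to_pitches(chord, policy), config, spectral)
        l_new = leaky_integrate(l, inst, dur, config.tau_local)
        g_new = leaky_integrate(g, inst, dur, config.tau_global)
        if i > 0:
            context = g_new if include_current_in_global else g
            out[i] = tonal_dissimilarity(context, l_new)
        g, l = g_new, l_new
    return out


def sd_sequence(seq: ChordSequence, policy: VoicingPolicy = VoicingPolicy(),
                config: SpectralConfig = SpectralConfig()) -> np.ndarray:
    """Per-chord spectral distance to the preceding chord (first chord NaN)."""
    spectra = [chord_spectrum(c, policy, config) for c in seq.chords]
    out = np.full(len(seq), np.nan)
    for i in range(1, len(seq)):
        out[i] = spectral_distance(spectra[i - 1], spectra[i])
    return out
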