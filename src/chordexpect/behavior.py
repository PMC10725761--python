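"""Preprocessing of continuous slider traces into per-chord ratings.

The raw behavioural signal is a 20 Hz stream of slider positions discretized
to 0--1023.  The pipeline: five-sample symmetric median filter, per-chord
mode extraction in the window [onset + 1 s, next onset), discard of the
first chord of every song (the slider starts reset), averaging across
subjects within group, and standardization.  Stationarity of the per-song
series is assessed with an Augmented Dickey-Fuller test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import adfuller

__all__ = [
    "DataError",
    "SliderTrace",
    "median_filter",
    "extract_chord_rating",
    "discard_first_and_average",
    "standardize",
    "Standardization",
    "StationarityResult",
    "stationarity_check",
    "preprocess_traces",
]


class DataError(ValueError):
    """Input data violates a pipeline precondition."""


@dataclass
class SliderTrace:
    """One subject's slider samples for one song."""

    subject_id: str
    song_id: str
    t: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=int)
        if self.t.shape != self.value.shape:
            raise DataError("timestamps and values must align")
        if np.any(np.diff(self.t) <= 0):
            raise DataError("timestamps must be strictly increasing")
        if self.value.min(initial=0) < 0 or self.value.max(initial=0) > 1023:
            raise DataError("slider values must lie in [0, 1023]")


def median_filter(trace: SliderTrace, width: int = 5) -> SliderTrace:
    """Symmetric running median; windows shrink symmetrically at the edges."""
    if width % 2 != 1:
        raise ValueError("filter width must be odd")
    k = width // 2
    v = trace.value
    n = len(v)
    out = np.empty(n, dtype=int)
    if n > 2 * k:
        win = np.lib.stride_tricks.sliding_window_view(v, width)
        out[k:n - k] = np.median(win, axis=1)
    for i in range(min(k, n)):
        h = min(i, n - 1 - i, k)
        out[i] = int(np.median(v[i - h:i + h + 1]))
        j = n - 1 - i
        h = min(j, n - 1 - j, k)
        out[j] = int(np.median(v[j - h:j + h + 1]))
    return replace(trace, value=out)


def extract_chord_rating(trace: SliderTrace, onsets: np.ndarray,
                         chord_duration: float, delay: float = 1.0) -> np.ndarray:
    """Modal slider value per chord in [onset + delay, next onset).

    Ties are broken by the smallest value.  The last chord's window ends at
    onset + chord_duration.
    """
    onsets = np.asarray(onsets, dtype=float)
    if np.any(np.diff(onsets) <= 0):
        raise DataError("onsets must be strictly increasing")
    ends = np.append(onsets[1:], onsets[-1] + chord_duration)
    eps = 1e-9
    out = np.empty(len(onsets), dtype=int)
    for i, (a, b) in enumerate(zip(onsets + delay, ends)):
        w = trace.value[(trace.t >= a - eps) & (trace.t < b - eps)]
        if w.size == 0:
            raise DataError(
                f"empty rating window for chord {i + 1} of song {trace.song_id!r}")
        vals, counts = np.unique(w, return_counts=True)
        out[i] = int(vals[np.argmax(counts)])  # unique() sorts: smallest wins ties
    return out


def discard_first_and_average(ratings: pd.DataFrame) -> pd.DataFrame:
    """Group-average per-chord ratings, dropping each song's first chord.

    ``ratings`` has one row per (subject_id, song_id, position, group,
    rating).  The output has one row per (song_id, position, group) with the
    mean rating and the number of subjects averaged; row count equals
    (total chords - number of songs) x number of groups.
    """
    required = {"subject_id", "song_id", "position", "group", "rating"}
    if not required.issubset(ratings.columns):
        raise DataError(f"ratings need columns {sorted(required)}")
    firsts = ratings.groupby("song_id")["position"].transform("min")
    kept = ratings[ratings["position"] > firsts]
    counts = kept.groupby("group")["subject_id"].nunique()
    if (counts == 0).any() or counts.empty:
        raise DataError("every group needs at least one subject")
    out = (kept.groupby(["song_id", "position", "group"], as_index=False)
               .agg(rating=("rating", "mean"), n_subjects=("subject_id", "nunique")))
    return out.sort_values(["song_id", "position", "group"], ignore_index=True)


@dataclass(frozen=True)
class Standardization:
    """Recorded column means and standard deviations (for the inverse map)."""

    mean: dict[str, float]
    sd: dict[str, float]

    def inverse(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for c in self.mean:
            if c in out.columns:
                out[c] = out[c] * self.sd[c] + self.mean[c]
        return out


def standardize(df: pd.DataFrame, columns: list[str]) -> tuple[pd.DataFrame, Standardization]:
    """Center and scale the named columns to mean 0, sd 1."""
    out = df.copy()
    means, sds = {}, {}
    for c in columns:
        x = out[c].to_numpy(dtype=float)
        sd = float(x.std(ddof=0))
        if sd == 0:
            raise DataError(f"column {c!r} has zero variance")
        means[c], sds[c] = float(x.mean()), sd
        out[c] = (x - means[c]) / sd
    return out, Standardization(means, sds)


@dataclass(frozen=True)
class StationarityResult:
    statistic: float
    pvalue: float
    used_lag: int
    reject_unit_root: bool


def stationarity_check(series: np.ndarray, maxlag: int = 10,
                       alpha: float = 0.05) -> StationarityResult:
    """Augmented Dickey-Fuller test with drift; lag order by AIC up to 10.

    ``reject_unit_root=True`` indicates the series looks stationary, i.e.
    differencing is not required.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 10:
        raise DataError("series too short for a stationarity check")
    if x.std(ddof=0) == 0:
        raise DataError("constant series: stationarity check undefined")
    maxlag = min(maxlag, (len(x) - 1) // 2 - 2)
    stat, pvalue, used_lag, *_ = adfuller(x, maxlag=maxlag, regression="c",
                                          autolag="AIC")
    return StationarityResult(float(stat), float(pvalue), int(used_lag),
                              bool(pvalue < alpha))


def preprocess_traces(traces: list[SliderTrace], onsets_by_song: dict[str, np.ndarray],
                      chord_duration: float, group_of_subject: dict[str, str],
                      filter_width: int = 5, window_delay: float = 1.0,
                      standardize_output: bool = True
                      ) -> tuple[pd.DataFrame, Standardization | None]:
    """Full trace-to-RatingTable pipeline.

    Returns the group-averaged rating table (standardized over the whole
    table by default) and the recorded standardization.
    """
    rows = []
    for tr in traces:
        onsets = np.asarray(onsets_by_song[tr.song_id], dtype=float)
        filtered = median_filter(tr, filter_width)
        vals = extract_chord_rating(filtered, onsets, chord_duration, window_delay)
        for i, v in enumerate(vals):
            rows.append({"subject_id": tr.subject_id, "song_id": tr.song_id,
                         "position": i + 1,
                         "group": group_of_subject[tr.subject_id], "rating": v})
    table = discard_first_and_average(pd.DataFrame(rows))
    if not standardize_output:
        return table, None
    table, params = standardize(table, ["rating"])
    return table, params
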