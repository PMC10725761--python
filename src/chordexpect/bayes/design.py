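"""Regression specifications and design construction.

A term is a tuple of predictor column names; an interaction is the
element-wise product of its (standardized) parents.  Every term appears
both at the population level and as a song-level varying effect (standard
hierarchical centering: reported effects are the population-level means).
The varying intercept is always included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RegressionSpec", "RegressionData", "build_design", "PRESETS"]

Term = tuple[str, ...]

_EXP1_BASE: list[Term] = [("musicianship",), ("valence",), ("arousal",)]
_EXP2_BASE: list[Term] = [("valence",), ("arousal",), ("dissonance",),
                          ("spectral_centroid",), ("spectral_complexity",)]


def _exp1_single(pred: str) -> list[Term]:
    return _EXP1_BASE + [(pred,), (pred, "musicianship")]


_EXP1_ADDITIVE = _exp1_single("ic") + [("tonal_dissimilarity",),
                                       ("tonal_dissimilarity", "musicianship")]

#: Preset name -> list of slope terms (the varying intercept is implicit).
PRESETS: dict[str, list[Term]] = {
    "exp1_null": list(_EXP1_BASE),
    "exp1_additive": list(_EXP1_ADDITIVE),
    "exp1_supra": _EXP1_ADDITIVE + [("ic", "tonal_dissimilarity"),
                                    ("ic", "tonal_dissimilarity", "musicianship")],
    "exp2_idyom": _EXP2_BASE + [("ic",), ("entropy",), ("ic", "entropy")],
    "exp2_pp": _EXP2_BASE + [("tonal_dissimilarity",)],
    "exp2_additive": _EXP2_BASE + [("tonal_dissimilarity",), ("ic",), ("entropy",),
                                   ("ic", "entropy")],
}
PRESETS["exp2_supra"] = PRESETS["exp2_additive"] + [
    ("tonal_dissimilarity", "ic", "entropy"),
    ("tonal_dissimilarity", "ic"),
    ("tonal_dissimilarity", "entropy"),
]


@dataclass
class RegressionSpec:
    """Response, slope terms, and the AR(1) flag for one regression model."""

    response: str = "rating"
    terms: list[Term] = field(default_factory=list)
    ar1: bool = True
    preset: str | None = None

    @classmethod
    def from_preset(cls, name: str, predictor: str | None = None,
                    response: str = "rating") -> "RegressionSpec":
        """Expand a named preset; ``exp1_single`` needs ``predictor``."""
        if name == "exp1_single":
            if predictor is None:
                raise ValueError("exp1_single needs a predictor column name")
            terms = _exp1_single(predictor)
            name = f"exp1_single({predictor})"
        elif name in PRESETS:
            terms = list(PRESETS[name])
        else:
            raise ValueError(f"unknown preset {name!r}; "
                             f"choose from {sorted(PRESETS)} or 'exp1_single'")
        return cls(response=response, terms=terms, preset=name)

    @property
    def term_names(self) -> list[str]:
        return ["intercept"] + [" x ".join(t) for t in self.terms]


@dataclass
class RegressionData:
    """Model-ready arrays: shared design for population and song levels."""

    y: np.ndarray              # (N,) response
    X: np.ndarray              # (N, p) population design (intercept first)
    song_idx: np.ndarray       # (N,) int codes into song_ids
    series_idx: np.ndarray     # (N,) int codes of AR(1) chains
    is_start: np.ndarray       # (N,) bool, first row of each chain
    song_ids: list[str]
    term_names: list[str]
    table: pd.DataFrame

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_terms(self) -> int:
        return self.X.shape[1]


def _check_standardized(table: pd.DataFrame, col: str) -> None:
    x = table[col].to_numpy(dtype=float)
    if abs(x.mean()) > 1e-6 or abs(x.std(ddof=0) - 1.0) > 1e-3:
        raise ValueError(f"column {col!r} must be standardized before modelling")


def build_design(table: pd.DataFrame, spec: RegressionSpec) -> RegressionData:
    """Expand a merged rating/predictor table into model-ready arrays.

    The table needs one row per (song_id, position[, group]) with all parent
    columns standardized and no missing values.  Rows are sorted by AR(1)
    chain (song x group when a group column is present, else song) and
    position, which fixes the innovation ordering.
    """
    parents = sorted({c for t in spec.terms for c in t})
    missing = [c for c in parents + [spec.response, "song_id", "position"]
               if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    sort_keys = ["song_id"] + (["group"] if "group" in table.columns else []) + ["position"]
    tab = table.sort_values(sort_keys, ignore_index=True)
    used = parents + [spec.response]
    if tab[used].isna().any().any():
        raise ValueError("design table contains missing values")
    for c in parents + [spec.response]:
        _check_standardized(tab, c)

    cols = [np.ones(len(tab))]
    for t in spec.terms:
        x = np.ones(len(tab))
        for c in t:
            x = x * tab[c].to_numpy(dtype=float)
        cols.append(x)
    X = np.column_stack(cols)

    song_ids = list(pd.unique(tab["song_id"]))
    song_idx = tab["song_id"].map({s: i for i, s in enumerate(song_ids)}).to_numpy()
    if spec.ar1:
        chain_key = (tab["song_id"].astype(str)
                     + ("//" + tab["group"].astype(str) if "group" in tab.columns else ""))
    else:
        chain_key = pd.Series(np.arange(len(tab)).astype(str))  # every row its own chain
    codes, _ = pd.factorize(chain_key)
    is_start = np.ones(len(tab), dtype=bool)
    is_start[1:] = codes[1:] != codes[:-1]
    return RegressionData(
        y=tab[spec.response].to_numpy(dtype=float), X=X,
        song_idx=song_idx.astype(int), series_idx=codes.astype(int),
        is_start=is_start, song_ids=[str(s) for s in song_ids],
        term_names=spec.term_names, table=tab,
    )
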