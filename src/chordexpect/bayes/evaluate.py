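"""Predictive model evaluation: PSIS-LOO, model comparison, Bayesian stacking.

The expected log pointwise predictive density (ELPD) of each observation is
estimated by importance-sampling leave-one-out cross-validation with
Pareto-smoothed, truncated weights: for observation n and posterior draws
theta_s, elpd_n = log( sum_s w_ns p(y_n | theta_s) / sum_s w_ns ).  The
smoothing of the raw inverse-likelihood ratios (generalized-Pareto fit to
the largest 20% of weights, then truncation) is delegated to arviz's
``psislw``; observations with Pareto shape k > 0.7 are flagged.

Stacking finds simplex weights over candidate models maximizing the joint
log score of the combined leave-one-out predictive distribution; the
problem is convex and solved deterministically by SLSQP from the uniform
initial point (ties therefore return equal weights).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from arviz.stats import psislw
from scipy.optimize import minimize
from scipy.special import logsumexp

__all__ = ["ElpdResult", "StackingWeights", "psis_loo", "compare", "stacking"]


@dataclass
class ElpdResult:
    """PSIS-LOO estimate: pointwise contributions, total +/- SE, diagnostics."""

    pointwise: np.ndarray     # (N,) elpd_n
    elpd: float
    se: float
    pareto_k: np.ndarray      # (N,)
    n_obs: int

    @property
    def n_bad_k(self) -> int:
        return int(np.sum(self.pareto_k > 0.7))


def psis_loo(loglik: np.ndarray) -> ElpdResult:
    """PSIS-LOO from an (S_draws, N_obs) pointwise log-likelihood matrix."""
    ll = np.asarray(loglik, dtype=float)
    if not np.all(np.isfinite(ll)):
        bad = np.where(~np.isfinite(ll).all(axis=0))[0]
        raise FloatingPointError(f"non-finite log-likelihoods at observations {bad[:5]}")
    # arviz expects the sample axis last; returns normalized smoothed log weights
    lw, k = psislw(-ll.T)
    pointwise = logsumexp(lw + ll.T, axis=1)
    n = ll.shape[1]
    se = float(np.sqrt(n * np.var(pointwise)))
    return ElpdResult(pointwise=pointwise, elpd=float(pointwise.sum()), se=se,
                      pareto_k=np.asarray(k), n_obs=n)


def compare(results: dict[str, ElpdResult]) -> pd.DataFrame:
    """Rank models by ELPD; dELPD and dSE are versus the best model.

    dSE is sqrt(N * var(pointwise differences)), i.e. the paired standard
    error that accounts for shared observations.
    """
    names = list(results)
    ns = {r.n_obs for r in results.values()}
    if len(ns) != 1:
        raise ValueError("all models must score the same observations")
    n = ns.pop()
    best = max(names, key=lambda m: results[m].elpd)
    rows = []
    for m in names:
        diff = results[best].pointwise - results[m].pointwise
        rows.append({"model": m, "elpd": results[m].elpd, "se": results[m].se,
                     "delpd": results[best].elpd - results[m].elpd,
                     "dse": float(np.sqrt(n * np.var(diff))),
                     "bad_pareto_k": results[m].n_bad_k})
    return (pd.DataFrame(rows).sort_values("elpd", ascending=False, ignore_index=True)
            .set_index("model"))


@dataclass
class StackingWeights:
    """Simplex weights over candidate models and the achieved log score."""

    models: list[str]
    weights: np.ndarray
    log_score: float
    degenerate: bool = False   # all candidates identical: uniform returned

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.models, name="weight")


def stacking(pointwise: dict[str, np.ndarray]) -> StackingWeights:
    """Bayesian stacking of predictive distributions.

    ``pointwise`` maps model name to its (N,) pointwise log predictive
    densities (typically ``ElpdResult.pointwise``).  Maximizes
    sum_n log sum_k w_k exp(lpd_nk) over the simplex.
    """
    if len(pointwise) < 2:
        raise ValueError("stacking needs at least two models")
    names = list(pointwise)
    L = np.column_stack([np.asarray(pointwise[m], float) for m in names])  # (N, K)
    if L.ndim != 2 or len({v.shape for v in map(np.asarray, pointwise.values())}) != 1:
        raise ValueError("pointwise densities must share one shape")
    n, K = L.shape
    if np.allclose(L, L[:, [0]]):
        return StackingWeights(names, np.full(K, 1.0 / K),
                               float(logsumexp(L[:, 0] + np.log(1.0))), degenerate=True)
    ref = L.max(axis=1, keepdims=True)
    E = np.exp(L - ref)   # (N, K), scaled densities

    def neg_score(w: np.ndarray) -> tuple[float, np.ndarray]:
        mix = E @ w
        grad = -(E / mix[:, None]).sum(axis=0)
        return -float(np.sum(np.log(mix) + ref[:, 0])), grad

    res = minimize(neg_score, np.full(K, 1.0 / K), jac=True, method="SLSQP",
                   bounds=[(0.0, 1.0)] * K,
                   constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                                 "jac": lambda w: np.ones(K)}],
                   options={"maxiter": 500, "ftol": 1e-12})
    w = np.clip(res.x, 0.0, None)
    w = w / w.sum()
    return StackingWeights(names, w, -float(neg_score(w)[0]))
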