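"""Statsmodels-style model and results objects for the multilevel AR(1)
regression of chord ratings on expectancy simulations."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .design import RegressionData, RegressionSpec, build_design
from .evaluate import ElpdResult, psis_loo
from .sampler import SamplerConfig, gibbs_sample, pointwise_loglik

__all__ = ["ExpectancyRegression", "ExpectancyRegressionResults", "ConvergenceWarning"]


class ConvergenceWarning(UserWarning):
    """Raised when split R-hat exceeds the convergence threshold."""


class ExpectancyRegression:
    """Bayesian multilevel linear model with song-level varying effects and
    AR(1) residuals.

    Parameters
    ----------
    data : DataFrame
        One row per (song_id, position[, group]) with a standardized
        response and standardized predictor columns.
    spec : RegressionSpec
        Terms and response; usually built via ``RegressionSpec.from_preset``.

    Examples
    --------
    >>> model = ExpectancyRegression.from_preset(table, "exp1_additive")
    >>> res = model.fit(chains=2, warmup=500, draws=500, seed=1)
    >>> res.summary()
    """

    def __init__(self, data: pd.DataFrame, spec: RegressionSpec):
        self.spec = spec
        self.data = build_design(data, spec)

    @classmethod
    def from_preset(cls, data: pd.DataFrame, preset: str,
                    predictor: str | None = None) -> "ExpectancyRegression":
        return cls(data, RegressionSpec.from_preset(preset, predictor))

    def fit(self, chains: int = 4, warmup: int = 2500, draws: int = 2500,
            seed: int = 0, rhat_threshold: float = 1.01,
            mh_substeps: int = 2) -> "ExpectancyRegressionResults":
        config = SamplerConfig(chains=chains, warmup=warmup, draws=draws,
                               mh_substeps=mh_substeps)
        posterior = gibbs_sample(self.data, config, seed=seed)
        return ExpectancyRegressionResults(self, posterior, config, seed,
                                           rhat_threshold)


class ExpectancyRegressionResults:
    """Posterior draws, diagnostics and predictive evaluation of a fit."""

    def __init__(self, model: ExpectancyRegression, posterior: dict[str, np.ndarray],
                 config: SamplerConfig, seed: int, rhat_threshold: float = 1.01):
        self.model = model
        self.spec = model.spec
        self.data: RegressionData = model.data
        self.posterior = posterior
        self.config = config
        self.seed = seed
        self._loglik: np.ndarray | None = None
        self.diagnostics = self._diagnose()
        worst = self.diagnostics["rhat"].max()
        if worst >= rhat_threshold:
            warnings.warn(
                f"max split R-hat {worst:.3f} >= {rhat_threshold}: chains may "
                f"not have converged; inspect .diagnostics",
                ConvergenceWarning, stacklevel=2)

    # ----- diagnostics and summaries -------------------------------------

    def _scalar_draws(self) -> dict[str, np.ndarray]:
        """Reported parameters as (chain, draw) arrays."""
        named = {}
        for j, name in enumerate(self.data.term_names):
            named[f"beta[{name}]"] = self.posterior["beta"][..., j]
            named[f"tau[{name}]"] = self.posterior["tau"][..., j]
        named["rho"] = self.posterior["rho"]
        named["sigma"] = self.posterior["sigma"]
        return named

    def _diagnose(self) -> pd.DataFrame:
        rows = []
        for name, d in self._scalar_draws().items():
            ds = az.convert_to_dataset(d)
            rows.append({
                "parameter": name,
                "rhat": float(az.rhat(ds)["x"].values.item()),
                "ess_bulk": float(az.ess(ds)["x"].values.item()),
            })
        return pd.DataFrame(rows).set_index("parameter")

    def summary(self, credible_mass: float = 0.95) -> pd.DataFrame:
        """Posterior mean, sd and central credible interval per parameter."""
        lo = 100 * (1 - credible_mass) / 2
        rows = []
        for name, d in self._scalar_draws().items():
            flat = d.reshape(-1)
            rows.append({
                "parameter": name, "mean": flat.mean(), "sd": flat.std(ddof=1),
                f"{lo:g}%": np.percentile(flat, lo),
                f"{100 - lo:g}%": np.percentile(flat, 100 - lo),
                "rhat": self.diagnostics.loc[name, "rhat"],
                "ess_bulk": self.diagnostics.loc[name, "ess_bulk"],
            })
        return pd.DataFrame(rows).set_index("parameter")

    def coefficient_draws(self, term: str) -> np.ndarray:
        """Flattened posterior draws of one population-level coefficient."""
        j = self.data.term_names.index(term)
        return self.posterior["beta"][..., j].reshape(-1)

    def group_slopes(self, predictor: str) -> pd.DataFrame:
        """Musician / non-musician slopes of a predictor, computed draw-wise.

        Requires terms ``predictor`` and ``predictor x musicianship`` and a
        group column in the source table; the group-specific slope is
        beta_pred + beta_interaction * (group's standardized musicianship
        code).  Returns mean and 95% credible interval per group plus the
        difference contrast.
        """
        tab = self.data.table
        if "group" not in tab.columns:
            raise ValueError("group_slopes needs a 'group' column")
        main = self.coefficient_draws(predictor)
        inter = self.coefficient_draws(f"{predictor} x musicianship")
        codes = tab.groupby("group")["musicianship"].first()
        draws = {g: main + inter * codes[g] for g in codes.index}
        mus = [g for g in codes.index if codes[g] == codes.max()][0]
        non = [g for g in codes.index if codes[g] == codes.min()][0]
        draws["difference"] = draws[mus] - draws[non]
        rows = []
        for name, d in draws.items():
            rows.append({"contrast": name, "mean": d.mean(),
                         "2.5%": np.percentile(d, 2.5),
                         "97.5%": np.percentile(d, 97.5)})
        return pd.DataFrame(rows).set_index("contrast")

    # ----- predictive evaluation ------------------------------------------

    def pointwise_loglik(self) -> np.ndarray:
        if self._loglik is None:
            self._loglik = pointwise_loglik(self.posterior, self.data)
        return self._loglik

    def loo(self) -> ElpdResult:
        """PSIS-LOO expected log pointwise predictive density."""
        return psis_loo(self.pointwise_loglik())

    def _mu_draws(self, idx: np.ndarray) -> np.ndarray:
        X = self.data.X
        beta = self.posterior["beta"].reshape(-1, X.shape[1])[idx]
        b = self.posterior["b"].reshape(-1, *self.posterior["b"].shape[2:])[idx]
        mu = beta @ X.T
        for s in range(b.shape[1]):
            rows = self.data.song_idx == s
            mu[:, rows] += b[:, s, :] @ X[rows].T
        return mu

    def posterior_predictive(self, seed: int = 0, n_draws: int = 200) -> dict:
        """Replicate response series (including AR(1) noise) and compare
        observed vs replicated mean, sd and pooled lag-1 autocorrelation."""
        rng = np.random.default_rng([seed, 21])
        S = self.posterior["beta"].shape[0] * self.posterior["beta"].shape[1]
        idx = rng.choice(S, size=min(n_draws, S), replace=False)
        rho = self.posterior["rho"].reshape(-1)[idx]
        sigma = self.posterior["sigma"].reshape(-1)[idx]
        mu = self._mu_draws(idx)
        # vectorized AR(1) replication across draws
        n = self.data.n_obs
        e = np.empty((len(idx), n))
        z = rng.standard_normal((len(idx), n))
        for t in range(n):
            if self.data.is_start[t]:
                e[:, t] = sigma / np.sqrt(1 - rho ** 2) * z[:, t]
            else:
                e[:, t] = rho * e[:, t - 1] + sigma * z[:, t]
        y_rep = mu + e

        def lag1(y):
            a = y[..., :-1][..., ~self.data.is_start[1:]]
            bb = y[..., 1:][..., ~self.data.is_start[1:]]
            am = a - a.mean(axis=-1, keepdims=True)
            bm = bb - bb.mean(axis=-1, keepdims=True)
            return (am * bm).sum(-1) / np.sqrt((am ** 2).sum(-1) * (bm ** 2).sum(-1))

        stats = pd.DataFrame({
            "mean": y_rep.mean(axis=1), "sd": y_rep.std(axis=1), "lag1": lag1(y_rep)})
        observed = {"mean": float(self.data.y.mean()), "sd": float(self.data.y.std()),
                    "lag1": float(lag1(self.data.y[None, :])[0])}
        return {"y_rep": y_rep, "replicated": stats, "observed": observed}

    # ----- persistence and plotting ---------------------------------------

    def save(self, path) -> None:
        """Persist draws + spec + diagnostics as an .npz archive."""
        meta = {"terms": [list(t) for t in self.spec.terms],
                "response": self.spec.response, "preset": self.spec.preset,
                "seed": self.seed,
                "chains": self.config.chains, "warmup": self.config.warmup,
                "draws": self.config.draws}
        np.savez_compressed(path, _meta=json.dumps(meta),
                            _diagnostics=self.diagnostics.to_json(),
                            loglik=self.pointwise_loglik(), **self.posterior)

    def plot_coefficients(self, ax=None):
        """Forest plot of population-level coefficient posteriors."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.4 * self.data.n_terms + 1))
        summ = self.summary()
        betas = summ[summ.index.str.startswith("beta[")]
        y = np.arange(len(betas))[::-1]
        ax.errorbar(betas["mean"], y,
                    xerr=[betas["mean"] - betas["2.5%"],
                          betas["97.5%"] - betas["mean"]],
                    fmt="o", capsize=3)
        ax.axvline(0, color="grey", lw=0.8)
        ax.set_yticks(y, [s[5:-1] for s in betas.index])
        ax.set_xlabel("standardized effect")
        return ax
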