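"""Blocked Gibbs / Metropolis-within-Gibbs sampler for the multilevel
Gaussian AR(1) regression.

Model, for observation n in song s(n) arranged in AR(1) chains:

    y_n = x_n' beta + x_n' b_{s(n)} + e_n
    e_t = rho * e_{t-1} + eta_t,   eta_t ~ N(0, sigma^2),
    e_1 ~ N(0, sigma^2 / (1 - rho^2))          (stationary start)
    beta_j ~ N(0, 1)
    b_s ~ N(0, Sigma_b),  Sigma_b = diag(tau) C diag(tau)
    tau_j, sigma ~ Half-Cauchy(0, 1),  C ~ LKJ(2),  rho ~ Uniform(-1, 1)

Conditionally conjugate blocks (beta, each b_s) are drawn exactly after
AR(1) whitening; (tau, C) and (rho, sigma) are updated by adaptive
per-coordinate random-walk Metropolis on unconstrained scales.  The LKJ
prior is parameterized by canonical partial correlations (C-vine), under
which LKJ(eta) factorizes into independent scaled Beta(a_j, a_j) laws with
a_j = eta + (q - 2 - j)/2 for CPC column j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .design import RegressionData

__all__ = ["SamplerConfig", "gibbs_sample", "cpc_to_cholesky", "lkj_cpc_logprior",
           "ar1_loglik", "pointwise_loglik", "simulate_ar1_noise"]


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC budget; defaults follow the reference analysis
    (4 chains x 2500 warm-up + 2500 kept = 10000 draws)."""

    chains: int = 4
    warmup: int = 2500
    draws: int = 2500
    lkj_eta: float = 2.0
    target_accept: float = 0.44   # per-coordinate random walk optimum
    mh_substeps: int = 2


def cpc_to_cholesky(x_flat: np.ndarray, q: int) -> np.ndarray:
    """Lower Cholesky factor of a correlation matrix from CPCs in (-1, 1).

    CPC ordering: (i, j) for 1 <= i < q, 0 <= j < i, row-major.
    """
    L = np.zeros((q, q))
    L[0, 0] = 1.0
    k = 0
    for i in range(1, q):
        rem = 1.0
        for j in range(i):
            L[i, j] = x_flat[k] * np.sqrt(rem)
            rem *= 1.0 - x_flat[k] ** 2
            k += 1
        L[i, i] = np.sqrt(rem)
    return L


def _cpc_columns(q: int) -> np.ndarray:
    """Column index j of each flat CPC entry (sets its Beta exponent)."""
    return np.array([j for i in range(1, q) for j in range(i)], dtype=int)


def lkj_cpc_logprior(z_flat: np.ndarray, q: int, eta: float) -> float:
    """Log density of LKJ(eta) in unconstrained CPC coordinates z = atanh(x).

    Includes the tanh Jacobian: each term is a_j * log(1 - x^2) with
    a_j = eta + (q - 2 - j)/2 (normalizing constants dropped).
    """
    x = np.tanh(z_flat)
    a = eta + (q - 2 - _cpc_columns(q)) / 2.0
    return float(np.sum(a * np.log1p(-x ** 2)))


def _halfcauchy_logprior_log(z: np.ndarray | float) -> float:
    """Half-Cauchy(0,1) on exp(z), including the exp Jacobian."""
    t = np.exp(z)
    return float(np.sum(-np.log1p(t ** 2) + z))


def ar1_loglik(e: np.ndarray, is_start: np.ndarray, prev: np.ndarray,
               rho: float, sigma: float) -> float:
    """Stationary AR(1) log likelihood of residual chains ``e``."""
    v = e - rho * e[prev]
    s2 = sigma ** 2
    ll = -0.5 * np.sum(~is_start) * np.log(2 * np.pi * s2)
    ll -= np.sum(v[~is_start] ** 2) / (2 * s2)
    m2 = s2 / (1 - rho ** 2)
    ll += np.sum(-0.5 * np.log(2 * np.pi * m2) - e[is_start] ** 2 / (2 * m2))
    return float(ll)


def _sigma_b_loglik(b: np.ndarray, tau: np.ndarray, Lc: np.ndarray) -> float:
    """Sum_s log N(b_s | 0, diag(tau) Lc Lc' diag(tau))."""
    Ls = tau[:, None] * Lc
    w = solve_triangular(Ls, b.T, lower=True)
    n_song = b.shape[0]
    return float(-n_song * np.sum(np.log(np.diag(Ls))) - 0.5 * np.sum(w ** 2)
                 - 0.5 * n_song * b.shape[1] * np.log(2 * np.pi))


def _whiten(v: np.ndarray, rho: float, prev: np.ndarray,
            is_start: np.ndarray) -> np.ndarray:
    out = v - rho * v[prev]
    out[is_start] = np.sqrt(1 - rho ** 2) * v[is_start]
    return out


def gibbs_sample(data: RegressionData, config: SamplerConfig = SamplerConfig(),
                 seed: int = 0) -> dict[str, np.ndarray]:
    """Run the sampler; returns draws keyed by parameter, chain-major.

    Shapes: beta (C, D, p); b (C, D, n_song, p); tau (C, D, p);
    cpc (C, D, p(p-1)/2) on the unconstrained scale; rho, sigma (C, D).
    """
    X, y = data.X, data.y
    n, p = X.shape
    n_song = len(data.song_ids)
    m = p * (p - 1) // 2
    prev = np.arange(n) - 1
    prev[data.is_start] = np.where(data.is_start)[0]
    is_start = data.is_start
    song_rows = [np.where(data.song_idx == s)[0] for s in range(n_song)]

    out = {k: np.empty(s) for k, s in {
        "beta": (config.chains, config.draws, p),
        "b": (config.chains, config.draws, n_song, p),
        "tau": (config.chains, config.draws, p),
        "cpc": (config.chains, config.draws, m),
        "rho": (config.chains, config.draws),
        "sigma": (config.chains, config.draws),
    }.items()}

    for chain in range(config.chains):
        rng = np.random.default_rng([seed, 101, chain])
        beta = 0.1 * rng.standard_normal(p)
        b = np.zeros((n_song, p))
        log_tau = np.log(0.3 + 0.2 * np.abs(rng.standard_normal(p)))
        z_cpc = np.zeros(m)
        z_rho = 0.2 * rng.standard_normal()
        log_sigma = 0.2 * rng.standard_normal()
        scales = np.full(p + m + 2 + p, 0.3)      # MH step sizes, adapted in warmup
        Lc = cpc_to_cholesky(np.tanh(z_cpc), p)

        def sigma_target(lt: np.ndarray, zc: np.ndarray, Lcorr: np.ndarray) -> float:
            return (_sigma_b_loglik(b, np.exp(lt), Lcorr)
                    + _halfcauchy_logprior_log(lt)
                    + lkj_cpc_logprior(zc, p, config.lkj_eta))

        total = config.warmup + config.draws
        for it in range(total):
            rho = np.tanh(z_rho)
            sigma = np.exp(log_sigma)
            s2 = sigma ** 2

            Xw = np.column_stack([_whiten(X[:, j], rho, prev, is_start)
                                  for j in range(p)])
            yw = _whiten(y, rho, prev, is_start)

            # --- song effects: exact Gaussian conditional, per song
            tau = np.exp(log_tau)
            Ls = tau[:, None] * Lc
            Sig_inv = cho_solve((Ls, True), np.eye(p))
            r_pop = yw - Xw @ beta
            for s in range(n_song):
                rows = song_rows[s]
                Zs = Xw[rows]
                prec = Zs.T @ Zs / s2 + Sig_inv
                cf = cho_factor(prec, lower=True)
                mean = cho_solve(cf, Zs.T @ r_pop[rows] / s2)
                b[s] = mean + solve_triangular(cf[0], rng.standard_normal(p),
                                               lower=True, trans="T")

            # --- population coefficients: exact Gaussian conditional
            mu_b = np.einsum("nj,nj->n", X, b[data.song_idx])
            mu_b_w = _whiten(mu_b, rho, prev, is_start)
            r = yw - mu_b_w
            prec = Xw.T @ Xw / s2 + np.eye(p)
            cf = cho_factor(prec, lower=True)
            beta = (cho_solve(cf, Xw.T @ r / s2)
                    + solve_triangular(cf[0], rng.standard_normal(p),
                                       lower=True, trans="T"))

            # --- (tau, C): per-coordinate adaptive random-walk Metropolis
            cur = sigma_target(log_tau, z_cpc, Lc)
            for _ in range(config.mh_substeps):
                for k in range(p + m):
                    if k < p:
                        prop_lt = log_tau.copy()
                        prop_lt[k] += scales[k] * rng.standard_normal()
                        cand = sigma_target(prop_lt, z_cpc, Lc)
                    else:
                        prop_z = z_cpc.copy()
                        prop_z[k - p] += scales[k] * rng.standard_normal()
                        Lp = cpc_to_cholesky(np.tanh(prop_z), p)
                        cand = sigma_target(log_tau, prop_z, Lp)
                    acc = cand - cur
                    if np.log(rng.random()) < acc:
                        cur = cand
                        if k < p:
                            log_tau = prop_lt
                        else:
                            z_cpc, Lc = prop_z, Lp
                    if it < config.warmup:
                        rate = 1.0 if acc >= 0 else float(np.exp(acc))
                        scales[k] *= np.exp((rate - config.target_accept)
                                            / np.sqrt(1 + it))

            # --- ancillary rescaling of tau (interweaving): the centered
            # conditional of tau | b collapses in the funnel near tau = 0, so
            # re-update each tau_j with the standardized effects u held fixed
            # (b_s = diag(tau) Lc u_s), against the whitened data likelihood.
            tau = np.exp(log_tau)
            Ls = tau[:, None] * Lc
            u = solve_triangular(Ls, b.T, lower=True)      # (p, n_song)
            Lu = Lc @ u                                    # b[:, j] = tau_j * Lu[j]
            bsong = b[data.song_idx]
            res_w = yw - Xw @ beta - np.einsum("nj,nj->n", Xw, bsong)
            for j in range(p):
                step = scales[p + m + 2 + j] * rng.standard_normal()
                new_tau_j = np.exp(log_tau[j] + step)
                delta = (new_tau_j - tau[j]) * Lu[j]       # change of b[:, j]
                res_new = res_w - Xw[:, j] * delta[data.song_idx]
                acc = ((np.sum(res_w ** 2) - np.sum(res_new ** 2)) / (2 * s2)
                       + _halfcauchy_logprior_log(log_tau[j] + step)
                       - _halfcauchy_logprior_log(log_tau[j]))
                if np.log(rng.random()) < acc:
                    log_tau[j] += step
                    tau = np.exp(log_tau)
                    b[:, j] = tau[j] * Lu[j]
                    res_w = res_new
                if it < config.warmup:
                    rate = 1.0 if acc >= 0 else float(np.exp(acc))
                    scales[p + m + 2 + j] *= np.exp((rate - config.target_accept)
                                                    / np.sqrt(1 + it))
            mu_b = np.einsum("nj,nj->n", X, b[data.song_idx])

            # --- (rho, sigma): per-coordinate Metropolis on the residuals
            e = y - X @ beta - mu_b
            def rs_target(zr: float, ls: float) -> float:
                return (ar1_loglik(e, is_start, prev, np.tanh(zr), np.exp(ls))
                        + np.log1p(-np.tanh(zr) ** 2)
                        + _halfcauchy_logprior_log(ls))
            cur = rs_target(z_rho, log_sigma)
            for _ in range(config.mh_substeps):
                for k, which in ((p + m, "rho"), (p + m + 1, "sigma")):
                    step = scales[k] * rng.standard_normal()
                    if which == "rho":
                        cand = rs_target(z_rho + step, log_sigma)
                    else:
                        cand = rs_target(z_rho, log_sigma + step)
                    acc = cand - cur
                    if np.log(rng.random()) < acc:
                        cur = cand
                        if which == "rho":
                            z_rho += step
                        else:
                            log_sigma += step
                    if it < config.warmup:
                        rate = 1.0 if acc >= 0 else float(np.exp(acc))
                        scales[k] *= np.exp((rate - config.target_accept)
                                            / np.sqrt(1 + it))

            if it >= config.warmup:
                d = it - config.warmup
                out["beta"][chain, d] = beta
                out["b"][chain, d] = b
                out["tau"][chain, d] = np.exp(log_tau)
                out["cpc"][chain, d] = z_cpc
                out["rho"][chain, d] = np.tanh(z_rho)
                out["sigma"][chain, d] = np.exp(log_sigma)
    return out


def pointwise_loglik(draws: dict[str, np.ndarray], data: RegressionData,
                     chunk: int = 200) -> np.ndarray:
    """Per-draw, per-observation log density under the AR(1) innovation
    decomposition (first observation of each chain uses the stationary
    marginal).  Returns an (S_total, N) matrix, draws flattened chain-major.
    """
    X, y = data.X, data.y
    n = len(y)
    prev = np.arange(n) - 1
    prev[data.is_start] = np.where(data.is_start)[0]
    beta = draws["beta"].reshape(-1, X.shape[1])
    b = draws["b"].reshape(-1, *draws["b"].shape[2:])
    rho = draws["rho"].reshape(-1)
    sigma = draws["sigma"].reshape(-1)
    S = beta.shape[0]
    ll = np.empty((S, n))
    for lo in range(0, S, chunk):
        hi = min(lo + chunk, S)
        mu = beta[lo:hi] @ X.T
        for s in range(b.shape[1]):
            rows = data.song_idx == s
            mu[:, rows] += b[lo:hi, s, :] @ X[rows].T
        e = y[None, :] - mu
        r = rho[lo:hi, None]
        s2 = sigma[lo:hi, None] ** 2
        v = e - r * e[:, prev]
        lp = -0.5 * np.log(2 * np.pi * s2) - v ** 2 / (2 * s2)
        m2 = s2 / (1 - r ** 2)
        lp_start = -0.5 * np.log(2 * np.pi * m2) - e ** 2 / (2 * m2)
        ll[lo:hi] = np.where(data.is_start[None, :], lp_start, lp)
    return ll


def simulate_ar1_noise(n_draws: int, is_start: np.ndarray, rho: np.ndarray,
                       sigma: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Simulate stationary AR(1) chains for posterior predictive draws."""
    n = len(is_start)
    e = np.empty((n_draws, n))
    z = rng.standard_normal((n_draws, n))
    marg = sigma / np.sqrt(1 - rho ** 2)
    for t in range(n):
        if is_start[t]:
            e[:, t] = marg * z[:, t]
        else:
            e[:, t] = rho * e[:, t - 1] + sigma * z[:, t]
    return e
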