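"""Independent brute-force oracles used by the test suite.

These are written directly from the mathematical definitions (plain
dictionaries and recursion, no shared code with the package) so they can
serve as references for the optimized implementations.
"""

from __future__ import annotations

import numpy as np


def brute_ngram_counts(sequences: list[list[str]], max_order: int) -> dict:
    """Count every (context, next-symbol) pair by direct enumeration."""
    counts: dict = {}
    for seq in sequences:
        for i in range(len(seq)):
            for k in range(0, min(max_order, i) + 1):
                ctx = tuple(seq[i - k:i])
                counts.setdefault(ctx, {}).setdefault(seq[i], 0)
                counts[ctx][seq[i]] += 1
    return counts


def brute_ppm_c(sequences: list[list[str]], context: tuple, vocab: list[str],
                max_order: int) -> np.ndarray:
    """Escape-method-C interpolated smoothing, written as plain recursion.

    p(s | ctx) = c(ctx, s)/(n + t) + t/(n + t) * p(s | ctx[1:]), bottoming
    out at the uniform distribution over the vocabulary; the recursion
    starts from the longest observed suffix of the (truncated) context.
    """
    counts = brute_ngram_counts(sequences, max_order)

    def rec(ctx: tuple) -> np.ndarray:
        if len(ctx) == 0:
            base = np.full(len(vocab), 1.0 / len(vocab))
        else:
            base = rec(ctx[1:])
        c = counts.get(ctx)
        if not c:
            return base
        n = sum(c.values())
        t = len(c)
        vec = np.array([c.get(s, 0) for s in vocab], dtype=float)
        return vec / (n + t) + (t / (n + t)) * base

    ctx = tuple(context)[max(0, len(context) - max_order):]
    while len(ctx) > 0 and ctx not in counts:
        ctx = ctx[1:]
    p = rec(ctx)
    return p / p.sum()


def exact_loo_gaussian_mean(y: np.ndarray, prior_var: float = 1.0,
                            noise_var: float = 1.0) -> float:
    """Exact leave-one-out log predictive density for the conjugate
    Gaussian mean model y_i ~ N(mu, noise_var), mu ~ N(0, prior_var)."""
    from scipy.stats import norm

    total = 0.0
    n = len(y)
    for i in range(n):
        rest = np.delete(y, i)
        post_prec = 1.0 / prior_var + (n - 1) / noise_var
        post_mean = (rest.sum() / noise_var) / post_prec
        pred_var = 1.0 / post_prec + noise_var
        total += norm.logpdf(y[i], post_mean, np.sqrt(pred_var))
    return float(total)
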