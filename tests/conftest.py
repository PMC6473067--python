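"""Shared fixtures and independent reference oracles.

The oracles here are deliberately naive (explicit loops, textbook formulas)
so they stay independent of the vectorised implementation paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from jointgsea import GeneSetCollection, PValueMatrix, clamp_pvalues


# ---------------------------------------------------------------------------
# mixture oracles
# ---------------------------------------------------------------------------

def enumeration_posterior(pvals: np.ndarray, prior: np.ndarray, alpha: np.ndarray):
    """Brute-force configuration posterior by direct enumeration.

    Returns (config_posterior (G, 2**N), per_dataset_posterior (G, N)) using
    plain products of alpha * p**(alpha-1); dataset 0 is the least
    significant bit of the configuration index.
    """
    g, n = pvals.shape
    n_configs = 2 ** n
    config_post = np.zeros((g, n_configs))
    de_post = np.zeros((g, n))
    for row in range(g):
        weights = []
        for k in range(n_configs):
            density = 1.0
            for i in range(n):
                if (k >> i) & 1:
                    density *= alpha[i] * pvals[row, i] ** (alpha[i] - 1.0)
            weights.append(prior[k] * density)
        total = sum(weights)
        for k in range(n_configs):
            config_post[row, k] = weights[k] / total
            for i in range(n):
                if (k >> i) & 1:
                    de_post[row, i] += weights[k] / total
    return config_post, de_post


def weighted_beta_mle(pvals: np.ndarray, config_posterior: np.ndarray):
    """Reference M-step: prior column means and the weighted Beta(a,1) MLE."""
    g, n_configs = config_posterior.shape
    n = int(math.log2(n_configs))
    prior = config_posterior.sum(axis=0) / g
    alpha = []
    for j in range(n):
        num = den = 0.0
        for row in range(g):
            w = sum(
                config_posterior[row, k]
                for k in range(n_configs)
                if (k >> j) & 1
            )
            num += w
            den += w * (-math.log(pvals[row, j]))
        alpha.append(num / den if den > 0 else math.nan)
    return prior, np.array(alpha)


def sample_from_mixture(
    n_features: int,
    prior: np.ndarray,
    alpha: np.ndarray,
    rng: np.random.Generator,
) -> PValueMatrix:
    """Draw a p-value matrix from the joint beta-uniform mixture model."""
    n = len(alpha)
    configs = rng.choice(2 ** n, size=n_features, p=prior)
    bits = ((configs[:, None] >> np.arange(n)[None, :]) & 1).astype(bool)
    u = rng.uniform(size=(n_features, n))
    p = np.where(bits, u ** (1.0 / np.asarray(alpha)), u)
    return clamp_pvalues(p)


# ---------------------------------------------------------------------------
# enrichment oracles
# ---------------------------------------------------------------------------

def naive_nks(ranked: list[str], members: set[str]) -> float:
    """Prefix-sum nKS computed literally: walk the list, track the maximum."""
    g, m = len(ranked), len(members)
    up = math.sqrt((g - m) / m)
    down = math.sqrt(m / (g - m))
    running = 0.0
    best = -math.inf
    for gene in ranked:
        running += up if gene in members else -down
        best = max(best, running)
    return best


def stepup_bh(pvalues: np.ndarray) -> np.ndarray:
    """Textbook Benjamini–Hochberg step-up adjustment."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p, kind="stable")
    n = len(p)
    adjusted_sorted = [min(1.0, p[order[i]] * n / (i + 1)) for i in range(n)]
    for i in range(n - 2, -1, -1):
        adjusted_sorted[i] = min(adjusted_sorted[i], adjusted_sorted[i + 1])
    out = np.empty(n)
    out[order] = adjusted_sorted
    return out


def pairwise_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """O(P^2) Mann–Whitney AUC with half-credit for tied scores."""
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    wins = 0.0
    for a, b in itertools.product(pos, neg):
        wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def small_collection() -> GeneSetCollection:
    universe = [f"g{i}" for i in range(40)]
    sets = {
        "setA": universe[:5],
        "setB": universe[5:13],
        "setC": universe[0:20:2],
    }
    return GeneSetCollection(sets, universe)
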