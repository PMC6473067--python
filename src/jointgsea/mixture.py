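"""Beta-uniform mixture model of p-values over joint differential-status
configurations.

Within one dataset, p-values of null (non-differential) features are modelled
as Uniform(0,1) and p-values of differential features as Beta(alpha, 1) with
shape ``alpha`` in (0, 1), giving the marginal density

    f(p) = pi1 * alpha * p**(alpha - 1) + (1 - pi1).

Across N datasets, a feature's differential status is a binary configuration
(D_1, ..., D_N); the joint model places a prior over all 2**N configurations
and assumes p-values are conditionally independent given the configuration.
The prior and the per-dataset shapes are estimated by EM, and the quantity of
interest is the per-dataset posterior Pr(D_i = 1 | p_g1, ..., p_gN).

Configurations are encoded as integers with dataset 0 as the least
significant bit: configuration ``k`` has dataset ``i`` differential iff
``(k >> i) & 1``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

#: Floor applied to incoming p-values so that -log(p) stays finite.
PVALUE_FLOOR = 1e-10

#: Clipping interval for the beta shape after each M-step.
ALPHA_MIN = 1e-4
ALPHA_MAX = 1.0 - 1e-4

#: The configuration prior has 2**N entries; refuse to go exponential.
MAX_DATASETS = 10


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PValueMatrix:
    """G x N matrix of p-values with feature and dataset identifiers.

    Entries must lie in (0, 1]; use :func:`clamp_pvalues` to floor raw
    p-values that may contain exact zeros.
    """

    values: np.ndarray
    feature_ids: Sequence[str]
    dataset_ids: Sequence[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        g, n = self.values.shape
        self.feature_ids = list(self.feature_ids)
        self.dataset_ids = list(self.dataset_ids)
        if len(self.feature_ids) != g or len(self.dataset_ids) != n:
            raise ValueError("identifier lengths do not match matrix shape")
        if len(set(self.feature_ids)) != g:
            raise ValueError("feature_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("p-values must be finite")
        if np.any(self.values <= 0) or np.any(self.values > 1):
            raise ValueError("p-values must lie in (0, 1]; clamp zeros first")
        if n > MAX_DATASETS:
            raise ValueError(
                f"N={n} datasets implies a {2**n}-entry configuration prior; "
                f"the joint model is capped at N <= {MAX_DATASETS}"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_datasets(self) -> int:
        return self.values.shape[1]


@dataclass
class MixtureParams:
    """Fitted joint mixture parameters.

    ``config_prior[k]`` is Pr(D_1, ..., D_N) for the configuration encoded by
    integer ``k`` (dataset 0 = least significant bit); ``alpha[i]`` is the
    Beta(alpha, 1) shape of dataset ``i``'s differential component.
    """

    config_prior: np.ndarray
    alpha: np.ndarray
    log_likelihood_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False

    def __post_init__(self) -> None:
        self.config_prior = np.asarray(self.config_prior, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.config_prior.shape != (2 ** len(self.alpha),):
            raise ValueError("config_prior must have 2**N entries")
        if np.any(self.config_prior < 0):
            raise ValueError("config_prior entries must be non-negative")
        if abs(self.config_prior.sum() - 1.0) > 1e-12:
            raise ValueError("config_prior must sum to 1")
        if np.any(self.alpha <= 0) or np.any(self.alpha >= 1):
            raise ValueError("alpha entries must lie strictly in (0, 1)")

    @property
    def n_datasets(self) -> int:
        return len(self.alpha)


@dataclass
class PosteriorMatrix:
    """Per-dataset posterior differential probabilities Pr(D_i=1 | p_g)."""

    values: np.ndarray
    feature_ids: Sequence[str]
    dataset_ids: Sequence[str]
    config_posterior: np.ndarray | None = None


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def clamp_pvalues(
    raw: np.ndarray,
    feature_ids: Sequence[str] | None = None,
    dataset_ids: Sequence[str] | None = None,
    floor: float = PVALUE_FLOOR,
) -> PValueMatrix:
    """Floor p-values at ``floor`` so -log(p) is finite, and wrap the result.

    Entries must already lie in [0, 1]; only the lower end is adjusted.
    """
    values = np.asarray(raw, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if np.any(values < 0) or np.any(values > 1):
        raise ValueError("raw p-values must lie in [0, 1]")
    values = np.maximum(values, floor)
    g, n = values.shape
    if feature_ids is None:
        feature_ids = [f"feature{i}" for i in range(g)]
    if dataset_ids is None:
        dataset_ids = [f"dataset{j}" for j in range(n)]
    return PValueMatrix(values, feature_ids, dataset_ids)


def marginal_density(p, pi1: float, alpha: float):
    """Single-dataset marginal density pi1*alpha*p**(alpha-1) + (1-pi1)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p must lie in (0, 1]")
    if not 0.0 <= pi1 <= 1.0:
        raise ValueError("pi1 must lie in [0, 1]")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    out = pi1 * alpha * p ** (alpha - 1.0) + (1.0 - pi1)
    return out.item() if out.ndim == 0 else out


def joint_density(p_vec, config, alpha) -> float:
    """Conditional joint density of one feature's p-values given a configuration.

    Each active dataset contributes alpha_i * p_i**(alpha_i - 1); inactive
    datasets contribute the uniform density 1.
    """
    p_vec = np.asarray(p_vec, dtype=float)
    config = np.asarray(config, dtype=int)
    alpha = np.asarray(alpha, dtype=float)
    if not (len(p_vec) == len(config) == len(alpha)):
        raise ValueError("p_vec, config and alpha must have equal length")
    if np.any(p_vec <= 0) or np.any(p_vec > 1):
        raise ValueError("p entries must lie in (0, 1]")
    if np.any(alpha <= 0) or np.any(alpha >= 1):
        raise ValueError("alpha entries must lie strictly in (0, 1)")
    active = config.astype(bool)
    return float(np.prod(alpha[active] * p_vec[active] ** (alpha[active] - 1.0)))


def config_matrix(n_datasets: int) -> np.ndarray:
    """(2**N, N) binary matrix; row k, column i = bit i of k (dataset 0 = LSB)."""
    k = np.arange(2 ** n_datasets)
    return ((k[:, None] >> np.arange(n_datasets)[None, :]) & 1).astype(float)


def _log_conditional_density(log_p: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """(G, 2**N) matrix of log f(p_g | configuration k, alpha)."""
    configs = config_matrix(len(alpha))
    # log of a per-dataset active factor: log(alpha_i) + (alpha_i - 1) log p_gi
    per_dataset = np.log(alpha)[None, :] + (alpha - 1.0)[None, :] * log_p
    return per_dataset @ configs.T


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def e_step(pvals: PValueMatrix, params: MixtureParams) -> np.ndarray:
    """Posterior over the 2**N configurations for every feature.

    Computed in log space; each row normalises to 1 (the all-null
    configuration always has positive density, so no row can vanish).
    """
    post, _ = _e_step_with_loglik(pvals, params)
    return post


def _e_step_with_loglik(
    pvals: PValueMatrix, params: MixtureParams
) -> tuple[np.ndarray, float]:
    if params.n_datasets != pvals.n_datasets:
        raise ValueError("params and p-value matrix disagree on N")
    log_p = np.log(pvals.values)
    log_joint = _log_conditional_density(log_p, params.alpha)
    with np.errstate(divide="ignore"):  # prior entries may be exactly 0
        log_num = log_joint + np.log(params.config_prior)[None, :]
    log_marginal = logsumexp(log_num, axis=1)
    if not np.all(np.isfinite(log_marginal)):
        bad = int(np.argmax(~np.isfinite(log_marginal)))
        raise FloatingPointError(
            f"non-finite likelihood for feature {pvals.feature_ids[bad]!r}"
        )
    post = np.exp(log_num - log_marginal[:, None])
    return post, float(log_marginal.sum())


def log_likelihood(pvals: PValueMatrix, params: MixtureParams) -> float:
    """Marginal log-likelihood of the p-value matrix under the joint model."""
    _, ll = _e_step_with_loglik(pvals, params)
    return ll


def m_step(
    pvals: PValueMatrix,
    config_posterior: np.ndarray,
    prev_alpha: np.ndarray | None = None,
) -> MixtureParams:
    """Update the configuration prior and beta shapes from posteriors.

    The prior update is the column mean of the configuration posterior. Each
    shape alpha_j is the weighted Beta(alpha, 1) maximum-likelihood estimate
    sum_g(w_gj) / sum_g(w_gj * (-log p_gj)) with weights w_gj the posterior
    mass on configurations where dataset j is differential, clipped into
    [ALPHA_MIN, ALPHA_MAX]. If a dataset has zero posterior weight, its shape
    is left unchanged (``prev_alpha``, or 0.5).
    """
    config_posterior = np.asarray(config_posterior, dtype=float)
    g, n_configs = config_posterior.shape
    n = pvals.n_datasets
    if n_configs != 2 ** n or g != pvals.n_features:
        raise ValueError("config_posterior shape does not match p-value matrix")
    row_sums = config_posterior.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-8):
        raise ValueError("config_posterior rows must sum to 1")

    prior = config_posterior.mean(axis=0)
    prior = prior / prior.sum()

    configs = config_matrix(n)
    weights = config_posterior @ configs  # (G, N): posterior Pr(D_j=1 | p_g)
    neg_log_p = -np.log(pvals.values)
    numer = weights.sum(axis=0)
    denom = (weights * neg_log_p).sum(axis=0)

    if prev_alpha is None:
        prev_alpha = np.full(n, 0.5)
    alpha = np.array(prev_alpha, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        est = numer / denom
    for j in range(n):
        if numer[j] <= 0.0:
            logger.warning(
                "dataset %s: no posterior evidence for the differential "
                "component; alpha left unchanged", pvals.dataset_ids[j]
            )
        elif denom[j] <= 0.0:
            # every weighted p-value is exactly 1; push alpha to its ceiling
            alpha[j] = ALPHA_MAX
        else:
            alpha[j] = est[j]
    alpha = np.clip(alpha, ALPHA_MIN, ALPHA_MAX)
    return MixtureParams(config_prior=prior, alpha=alpha)


def fit_em(
    pvals: PValueMatrix,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int | None = None,
) -> MixtureParams:
    """Fit the joint mixture by EM from the fixed standard initialization.

    Starts from a uniform configuration prior and alpha_i = 0.5 for every
    dataset, and iterates E/M steps until the relative change in marginal
    log-likelihood drops below ``tol`` or ``max_iter`` is reached. The
    ``seed`` argument is accepted for interface uniformity; the fit is
    deterministic (single fixed initialization, no restarts).
    """
    del seed
    n = pvals.n_datasets
    if pvals.n_features < 2 ** n:
        warnings.warn(
            f"only G={pvals.n_features} features for a {2**n}-configuration "
            "model; estimates may be unstable",
            stacklevel=2,
        )
    params = MixtureParams(
        config_prior=np.full(2 ** n, 1.0 / 2 ** n),
        alpha=np.full(n, 0.5),
    )
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        post, ll = _e_step_with_loglik(pvals, params)
        trace.append(ll)
        new_params = m_step(pvals, post, prev_alpha=params.alpha)
        params = new_params
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(trace[-1] - prev) <= tol * (abs(prev) + 1e-300):
                converged = True
                break
    params.log_likelihood_trace = trace
    params.n_iterations = n_iter
    params.converged = converged
    if not converged:
        logger.info("EM reached max_iter=%d without converging", max_iter)
    return params


def posterior_de(pvals: PValueMatrix, params: MixtureParams) -> PosteriorMatrix:
    """Per-dataset posterior Pr(D_i = 1 | p_g1, ..., p_gN) for every feature.

    Sums the configuration posterior over all configurations in which dataset
    ``i`` is differential.
    """
    post = e_step(pvals, params)
    configs = config_matrix(params.n_datasets)
    values = post @ configs
    return PosteriorMatrix(
        values=np.clip(values, 0.0, 1.0),
        feature_ids=pvals.feature_ids,
        dataset_ids=pvals.dataset_ids,
        config_posterior=post,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_params(params: MixtureParams, path) -> None:
    """Serialize fitted parameters to a plain-text key-value file."""
    n = params.n_datasets
    lines = [f"n_datasets\t{n}"]
    for i, a in enumerate(params.alpha):
        lines.append(f"alpha_{i}\t{float(a)!r}")
    for k, pr in enumerate(params.config_prior):
        lines.append(f"prior_{k:0{n}b}\t{float(pr)!r}")
    lines.append(f"n_iterations\t{params.n_iterations}")
    lines.append(f"converged\t{int(params.converged)}")
    if params.log_likelihood_trace:
        lines.append(f"log_likelihood\t{float(params.log_likelihood_trace[-1])!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_params(path) -> MixtureParams:
    """Read parameters written by :func:`write_params`."""
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                key, value = line.rstrip("\n").split("\t")
                kv[key] = value
    n = int(kv["n_datasets"])
    alpha = np.array([float(kv[f"alpha_{i}"]) for i in range(n)])
    prior = np.array([float(kv[f"prior_{k:0{n}b}"]) for k in range(2 ** n)])
    params = MixtureParams(config_prior=prior, alpha=alpha)
    params.n_iterations = int(kv.get("n_iterations", 0))
    params.converged = bool(int(kv.get("converged", 0)))
    if "log_likelihood" in kv:
        params.log_likelihood_trace = [float(kv["log_likelihood"])]
    return params
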