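"""MAPE meta-analysis baselines for pathway enrichment.

Three classic meta-analysis pipelines built on the maxP combination rule
(a feature is significant only if significant in every dataset):

* MAPE_Gene — combine gene p-values by maxP, rank genes on the combined
  p-value, then run the nKS permutation test on that single ranking.
* MAPE_Pathway — run the per-dataset nKS permutation test, combine the
  per-dataset pathway p-values by maxP, and assess the combined statistic
  against the analogous maxP of per-permutation pathway p-values.
* MAPE_I — take the minimum of a pathway's MAPE_Gene and MAPE_Pathway
  p-values as the statistic, with its null built the same way.

All three share one set of gene-label permutations per dataset; combined
statistics are small-is-significant, so their permutation p-value counts
#{null <= observed}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import (
    GeneSetCollection,
    bh_fdr,
    observed_nks,
    permutation_pvalue,
    permutation_stats,
    rank_genes,
    rank_table,
)
from .frameworks import StudyBundle, gene_pvalues
from .mixture import PValueMatrix


def maxp_meta(pvals: PValueMatrix) -> np.ndarray:
    """maxP combination: per-feature maximum p-value across datasets."""
    return pvals.values.max(axis=1)


def _pvalue_of_pool(values: np.ndarray, pool: np.ndarray) -> np.ndarray:
    """Small-is-significant permutation p-value: (#{pool <= v} + 1)/(n + 1)."""
    pool_sorted = np.sort(pool)
    n_le = np.searchsorted(pool_sorted, values, side="right")
    return (n_le + 1) / (pool_sorted.size + 1)


@dataclass
class _MapeParts:
    """Shared intermediates of the MAPE family for one study."""

    collection: GeneSetCollection
    gene_stat_obs: np.ndarray        # observed nKS on the maxP gene ranking
    gene_p_obs: np.ndarray           # its pooled-null p-value per pathway
    gene_p_perm: np.ndarray          # (B, P) per-permutation analogues
    pathway_stat_obs: np.ndarray     # maxP of per-dataset pathway p-values
    pathway_p_obs: np.ndarray
    pathway_stat_perm: np.ndarray    # (B, P) per-permutation maxP values


def _mape_parts(
    bundle: StudyBundle,
    collection: GeneSetCollection,
    n_permutations: int,
    seed: int,
) -> _MapeParts:
    pvals = gene_pvalues(bundle)
    member_idx = collection.member_indices()
    n_genes = collection.n_genes
    n = bundle.n_datasets

    # --- gene-level branch: one combined ranking by maxP ------------------
    combined = maxp_meta(pvals)
    order = rank_genes(combined, collection.universe, ascending=True)
    gene_stat_obs = observed_nks(order, member_idx, n_genes)
    rng = np.random.default_rng(seed)
    gene_null = permutation_stats(member_idx, n_genes, n_permutations, rng)
    gene_pool = gene_null.ravel()
    gene_p_obs = permutation_pvalue(gene_stat_obs, gene_pool)
    gene_p_perm = permutation_pvalue(gene_pool, gene_pool).reshape(gene_null.shape)

    # --- pathway-level branch: per-dataset p-values combined by maxP ------
    p_obs = np.empty((len(member_idx), n))
    p_perm = np.empty((n_permutations, len(member_idx), n))
    for i in range(n):
        order_i = rank_genes(pvals.values[:, i], collection.universe, ascending=True)
        obs_i = observed_nks(order_i, member_idx, n_genes)
        null_i = permutation_stats(
            member_idx, n_genes, n_permutations, np.random.default_rng(seed + 1 + i)
        )
        pool_i = null_i.ravel()
        p_obs[:, i] = permutation_pvalue(obs_i, pool_i)
        p_perm[:, :, i] = permutation_pvalue(pool_i, pool_i).reshape(null_i.shape)
    pathway_stat_obs = p_obs.max(axis=1)
    pathway_stat_perm = p_perm.max(axis=2)
    pathway_p_obs = _pvalue_of_pool(pathway_stat_obs, pathway_stat_perm.ravel())

    return _MapeParts(
        collection=collection,
        gene_stat_obs=gene_stat_obs,
        gene_p_obs=gene_p_obs,
        gene_p_perm=gene_p_perm,
        pathway_stat_obs=pathway_stat_obs,
        pathway_p_obs=pathway_p_obs,
        pathway_stat_perm=pathway_stat_perm,
    )


def _table(collection: GeneSetCollection, stat, pvalue) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "pathway": collection.set_names,
            "stat": stat,
            "pvalue": pvalue,
            "fdr": bh_fdr(pvalue),
        }
    )
    frame["rank"] = rank_table(frame)
    return frame


def mape_gene(
    bundle: StudyBundle,
    collection: GeneSetCollection,
    n_permutations: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """MAPE_Gene: nKS permutation test on the maxP-combined gene ranking."""
    parts = _mape_parts(bundle, collection, n_permutations, seed)
    return _table(collection, parts.gene_stat_obs, parts.gene_p_obs)


def mape_pathway(
    bundle: StudyBundle,
    collection: GeneSetCollection,
    n_permutations: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """MAPE_Pathway: maxP of per-dataset pathway p-values, permutation-calibrated."""
    parts = _mape_parts(bundle, collection, n_permutations, seed)
    return _table(collection, -parts.pathway_stat_obs, parts.pathway_p_obs)


def mape_i(
    bundle: StudyBundle,
    collection: GeneSetCollection,
    n_permutations: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """MAPE_I: minimum of the MAPE_Gene and MAPE_Pathway p-values per pathway,
    assessed against the permutation null of the same minimum."""
    parts = _mape_parts(bundle, collection, n_permutations, seed)
    min_obs = np.minimum(parts.gene_p_obs, parts.pathway_p_obs)
    pathway_p_perm = _pvalue_of_pool_rows(parts.pathway_stat_perm)
    min_null = np.minimum(parts.gene_p_perm, pathway_p_perm)
    pvalue = _pvalue_of_pool(min_obs, min_null.ravel())
    return _table(collection, -min_obs, pvalue)


def _pvalue_of_pool_rows(stat_perm: np.ndarray) -> np.ndarray:
    """p-value of every permuted combined statistic against its own pool."""
    return _pvalue_of_pool(stat_perm.ravel(), stat_perm.ravel()).reshape(
        stat_perm.shape
    )
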