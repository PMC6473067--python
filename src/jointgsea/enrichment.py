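"""Normalized Kolmogorov–Smirnov enrichment statistic with a pooled
gene-label permutation null and Benjamini–Hochberg FDR.

The statistic walks a significance-ranked gene list and accumulates
``+sqrt((G-M)/M)`` at each of the M set members and ``-sqrt(M/(G-M))`` at each
non-member; the increments sum to zero over the full list, so the maximum of
the running sum (the nKS statistic) is always >= 0 and is comparable across
set sizes. Significance is assessed by permuting gene labels B times,
recomputing the statistic for every pathway, and pooling all B*P permuted
values into one null; the p-value is (#{null >= observed} + 1) / (B*P + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    """Named gene sets over a common gene universe.

    ``sets`` maps pathway name -> member gene identifiers; members are stored
    in their given order but treated as sets. The universe fixes both G and
    the gene order used to index rankings.
    """

    sets: Mapping[str, Sequence[str]]
    universe: Sequence[str]
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.sets = {name: list(members) for name, members in self.sets.items()}
        self.universe = list(self.universe)
        if len(set(self.universe)) != len(self.universe):
            raise ValueError("universe contains duplicate gene identifiers")
        self._index = {g: i for i, g in enumerate(self.universe)}
        for name, members in self.sets.items():
            missing = [g for g in members if g not in self._index]
            if missing:
                raise ValueError(
                    f"gene set {name!r} has members outside the universe "
                    f"(e.g. {missing[0]!r}); intersect first"
                )

    @property
    def set_names(self) -> list[str]:
        return list(self.sets)

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    @property
    def n_genes(self) -> int:
        return len(self.universe)

    def sizes(self) -> dict[str, int]:
        return {name: len(m) for name, m in self.sets.items()}

    def member_indices(self) -> list[np.ndarray]:
        """Member positions in universe order, one int array per set."""
        return [
            np.fromiter((self._index[g] for g in members), dtype=np.intp)
            for members in self.sets.values()
        ]


# ---------------------------------------------------------------------------
# the statistic
# ---------------------------------------------------------------------------

def _nks_from_positions(positions: np.ndarray, n_genes: int) -> float:
    """nKS from sorted 0-based member positions within a ranked list.

    The running sum decreases strictly between member positions, so its
    maximum is attained at a member position; the prefix sum right after the
    k-th member (rank r_k, 1-based) is k*up - (r_k - k)*down.
    """
    m = positions.size
    if m == 0 or m >= n_genes:
        raise ValueError("set size must satisfy 0 < M < G")
    up = np.sqrt((n_genes - m) / m)
    down = np.sqrt(m / (n_genes - m))
    k = np.arange(1, m + 1, dtype=float)
    ranks = positions + 1.0
    return float(np.max(k * up - (ranks - k) * down))


def normalized_ks(ranked: Sequence[str], members: Iterable[str]) -> float:
    """nKS statistic of a gene set against a ranked gene list.

    ``ranked`` orders all G genes from most to least significant; ``members``
    must be a subset of it with 0 < M < G.
    """
    member_set = set(members)
    n_genes = len(ranked)
    positions = np.fromiter(
        (i for i, g in enumerate(ranked) if g in member_set), dtype=np.intp
    )
    if positions.size != len(member_set):
        raise ValueError("members must all appear in the ranked list")
    return _nks_from_positions(positions, n_genes)


def rank_genes(
    scores: np.ndarray,
    gene_ids: Sequence[str],
    ascending: bool = True,
) -> np.ndarray:
    """Order genes most-significant first; returns indices into ``gene_ids``.

    Ascending order for p-value-like scores, descending for posterior-like
    scores. Ties are broken by the stable order of the input identifiers.
    """
    scores = np.asarray(scores, dtype=float)
    key = scores if ascending else -scores
    return np.argsort(key, kind="stable")


def observed_nks(
    order: np.ndarray, member_indices: Sequence[np.ndarray], n_genes: int
) -> np.ndarray:
    """nKS per pathway for one ranking given as an index order of the universe."""
    position = np.empty(n_genes, dtype=np.intp)
    position[order] = np.arange(n_genes)
    return np.array(
        [_nks_from_positions(np.sort(position[idx]), n_genes) for idx in member_indices]
    )


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def permutation_stats(
    member_indices: Sequence[np.ndarray],
    n_genes: int,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(B, P) matrix of permuted nKS statistics.

    Each of the B rounds draws one gene-label permutation shared by all P
    pathways, mirroring a single relabelling of the ranked list.
    """
    out = np.empty((n_permutations, len(member_indices)))
    for b in range(n_permutations):
        position = rng.permutation(n_genes)
        for j, idx in enumerate(member_indices):
            out[b, j] = _nks_from_positions(np.sort(position[idx]), n_genes)
    return out


def permutation_null(
    ranked_scores: np.ndarray,
    collection: GeneSetCollection,
    n_permutations: int = 100,
    seed: int = 0,
    ascending: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled permutation null and observed nKS per pathway.

    Returns ``(null_pool, observed)`` where ``null_pool`` stacks all
    B*P permuted statistics and ``observed`` aligns with
    ``collection.set_names``.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    member_idx = collection.member_indices()
    order = rank_genes(ranked_scores, collection.universe, ascending=ascending)
    observed = observed_nks(order, member_idx, collection.n_genes)
    null = permutation_stats(member_idx, collection.n_genes, n_permutations, rng)
    return null.ravel(), observed


def permutation_pvalue(observed, null_pool: np.ndarray):
    """(#{null >= observed} + 1) / (len(null) + 1); ties count as >=."""
    null_sorted = np.sort(np.asarray(null_pool, dtype=float))
    if null_sorted.size == 0:
        raise ValueError("null pool is empty")
    observed = np.asarray(observed, dtype=float)
    n_ge = null_sorted.size - np.searchsorted(null_sorted, observed, side="left")
    out = (n_ge + 1) / (null_sorted.size + 1)
    return out.item() if out.ndim == 0 else out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues.copy()
    return multipletests(pvalues, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# single-dataset pipeline
# ---------------------------------------------------------------------------

def single_dataset_gsea(
    scores: np.ndarray,
    collection: GeneSetCollection,
    n_permutations: int = 100,
    seed: int = 0,
    ascending: bool = True,
) -> pd.DataFrame:
    """Full single-dataset enrichment analysis on one significance ranking.

    ``scores`` align with ``collection.universe`` and order genes
    most-significant first (ascending p-values by default). Returns a table
    with columns pathway, nks, pvalue, fdr, rank; rank orders by FDR then
    p-value then pathway name.
    """
    if collection.n_sets == 0:
        raise ValueError("gene set collection is empty")
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (collection.n_genes,):
        raise ValueError("scores must align with the collection universe")
    null_pool, observed = permutation_null(
        scores, collection, n_permutations=n_permutations, seed=seed,
        ascending=ascending,
    )
    pvals = permutation_pvalue(observed, null_pool)
    table = pd.DataFrame(
        {
            "pathway": collection.set_names,
            "nks": observed,
            "pvalue": pvals,
            "fdr": bh_fdr(pvals),
        }
    )
    table["rank"] = rank_table(table)
    return table


def rank_table(table: pd.DataFrame, by: tuple[str, ...] = ("fdr", "pvalue")) -> np.ndarray:
    """1-based ranks ordering a results table by the given columns ascending,
    with pathway name as the final tie-break."""
    order = table.sort_values([*by, "pathway"], kind="stable").index
    ranks = np.empty(len(table), dtype=int)
    ranks[table.index.get_indexer(order)] = np.arange(1, len(table) + 1)
    return ranks
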