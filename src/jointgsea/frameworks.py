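"""The two joint enrichment pipelines.

JointNormKS borrows information at the gene level: gene-wise p-values from
all N datasets are fitted with the joint beta-uniform mixture, each dataset's
genes are re-ranked by their posterior differential probability, and the
normalized KS statistic with a pooled permutation null scores every pathway
within every dataset.

JointPathway borrows at the pathway level: each dataset is first analysed on
its own (nKS + permutation p-value per pathway), and the joint mixture is
then fitted to the P x N matrix of pathway p-values; pathways are ranked by
their posterior enrichment probability per dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import (
    GeneSetCollection,
    bh_fdr,
    observed_nks,
    permutation_pvalue,
    permutation_stats,
    rank_table,
    single_dataset_gsea,
)
from .mixture import (
    MixtureParams,
    PosteriorMatrix,
    PValueMatrix,
    clamp_pvalues,
    fit_em,
    posterior_de,
)

logger = logging.getLogger(__name__)


@dataclass
class StudyBundle:
    """N expression datasets over a shared gene universe with two-group labels.

    ``expressions[i]`` is a (G, n_samples_i) matrix in ``gene_ids`` order;
    ``case_masks[i]`` flags the case (disease) samples of dataset i.
    """

    expressions: list[np.ndarray]
    case_masks: list[np.ndarray]
    gene_ids: Sequence[str]
    dataset_ids: Sequence[str]

    def __post_init__(self) -> None:
        self.expressions = [np.asarray(x, dtype=float) for x in self.expressions]
        self.case_masks = [np.asarray(m, dtype=bool) for m in self.case_masks]
        self.gene_ids = list(self.gene_ids)
        self.dataset_ids = list(self.dataset_ids)
        if not (
            len(self.expressions) == len(self.case_masks) == len(self.dataset_ids)
        ):
            raise ValueError("per-dataset field lengths disagree")
        g = len(self.gene_ids)
        for x, mask, name in zip(self.expressions, self.case_masks, self.dataset_ids):
            if x.shape[0] != g:
                raise ValueError(f"dataset {name!r} does not cover the gene universe")
            if x.shape[1] != mask.size:
                raise ValueError(f"dataset {name!r}: labels do not match samples")
            if mask.sum() < 2 or (~mask).sum() < 2:
                raise ValueError(f"dataset {name!r} needs >= 2 samples per group")

    @property
    def n_datasets(self) -> int:
        return len(self.expressions)


@dataclass
class JointResult:
    """Output of a joint pipeline: per-dataset enrichment tables plus the
    fitted mixture and the intermediate posterior matrix (gene-level for
    JointNormKS, pathway-level for JointPathway)."""

    table: pd.DataFrame
    params: MixtureParams
    posterior: PosteriorMatrix
    gene_pvalues: PValueMatrix


def gene_pvalues(bundle: StudyBundle) -> PValueMatrix:
    """Welch two-sample t-test p-value per gene per dataset, floored.

    Genes with zero variance and equal means in both groups get p = 1; genes
    with zero variance but different means get the p-value floor. Genes
    constant across every sample of a dataset are logged.
    """
    g = len(bundle.gene_ids)
    out = np.empty((g, bundle.n_datasets))
    for i, (x, mask) in enumerate(zip(bundle.expressions, bundle.case_masks)):
        case, ctrl = x[:, mask], x[:, ~mask]
        constant = (np.ptp(x, axis=1) == 0)
        if constant.any():
            logger.warning(
                "dataset %s: %d genes constant across all samples",
                bundle.dataset_ids[i], int(constant.sum()),
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False).pvalue
        nan = ~np.isfinite(p)
        if nan.any():
            equal_means = np.isclose(case.mean(axis=1), ctrl.mean(axis=1))
            p = np.where(nan, np.where(equal_means, 1.0, 0.0), p)
        out[:, i] = p
    return clamp_pvalues(out, bundle.gene_ids, bundle.dataset_ids)


def _posterior_order(posterior: np.ndarray, raw_p: np.ndarray) -> np.ndarray:
    """Rank genes by descending posterior; ties by ascending raw p-value,
    then by the stable universe order."""
    return np.lexsort((raw_p, -posterior))


def joint_norm_ks(
    bundle: StudyBundle,
    collection: GeneSetCollection,
    n_permutations: int = 100,
    seed: int = 0,
    params: MixtureParams | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> JointResult:
    """Gene-level joint enrichment analysis (JointNormKS).

    Steps: (1) gene-wise Welch p-values per dataset; (2) joint beta-uniform
    mixture fitted by EM (or ``params`` if supplied); (3) genes re-ranked per
    dataset by posterior Pr(D_i=1 | p_g), nKS and pooled permutation
    p-values on that ranking; (4) BH FDR and rank per dataset.
    """
    if bundle.gene_ids != collection.universe:
        raise ValueError("bundle genes must match the collection universe order")
    pvals = gene_pvalues(bundle)
    if params is None:
        params = fit_em(pvals, tol=tol, max_iter=max_iter)
    post = posterior_de(pvals, params)

    member_idx = collection.member_indices()
    n_genes = collection.n_genes
    # the permuted statistics do not depend on the ranking, so one pooled
    # null serves every dataset
    rng = np.random.default_rng(seed)
    null_pool = permutation_stats(member_idx, n_genes, n_permutations, rng).ravel()
    frames = []
    for i, dataset in enumerate(bundle.dataset_ids):
        order = _posterior_order(post.values[:, i], pvals.values[:, i])
        observed = observed_nks(order, member_idx, n_genes)
        pv = permutation_pvalue(observed, null_pool)
        frame = pd.DataFrame(
            {
                "pathway": collection.set_names,
                "dataset": dataset,
                "nks": observed,
                "pvalue": pv,
                "fdr": bh_fdr(pv),
            }
        )
        frame["rank"] = rank_table(frame)
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    return JointResult(table=table, params=params, posterior=post, gene_pvalues=pvals)


def joint_pathway(
    bundle: StudyBundle,
    collection: GeneSetCollection,
    n_permutations: int = 100,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> JointResult:
    """Pathway-level joint enrichment analysis (JointPathway).

    Steps: (1) per-dataset nKS + pooled permutation p-value per pathway;
    (2) joint mixture fitted by EM on the P x N pathway p-value matrix;
    (3) per-dataset posterior enrichment probability per pathway, ranked
    descending. A BH FDR on the pathway-level permutation p-values is
    reported as a supplementary column.
    """
    if bundle.gene_ids != collection.universe:
        raise ValueError("bundle genes must match the collection universe order")
    pvals = gene_pvalues(bundle)

    # one shared pooled null (the permuted statistics are ranking-free)
    singles = [
        single_dataset_gsea(
            pvals.values[:, i], collection, n_permutations=n_permutations,
            seed=seed,
        )
        for i in range(bundle.n_datasets)
    ]
    pathway_p = np.column_stack([t["pvalue"].to_numpy() for t in singles])
    pathway_pvals = clamp_pvalues(pathway_p, collection.set_names, bundle.dataset_ids)
    params = fit_em(pathway_pvals, tol=tol, max_iter=max_iter)
    post = posterior_de(pathway_pvals, params)

    frames = []
    for i, dataset in enumerate(bundle.dataset_ids):
        frame = pd.DataFrame(
            {
                "pathway": collection.set_names,
                "dataset": dataset,
                "nks": singles[i]["nks"].to_numpy(),
                "pvalue": singles[i]["pvalue"].to_numpy(),
                "posterior": post.values[:, i],
                "fdr": bh_fdr(singles[i]["pvalue"].to_numpy()),
            }
        )
        order = frame.sort_values(
            ["posterior", "pvalue", "pathway"],
            ascending=[False, True, True],
            kind="stable",
        ).index
        ranks = np.empty(len(frame), dtype=int)
        ranks[order] = np.arange(1, len(frame) + 1)
        frame["rank"] = ranks
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    return JointResult(table=table, params=params, posterior=post, gene_pvalues=pvals)
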