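"""Two-disease simulation benchmark: synthetic expression studies with known
differential genes and enriched pathways, plus the ROC/AUC harness comparing
the joint pipelines against single-dataset analysis and the MAPE baselines.

The design simulates two similar diseases sharing a configurable fraction of
their differential (DE) genes and of their enriched pathways. Every pathway
holds 50 genes; a non-enriched pathway carries the background expectation of
5 DE genes per dataset, an enriched pathway carries the enrichment strength
(10 = 20% or 15 = 30% of its members). Two scenarios control how an enriched
pathway's DE members overlap across diseases: in scenario 1 the smaller DE
complement is fully shared; in scenario 2 the DE members of the two diseases
do not overlap at all.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .enrichment import GeneSetCollection, single_dataset_gsea
from .frameworks import StudyBundle, gene_pvalues, joint_norm_ks, joint_pathway
from .mape import mape_gene, mape_i, mape_pathway

#: Expected DE genes per pathway when membership is random (50 * 1000/10000).
BACKGROUND_DE = 5


@dataclass(frozen=True)
class SimConfig:
    """Study-design constants of the simulation.

    Defaults are the full-scale design: 10,000 genes with 1,000 DE per
    dataset, 1,000 pathways of 50 genes with 100 enriched per dataset.
    ``de_similarity`` is the fraction of DE genes shared between the two
    diseases and ``shared_enriched`` the count of jointly enriched pathways.
    """

    n_genes: int = 10_000
    n_de: int = 1_000
    de_similarity: float = 0.9
    n_pathways: int = 1_000
    pathway_size: int = 50
    n_enriched: int = 100
    shared_enriched: int = 90
    enrichment_strength: int = 10
    scenario: int = 1
    samples_per_group: int = 20
    effect_size: float = 1.0
    n_replicates: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2):
            raise ValueError("scenario must be 1 or 2")
        if not 0.0 <= self.de_similarity <= 1.0:
            raise ValueError("de_similarity must lie in [0, 1]")
        if self.shared_enriched > self.n_enriched:
            raise ValueError("shared enriched pathways cannot exceed the marginal count")
        if 2 * self.n_enriched - self.shared_enriched > self.n_pathways:
            raise ValueError("enriched pathway counts exceed the number of pathways")
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed n_genes")
        if self.effect_size != 0 and self.enrichment_strength <= BACKGROUND_DE:
            raise ValueError(
                f"enrichment strength must exceed the background of {BACKGROUND_DE} "
                "DE genes per pathway"
            )
        if self.enrichment_strength > self.pathway_size:
            raise ValueError("enrichment strength cannot exceed pathway size")

    @property
    def n_shared_de(self) -> int:
        return round(self.de_similarity * self.n_de)


def scaled_config(**overrides) -> SimConfig:
    """Reduced problem size preserving the full design's ratios.

    2,000 genes / 200 DE / 200 pathways / 20 enriched per dataset; the
    default 90% pathway similarity becomes 18 shared enriched pathways.
    """
    base = dict(
        n_genes=2_000,
        n_de=200,
        n_pathways=200,
        n_enriched=20,
        shared_enriched=18,
        n_replicates=10,
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class SimulatedStudy:
    """One simulated two-disease study with its ground truth."""

    bundle: StudyBundle
    collection: GeneSetCollection
    de_labels: np.ndarray          # (G, 2) bool: DE status per dataset
    enrichment_labels: np.ndarray  # (P, 2) bool: enrichment status per dataset
    pathway_classes: list[tuple[bool, bool]]
    config: SimConfig


# ---------------------------------------------------------------------------
# ground-truth construction
# ---------------------------------------------------------------------------

def assign_de_labels(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw per-dataset DE labels with the configured overlap.

    Exactly ``n_de`` genes are DE in each dataset, ``n_shared_de`` of them in
    both; shared and dataset-specific genes are drawn uniformly without
    replacement from the universe.
    """
    shared = config.n_shared_de
    specific = config.n_de - shared
    if shared + 2 * specific > config.n_genes:
        raise ValueError("DE gene counts are infeasible for this universe size")
    picks = rng.choice(config.n_genes, size=shared + 2 * specific, replace=False)
    labels = np.zeros((config.n_genes, 2), dtype=bool)
    labels[picks[:shared], :] = True
    labels[picks[shared:shared + specific], 0] = True
    labels[picks[shared + specific:], 1] = True
    assert labels[:, 0].sum() == labels[:, 1].sum() == config.n_de
    assert (labels.all(axis=1)).sum() == shared
    return labels


def pathway_composition(
    scenario: int,
    strength: int,
    enriched: tuple[bool, bool],
    pathway_size: int = 50,
    background: int = BACKGROUND_DE,
) -> tuple[int, int, int, int]:
    """Member counts (n00, n10, n01, n11) of one pathway by DE stratum.

    ``n10`` counts members DE only in dataset 1, ``n01`` only in dataset 2,
    ``n11`` in both, ``n00`` in neither. A dataset in which the pathway is
    enriched receives ``strength`` DE members, otherwise the background
    count. Scenario 1 shares as many DE members as possible across diseases;
    scenario 2 shares none for pathways enriched in either disease
    (non-enriched pathways keep the background overlap in both scenarios).
    """
    k1 = strength if enriched[0] else background
    k2 = strength if enriched[1] else background
    if scenario == 1 or not any(enriched):
        n11 = min(k1, k2)
    else:
        n11 = 0
    n10, n01 = k1 - n11, k2 - n11
    n00 = pathway_size - n10 - n01 - n11
    if n00 < 0:
        raise ValueError("pathway composition exceeds pathway size")
    return n00, n10, n01, n11


def build_pathways(
    config: SimConfig, de_labels: np.ndarray, rng: np.random.Generator
) -> tuple[GeneSetCollection, np.ndarray, list[tuple[bool, bool]]]:
    """Sample pathway memberships stratified by joint DE status.

    Dataset 1's enriched pathways occupy indices 0..n_enriched-1 and dataset
    2's a window shifted so that exactly ``shared_enriched`` indices overlap;
    designs differing only in pathway similarity therefore disagree on the
    class of just a few pathways. Members are drawn without replacement
    within a pathway from the four DE strata in exactly the counts of
    :func:`pathway_composition`, using one spawned random stream per pathway
    (again so that similarity settings share draws); genes may recur across
    pathways.
    """
    strata = {
        (0, 0): np.flatnonzero(~de_labels[:, 0] & ~de_labels[:, 1]),
        (1, 0): np.flatnonzero(de_labels[:, 0] & ~de_labels[:, 1]),
        (0, 1): np.flatnonzero(~de_labels[:, 0] & de_labels[:, 1]),
        (1, 1): np.flatnonzero(de_labels[:, 0] & de_labels[:, 1]),
    }
    start2 = config.n_enriched - config.shared_enriched
    classes: list[tuple[bool, bool]] = [
        (p < config.n_enriched, start2 <= p < start2 + config.n_enriched)
        for p in range(config.n_pathways)
    ]
    sets: dict[str, list[str]] = {}
    enrichment = np.zeros((config.n_pathways, 2), dtype=bool)
    width = len(str(config.n_pathways - 1))
    streams = rng.spawn(config.n_pathways)
    for p, enr in enumerate(classes):
        counts = pathway_composition(
            config.scenario, config.enrichment_strength, enr, config.pathway_size
        )
        members: list[int] = []
        for key, cnt in zip([(0, 0), (1, 0), (0, 1), (1, 1)], counts):
            if cnt == 0:
                continue
            pool = strata[key]
            if pool.size < cnt:
                raise ValueError(
                    f"stratum {key} has only {pool.size} genes but {cnt} are needed"
                )
            members.extend(streams[p].choice(pool, size=cnt, replace=False))
        sets[f"pathway{p:0{width}d}"] = [f"gene{g}" for g in members]
        enrichment[p] = enr
    universe = [f"gene{g}" for g in range(config.n_genes)]
    return GeneSetCollection(sets, universe), enrichment, classes


def generate_expression(
    config: SimConfig, de_labels: np.ndarray, rng: np.random.Generator
) -> StudyBundle:
    """Normal mean-shift expression model for the two datasets.

    Each gene draws a baseline mean mu ~ Uniform(5, 9) and standard deviation
    sigma ~ Uniform(0.5, 1.5), shared across datasets. Controls are
    N(mu, sigma^2); cases of a gene that is DE in a dataset are shifted by
    ``effect_size * sigma`` with a random sign per gene-dataset pair.
    """
    g = config.n_genes
    n = config.samples_per_group
    mu = rng.uniform(5.0, 9.0, size=g)
    sigma = rng.uniform(0.5, 1.5, size=g)
    expressions, masks = [], []
    for i in range(2):
        x = rng.normal(mu[:, None], sigma[:, None], size=(g, 2 * n))
        sign = rng.choice([-1.0, 1.0], size=g)
        shift = np.where(de_labels[:, i], sign * config.effect_size * sigma, 0.0)
        x[:, :n] += shift[:, None]  # first n samples are cases
        mask = np.zeros(2 * n, dtype=bool)
        mask[:n] = True
        expressions.append(x)
        masks.append(mask)
    return StudyBundle(
        expressions=expressions,
        case_masks=masks,
        gene_ids=[f"gene{j}" for j in range(g)],
        dataset_ids=["disease1", "disease2"],
    )


def simulate_study(config: SimConfig, seed: int | None = None) -> SimulatedStudy:
    """Generate one complete two-disease study from a design configuration.

    Expression is drawn before pathway membership so that designs differing
    only in their pathway-level settings share identical gene-level data for
    the same seed (paired comparisons across pathway-similarity settings).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    de_labels = assign_de_labels(config, rng)
    bundle = generate_expression(config, de_labels, rng)
    collection, enrichment, classes = build_pathways(config, de_labels, rng)
    return SimulatedStudy(
        bundle=bundle,
        collection=collection,
        de_labels=de_labels,
        enrichment_labels=enrichment,
        pathway_classes=classes,
        config=config,
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def auc_score(scores: np.ndarray, truth: np.ndarray) -> float:
    """Mann–Whitney AUC: probability an enriched pathway outscores a
    non-enriched one, ties counting one half."""
    truth = np.asarray(truth, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if truth.all() or not truth.any():
        raise ValueError("AUC undefined when truth labels are constant")
    return float(roc_auc_score(truth, scores))


def _scores_single(study, n_permutations, seed):
    pvals = gene_pvalues(study.bundle)
    return {
        ds: single_dataset_gsea(
            pvals.values[:, i], study.collection,
            n_permutations=n_permutations, seed=seed + i,
        )["nks"].to_numpy()
        for i, ds in enumerate(study.bundle.dataset_ids)
    }


def _scores_joint_norm_ks(study, n_permutations, seed):
    result = joint_norm_ks(
        study.bundle, study.collection, n_permutations=n_permutations, seed=seed
    )
    return {
        ds: sub.set_index("pathway")["nks"]
        .loc[study.collection.set_names]
        .to_numpy()
        for ds, sub in result.table.groupby("dataset")
    }


def _scores_joint_pathway(study, n_permutations, seed):
    result = joint_pathway(
        study.bundle, study.collection, n_permutations=n_permutations, seed=seed
    )
    out = {}
    for ds, sub in result.table.groupby("dataset"):
        sub = sub.set_index("pathway").loc[study.collection.set_names]
        # posterior saturates; break ties with the dataset's own pathway p-value
        out[ds] = sub["posterior"].to_numpy() - 1e-6 * sub["pvalue"].to_numpy()
    return out


def _mape_scores(table, study):
    scores = table.set_index("pathway")["stat"].loc[study.collection.set_names]
    return {ds: scores.to_numpy() for ds in study.bundle.dataset_ids}


def _scores_mape_gene(study, n_permutations, seed):
    return _mape_scores(
        mape_gene(study.bundle, study.collection, n_permutations, seed), study
    )


def _scores_mape_pathway(study, n_permutations, seed):
    return _mape_scores(
        mape_pathway(study.bundle, study.collection, n_permutations, seed), study
    )


def _scores_mape_i(study, n_permutations, seed):
    return _mape_scores(
        mape_i(study.bundle, study.collection, n_permutations, seed), study
    )


#: Benchmark methods: each maps a study to per-dataset pathway scores where
#: larger means more enriched. MAPE methods yield one shared ranking that is
#: scored against each dataset's truth.
METHODS: Mapping[str, Callable] = {
    "single": _scores_single,
    "jointnormks": _scores_joint_norm_ks,
    "jointpathway": _scores_joint_pathway,
    "mape_gene": _scores_mape_gene,
    "mape_pathway": _scores_mape_pathway,
    "mape_i": _scores_mape_i,
}


def run_benchmark(
    configs: Iterable[SimConfig],
    methods: Sequence[str] = ("single", "jointnormks"),
    n_permutations: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """AUC benchmark over a grid of designs.

    For every configuration and replicate one study is generated and shared
    by all methods; each method's per-dataset pathway scores are scored
    against that dataset's enrichment truth. Returns one row per
    (configuration, replicate, method, dataset) with the AUC and the method
    runtime in seconds.
    """
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise ValueError(f"unknown methods: {unknown}; choose from {list(METHODS)}")
    rows = []
    for config in configs:
        for rep in range(config.n_replicates):
            study_seed = (seed + 7919 * rep) % (2**31)
            study = simulate_study(config, seed=study_seed)
            truth = study.enrichment_labels
            for method in methods:
                start = time.perf_counter()
                scores = METHODS[method](study, n_permutations, study_seed)
                elapsed = time.perf_counter() - start
                for i, ds in enumerate(study.bundle.dataset_ids):
                    rows.append(
                        {
                            "scenario": config.scenario,
                            "strength": config.enrichment_strength,
                            "de_similarity": config.de_similarity,
                            "shared_enriched": config.shared_enriched,
                            "effect_size": config.effect_size,
                            "replicate": rep,
                            "method": method,
                            "dataset": ds,
                            "auc": auc_score(scores[ds], truth[:, i]),
                            "runtime_s": elapsed,
                        }
                    )
    return pd.DataFrame(rows)


def summarize_benchmark(report: pd.DataFrame) -> pd.DataFrame:
    """Mean AUC per (design, method) over replicates and datasets."""
    keys = ["scenario", "strength", "de_similarity", "shared_enriched",
            "effect_size", "method"]
    return (
        report.groupby(keys, as_index=False)["auc"]
        .mean()
        .rename(columns={"auc": "mean_auc"})
    )
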