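"""Joint pipelines: gene p-values, JointNormKS, JointPathway."""

import numpy as np
import pytest
from scipy import stats

from jointgsea import (
    MixtureParams,
    StudyBundle,
    gene_pvalues,
    joint_norm_ks,
    joint_pathway,
    scaled_config,
    simulate_study,
    single_dataset_gsea,
)


def _bundle_from_arrays(arrays, n_case):
    masks = []
    for x in arrays:
        mask = np.zeros(x.shape[1], dtype=bool)
        mask[:n_case] = True
        masks.append(mask)
    return StudyBundle(
        expressions=arrays,
        case_masks=masks,
        gene_ids=[f"g{i}" for i in range(arrays[0].shape[0])],
        dataset_ids=[f"d{i}" for i in range(len(arrays))],
    )


def test_gene_pvalues_identical_groups_give_p_one():
    block = np.tile(np.arange(6.0), (4, 1))  # cases identical to controls
    bundle = _bundle_from_arrays([np.hstack([block, block])], n_case=6)
    pv = gene_pvalues(bundle)
    np.testing.assert_allclose(pv.values, 1.0)


def test_gene_pvalues_strong_separation_hits_floor(rng):
    case = rng.normal(5.0, 1.0, size=(3, 20))
    ctrl = rng.normal(0.0, 1.0, size=(3, 20))
    bundle = _bundle_from_arrays([np.hstack([case, ctrl])], n_case=20)
    pv = gene_pvalues(bundle)
    assert np.all(pv.values < 1e-9)


def test_gene_pvalues_match_per_gene_welch(rng):
    x = rng.normal(size=(25, 16))
    bundle = _bundle_from_arrays([x], n_case=7)
    pv = gene_pvalues(bundle)
    for g in range(25):
        expected = stats.ttest_ind(x[g, :7], x[g, 7:], equal_var=False).pvalue
        assert pv.values[g, 0] == pytest.approx(expected, rel=1e-12)


def test_bundle_validation_rejects_tiny_groups(rng):
    x = rng.normal(size=(5, 4))
    with pytest.raises(ValueError, match="2 samples per group"):
        _bundle_from_arrays([x], n_case=1)


@pytest.fixture(scope="module")
def small_study():
    config = scaled_config(
        n_genes=400, n_de=40, de_similarity=0.8, n_pathways=40, n_enriched=8,
        shared_enriched=6, enrichment_strength=10, n_replicates=1,
    )
    return simulate_study(config, seed=5)


def test_joint_norm_ks_single_dataset_reduces_to_gsea(small_study):
    """With N=1 the joint pipeline is exactly single-dataset GSEA."""
    bundle = small_study.bundle
    solo = StudyBundle(
        expressions=bundle.expressions[:1],
        case_masks=bundle.case_masks[:1],
        gene_ids=bundle.gene_ids,
        dataset_ids=bundle.dataset_ids[:1],
    )
    result = joint_norm_ks(solo, small_study.collection, n_permutations=20, seed=4)
    pv = gene_pvalues(solo)
    reference = single_dataset_gsea(
        pv.values[:, 0], small_study.collection, n_permutations=20, seed=4
    )
    sub = result.table.drop(columns="dataset").reset_index(drop=True)
    assert sub.equals(reference)


def test_joint_norm_ks_factorized_prior_matches_gsea_ranking(small_study):
    """An independence (product) prior makes each dataset's posterior a
    monotone transform of its own p-values, reproducing the single-dataset
    pathway ranking."""
    marginals = [np.array([0.8, 0.2]), np.array([0.7, 0.3])]
    prior = np.array(
        [marginals[0][k & 1] * marginals[1][(k >> 1) & 1] for k in range(4)]
    )
    params = MixtureParams(prior, np.array([0.3, 0.4]))
    result = joint_norm_ks(
        small_study.bundle, small_study.collection, n_permutations=20, seed=4,
        params=params,
    )
    pv = result.gene_pvalues
    for i, dataset in enumerate(small_study.bundle.dataset_ids):
        reference = single_dataset_gsea(
            pv.values[:, i], small_study.collection, n_permutations=20, seed=4
        )
        sub = (
            result.table[result.table["dataset"] == dataset]
            .drop(columns="dataset")
            .reset_index(drop=True)
        )
        assert sub.equals(reference)


def test_joint_norm_ks_reproducible(small_study):
    kwargs = dict(n_permutations=15, seed=11)
    r1 = joint_norm_ks(small_study.bundle, small_study.collection, **kwargs)
    r2 = joint_norm_ks(small_study.bundle, small_study.collection, **kwargs)
    assert r1.table.equals(r2.table)
    np.testing.assert_array_equal(r1.posterior.values, r2.posterior.values)


def test_joint_pathway_identical_datasets_symmetric(small_study):
    bundle = small_study.bundle
    twin = StudyBundle(
        expressions=[bundle.expressions[0], bundle.expressions[0].copy()],
        case_masks=[bundle.case_masks[0], bundle.case_masks[0].copy()],
        gene_ids=bundle.gene_ids,
        dataset_ids=["a", "b"],
    )
    result = joint_pathway(twin, small_study.collection, n_permutations=15, seed=2)
    np.testing.assert_allclose(
        result.posterior.values[:, 0], result.posterior.values[:, 1], atol=1e-12
    )


def test_joint_pathway_single_dataset_ranks_by_pathway_pvalue(small_study):
    bundle = small_study.bundle
    solo = StudyBundle(
        expressions=bundle.expressions[:1],
        case_masks=bundle.case_masks[:1],
        gene_ids=bundle.gene_ids,
        dataset_ids=bundle.dataset_ids[:1],
    )
    result = joint_pathway(solo, small_study.collection, n_permutations=20, seed=6)
    table = result.table
    # posterior ranking must agree with the pathway p-value ordering
    by_posterior = table.sort_values("rank")["pvalue"].to_numpy()
    assert np.all(np.diff(by_posterior) >= 0)


def test_joint_tables_cover_all_pathways_per_dataset(small_study):
    result = joint_pathway(
        small_study.bundle, small_study.collection, n_permutations=10, seed=1
    )
    for _, sub in result.table.groupby("dataset"):
        assert sorted(sub["pathway"]) == sorted(small_study.collection.set_names)
        assert sorted(sub["rank"]) == list(range(1, small_study.collection.n_sets + 1))


def test_gene_universe_mismatch_rejected(small_study, small_collection):
    with pytest.raises(ValueError, match="universe"):
        joint_norm_ks(small_study.bundle, small_collection, n_permutations=5)
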