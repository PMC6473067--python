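# jointgsea

Joint gene set enrichment analysis across similar disease transcriptome
datasets.

## The problem

Gene set (pathway) enrichment analysis asks whether the members of a
predefined gene set sit unusually high in a list of genes ranked by
differential-expression evidence between two sample groups. When a disease
study is small, single-dataset enrichment analysis lacks power — but public
repositories hold expression studies of *similar* diseases that plausibly
share dysregulated genes and pathways. `jointgsea` implements a joint
analysis framework that borrows strength across N such datasets instead of
forcing the all-or-nothing concordance assumption of classic meta-analysis.

## The model

Within one dataset, p-values are modelled by a beta-uniform mixture:
null features are Uniform(0,1), differential features Beta(α, 1) with
α ∈ (0, 1):

    f(p) = Pr(D=1) · α p^(α−1) + (1 − Pr(D=1))

Across N datasets a feature has a binary configuration (D₁, …, D_N) of
differential status, and the joint density places a prior over all 2^N
configurations:

    f(p_g) = Σ_{D₁…D_N} Pr(D₁…D_N) · Π_i f(p_gi | D_i)

The configuration prior and the shape vector α are estimated by EM
(uniform prior and α = 0.5 at initialization); the quantity of interest is
the per-dataset posterior Pr(D_i = 1 | p_g1, …, p_gN), through which a gene
weakly significant in one disease is promoted when the similar disease
supports it.

Enrichment of a pathway with M of G genes is scored by the normalized
Kolmogorov–Smirnov statistic: walk the ranked gene list accumulating
+√((G−M)/M) at members and −√(M/(G−M)) elsewhere and take the maximum of
the running sum. Significance comes from B gene-label permutations pooled
across all P pathways, p = (#{null ≥ observed} + 1)/(B·P + 1), with
Benjamini–Hochberg FDR control.

Two pipelines combine these pieces:

* **JointNormKS** (gene level) — joint mixture on gene p-values, re-rank
  each dataset's genes by posterior, then nKS + permutation p-values + FDR.
* **JointPathway** (pathway level) — per-dataset nKS p-values first, then
  the joint mixture on the P×N pathway p-value matrix; pathways ranked by
  posterior enrichment probability.

Baselines for comparison: per-dataset single analysis and the MAPE
meta-analysis family (MAPE_Gene, MAPE_Pathway, MAPE_I) built on the maxP
combination rule. A simulation module generates two-disease studies with
exact ground truth (shared/specific DE genes and enriched pathways, two
overlap scenarios) and an ROC/AUC benchmark harness compares all methods.

## Worked example

```python
from jointgsea import (scaled_config, simulate_study, joint_norm_ks,
                       significant_pathways)

config = scaled_config(scenario=2, seed=7)       # 2,000 genes, 200 pathways
study = simulate_study(config)
result = joint_norm_ks(study.bundle, study.collection,
                       n_permutations=50, seed=7)
print("alpha:", result.params.alpha.round(3))
print("prior:", result.params.config_prior.round(3))
hits = significant_pathways(
    result.table[result.table["dataset"] == "disease1"], cutoff=0.1)
print(len(hits), "significant pathways")
print(hits.head(3).to_string(index=False))
```

prints

```
alpha: [0.235 0.25 ]
prior: [0.829 0.    0.    0.171]
15 significant pathways
   pathway  dataset        nks  pvalue      fdr  rank
pathway011 disease1 108.727016  0.0001 0.013332     1
pathway017 disease1  98.799071  0.0002 0.013332     2
pathway019 disease1  97.838302  0.0002 0.013332     3
```

The fitted shapes (α ≈ 0.24 per disease) say both datasets carry strong
differential signal; the configuration prior puts essentially all mass on
"null in both" (0.83) and "differential in both" (0.17), reflecting the 90%
DE-gene overlap of this design. At an FDR cutoff of 0.1 the pipeline
recovers 15 of the 20 truly enriched pathways of dataset 1; scoring the
full ranking against the ground truth gives AUC ≈ 0.99 in both datasets.

A command-line interface mirrors the library (`jointgsea run-joint`,
`run-single`, `run-mape`, `simulate`, `benchmark`); see `jointgsea --help`.

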