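# Methods

## Joint beta-uniform mixture of p-values

Each feature (gene, or pathway in the pathway-level pipeline) carries one
p-value per dataset. Null p-values are Uniform(0,1); differential p-values
follow Beta(α, 1) with α ∈ (0, 1), density α p^(α−1). Across N datasets a
feature's status is a binary configuration (D₁, …, D_N); conditional on the
configuration, p-values are independent, so the joint density is the
configuration-prior-weighted product of per-dataset component densities.

Parameters are the 2^N-vector configuration prior and the shape vector α,
fitted by EM:

* **E-step.** Posterior over configurations per feature: prior × conditional
  density, normalized. Computed in log space (p^(α−1) overflows as p → 0);
  the all-null configuration always has density 1, so no posterior row can
  vanish.
* **M-step.** The prior update is the column mean of the configuration
  posterior. Each α_j is the weighted Beta(α,1) maximum-likelihood estimate
  Σ_g w_gj / Σ_g w_gj(−log p_gj), where w_gj is the feature's posterior
  mass on configurations with D_j = 1, clipped into [1e-4, 1−1e-4] to keep
  it inside the open unit interval that the beta component requires. If a
  dataset receives zero weight its shape is left unchanged with a warning.
* **Initialization and stopping.** Uniform prior, all α = 0.5, a single
  deterministic start (no restarts). Iteration stops when the relative
  change in marginal log-likelihood falls below 1e-8 (configurable) or
  after 1,000 iterations. The log-likelihood trace is retained and is
  non-decreasing up to 1e-8 numerical slack (the α clip can in principle
  break exact monotonicity; in practice it binds only on no-signal data).

Configurations are encoded as integers with dataset 0 as the least
significant bit. The per-dataset posterior Pr(D_i = 1 | p_g) sums the
configuration posterior over configurations with bit i set. Incoming
p-values are floored at 1e-10 so −log p stays finite (permutation p-values
are bounded away from zero by construction, t-test p-values are not). N is
capped at 10: the prior grows as 2^N and no hierarchical approximation is
implemented.

**Identifiability caveat.** As α → 1 the beta component collapses onto the
uniform density and the configuration prior becomes unidentifiable. On
data with no signal EM therefore drives α to its ceiling while the prior
stalls near its initialization; the fitted α, not the prior mass on the
all-null configuration, is the reliable no-signal diagnostic. With genuine
signal (α well below 1) both the prior and α are recovered accurately
(parameter-recovery test: N = 2, G = 10,000, α = (0.3, 0.4), dependent
prior; errors within ±0.05 / ±0.03 in ≥ 90% of replicates).

## Normalized KS enrichment statistic

Genes are ordered most-significant first — ascending p-value, or descending
posterior in the joint pipeline, with posterior ties broken by the
dataset's own p-value ascending and then by stable input order (posteriors
saturate at 1 under strong signal, so the tie-break preserves within-dataset
evidence). For a pathway with M of G genes the running sum gains
+√((G−M)/M) at members and −√(M/(G−M)) at non-members; the increments sum
to zero over the full list, so the maximum prefix sum (the statistic) is
non-negative and size-normalized. Because the sum strictly decreases
between member positions, the implementation evaluates it only at member
ranks.

The null is built by permuting gene labels: each of B rounds draws one
permutation shared by all P pathways, and all B·P permuted statistics are
pooled. The p-value is (#{null ≥ observed} + 1)/(B·P + 1), so its minimum
is 1/(B·P+1) and values are multiples of that unit. B defaults to 100
(50 in the scaled benchmark). Permuted statistics depend on the permutation
only through member positions — not on the ranking scores — so one pooled
null serves every dataset of a study. Pooling across pathways follows the
printed procedure even though it mixes set sizes when sizes differ; a
per-size stratified null would be the conservative alternative and is left
to the caller by filtering the collection to one size. Benjamini–Hochberg
FDR (statsmodels) is applied per dataset; pathways are ranked by FDR, then
p-value, then name.

## Pipelines

**JointNormKS**: Welch two-sample t-test p-values per gene per dataset
(no equal-variance assumption; zero-variance genes with equal means get
p = 1) → joint mixture EM → per-dataset posterior ranking → nKS +
permutation p-value + FDR. With N = 1 or an independence (product-form)
prior the posterior is a monotone transform of the dataset's own p-values
and the pipeline reproduces single-dataset GSEA exactly (verified in
tests).

**JointPathway**: per-dataset nKS permutation p-values → joint mixture on
the P×N pathway p-value matrix → per-dataset posterior enrichment
probability, ranked descending. The output table also carries a BH FDR of
the pathway-level permutation p-values as a supplementary column for
interface uniformity with the other pipelines.

**MAPE baselines**: maxP combination (row-wise maximum p-value — a feature
must be significant everywhere). MAPE_Gene ranks genes by maxP and runs the
nKS test on that single ranking. MAPE_Pathway combines per-dataset pathway
p-values by maxP and calibrates the combined statistic against the maxP of
per-permutation pathway p-values, combined exactly as the observed ones
(small is significant, so the count direction flips). MAPE_I takes the
minimum of a pathway's MAPE_Gene and MAPE_Pathway p-values with the
analogous min-combined permutation null. The per-dataset permutation
rounds use distinct streams so the combined nulls pair independent
components, mirroring independent studies under the null.

## Simulation design

Two diseases, G = 10,000 genes, 1,000 DE genes per dataset with a shared
fraction of 0.6–0.9; 1,000 pathways of exactly 50 genes, 100 enriched per
dataset with 60–90 shared. A random 50-gene pathway is expected to contain
5 DE genes, so non-enriched pathways carry exactly that background count
and enriched pathways carry the enrichment strength (10 = 20% or
15 = 30% of members). Pathway members are drawn without replacement within
a pathway from the four joint-DE strata (DE in neither / only one / both)
in exact per-class counts; scenario 1 shares as many DE members as
possible between the diseases, scenario 2 shares none within enriched
pathways. Genes may belong to several pathways.

Expression values use a Normal mean-shift model: per gene a baseline mean
μ ~ Uniform(5, 9) and σ ~ Uniform(0.5, 1.5) drawn once and shared across
datasets; controls are N(μ, σ²) and cases of a DE gene are shifted by
±(effect size)·σ with random sign per gene-dataset pair. Defaults: 20
samples per group, effect size 1.0 — chosen so that single-dataset AUC sits
mid-range rather than saturating, the regime in which methods are
distinguishable. These distributional choices are this package's own
stand-in for an external generation recipe and are fully configurable.

What the generator does **not** emulate: gene-gene correlation,
heavy-tailed or count-distributed expression, batch effects, unequal group
sizes, and pathway-pathway dependence beyond shared genes. Passing
benchmarks here demonstrate correct mechanics and the expected qualitative
orderings under the model's assumptions, not performance on real
microarray or RNA-seq data.

Benchmarking scores each method's per-dataset pathway ranking (the raw
statistic: nKS, posterior, or combined p-value — finer-grained than the
discretized permutation p-values) against that dataset's enrichment truth
with the Mann–Whitney AUC (ties half-credit); MAPE's single combined
ranking is scored against each dataset's truth separately. All methods see
identical studies within a replicate. Studies are generated
DE-labels → expression → pathways, with one spawned random stream per
pathway and a sliding-window layout of enriched pathway indices, so designs
differing only in pathway similarity share their gene-level data and most
pathway draws — paired comparisons that sharpen similarity-sweep contrasts
at fixed replicate counts.

## Problem sizes and tolerances

The default test and benchmark scale is G = 2,000, 200 DE genes, P = 200
pathways, 20 enriched (18 shared at 90% similarity), B = 50 permutations,
10 replicates — the full paper-scale design divided by five with all
ratios preserved; full scale is available by constructing `SimConfig`
directly. Exact checks (enumeration oracle, prefix-sum oracle, BH
reference) use 1e-12 absolute tolerance; EM monotonicity allows 1e-8;
stochastic checks (recovery rates, AUC orderings, null calibration in
[0.45, 0.55]) run at fixed seeds.

## Known limitations

* Gene set independence is assumed; overlapping sets share evidence
  without adjustment.
* The pooled permutation null mixes pathway sizes when sizes differ.
* N > 10 datasets are rejected rather than approximated.
* The no-signal regime identifies α but not the configuration prior (see
  the identifiability caveat above).
* MAPE implementations follow published outlines with this package's
  permutation machinery; they are comparison baselines, not a faithful
  port of the original software.
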