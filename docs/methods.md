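# Methods

This note documents the models, defaults and numerical choices behind
`phodnet`, and what the synthetic benchmarks do and do not demonstrate.

## Data model

The universal input is a taxon × sample count table with exact,
case-sensitive identifier matching. Missing cells are illegal rather than
imputed: the downstream statistics are correlation-based, and silent
imputation would bias every pairwise estimate. Relative abundance is plain
column closure (each sample sums to 1) and is idempotent.

## Diversity and niche metrics

Shannon entropy uses the natural logarithm by default (configurable base);
zero counts are excluded from the sum. Chao1 is S_obs + F₁²/(2F₂) and
switches to the bias-corrected S_obs + F₁(F₁−1)/2 whenever no doubletons are
present — this avoids division by zero and is standard practice. No
rarefaction is applied before diversity estimation; depth sensitivity is the
user's responsibility.

Levins breadth treats a taxon's distribution of its own total across samples
as its resource-use distribution: B = 1/Σ p² ∈ [1, n_samples]. Pianka overlap
is the normalized inner product of two taxa's share profiles, in [0, 1].
Community-level breadth and overlap are unweighted means over taxa (pairs)
present in at least 2 samples; rarer taxa are degenerate specialists (B = 1)
that would dominate the means without contributing information.

Temporal slopes are ordinary least squares of an index against year, pooled
across replicates for the headline slope/r²/p. Slope *comparison* between
treatments uses a Welch two-sample t-test on per-replicate slopes — the field
replicate is the unit of replication, which is the conservative choice when
the within-replicate residuals are autocorrelated over years.

The phosphorus activation coefficient is PAC = (AP/1000)/TP, i.e. available P
as a dimensionless fraction of total P after aligning mg/kg with g/kg.

## Network inference

Spearman rank correlation (average ranks for ties; p from the t-distribution
with n−2 df) is computed between all taxa present in at least 1/3 of the
samples being networked — prevalence filtering removes correlations driven by
shared zeros. An edge requires |r| > 0.8 and p < 0.01; p-values are
uncorrected by default, with Benjamini–Hochberg available by flag. Networks
are intended to be built per treatment (optionally per year-period via
`group_samples_by_period`); pooling treatments mixes distinct community
states and dilutes within-treatment correlation structure.

Topology metrics are computed on the unsigned, unweighted graph: avgK =
2E/N, density = 2E/(N(N−1)), avgCC = mean local clustering, and average path
length over *connected node pairs only* — this keeps the metric defined and
deterministic for fragmented networks, at the cost of not penalizing
fragmentation itself (the robustness curve captures that instead). Modularity
uses deterministic greedy agglomerative maximization with ties broken by
sorted node insertion. NPE = negative/positive edge count, flagged undefined
when there are no positive edges.

## Stability metrics

**Natural connectivity** is ln((1/N) Σ exp λᵢ) over the eigenvalues of the
0/1 adjacency matrix, evaluated with `logsumexp` for numerical safety; an
edgeless graph scores exactly 0. Signs do not enter the spectral measure —
negative associations influence stability through cohesion and NPE instead.

**Robustness** removes ⌊fN⌋ uniformly sampled taxa per repetition for each
fraction f (default grid 0–0.8, step 0.05; 100 repetitions) and records the
natural connectivity of the induced subgraph. Each (fraction, repetition)
cell draws from a dedicated `default_rng([seed, fraction_index, repetition])`
stream, so results are independent of evaluation order. Two scalar summaries
are reported because bar-style comparisons need one number: the trapezoidal
area under the mean curve (AUC) and the mean connectivity at f = 0.5.

**Vulnerability** of node i is (E − Eᵢ)/E where E is global efficiency
(mean inverse shortest-path distance, disconnected pairs contributing 0) and
Eᵢ is the efficiency of the graph with node i deleted, normalized over the
remaining N−1 nodes — i.e. the standard efficiency of the reduced graph. The
alternative convention keeps the original N(N−1) normalization and shifts all
values; the maximum over nodes (the network value) is bounded by 1 under
either. Removing a low-centrality node can *raise* efficiency, so per-node
values may be negative.

**Cohesion** follows the Herren–McMahon recipe. Observed pairwise Pearson
correlations between taxa are computed across samples on relative abundances
(Spearman available by flag). The null expectation per pair is the mean over
`n_null` (default 200) randomizations in which each taxon's abundances are
independently permuted across samples — one `rng.permutation` per taxon per
iteration, taxa in row order, which is the documented, reproducible shuffle
protocol. Connectedness of taxon j is the mean of its positive (resp.
negative) null-corrected correlations, zero if none; sample cohesion is the
relative-abundance-weighted sum, giving C⁺ ≥ 0 and C⁻ ≤ 0, and
NPC = |C⁻|/C⁺ (flagged NaN where C⁺ = 0). Note that on relative abundances a
community in which *all* pairs correlate positively cannot exist — closure
forces each taxon's covariances with the rest to sum to −var — so C⁻ is
expected to be nonzero even for communities planted without negative
associations; what the planted negative fraction controls is how much *more*
negative cohesion appears.

## Fuzzy temporal clustering

Per treatment, each taxon's trajectory is its mean relative abundance per
year, z-scored across years (population sd); zero-variance taxa are dropped.
Fuzzy c-means uses fuzzifier m = 2, tolerance 1e−6 on the objective, maximum
500 iterations, random membership initialization from the seed; the objective
is asserted non-increasing every iteration, and a point coinciding with a
centroid receives crisp membership. The cluster count is user-chosen (a
partition-coefficient sweep is available for guidance); automatic selection
is deliberately avoided to keep runs deterministic. A taxon is counted as
temporally responsive when its maximum membership is ≥ 0.5 *and* its
cluster's centroid range across years is ≥ 1.0 standardized units — both
cutoffs are explicit flags and echoed in the output, since any such count is
only meaningful relative to its criterion.

## Synthetic generator

The generator emulates a 7-year, 5-treatment, 3-replicate field design with
60 taxa by default. Dependence is planted as a block-structured latent
correlation matrix realized through a Gaussian copula: per sample a
multivariate normal vector with the latent correlation is mapped through
exp(·) onto a static log-normal dominance profile (base spread 1.0, copula
noise sd 1.5), closed to proportions, and counted with a negative binomial at
depth 50 000 and size 10. Rank correlations survive every monotone step, so
the Spearman-based inference sees an attenuated but faithful image of the
latent structure; the attenuation is left uncorrected and all recovery
benchmarks are stated on realized values.

Sign structure: each taxon carries a latent sign (negative with probability q
solving 2q(1−q) = frac_negative), and a planted pair's sign is the product.
This one-factor sign assignment is mutually consistent, so at full
within-module density the planted block is exactly positive semi-definite and
the target magnitude (default 0.9) survives the PSD repair unchanged.
Independent per-pair signs at |r| = 0.9 are mutually contradictory — the
eigenvalue-clipping repair then shrinks planted entries to ~0.55–0.73, below
any 0.8 detection threshold — and are used only for frac_negative > 0.5,
where no consistent assignment exists. Partial within-module density
reintroduces some shrinkage regardless (a zero entry between two strongly
correlated partners is itself non-PSD), which is why the default interaction
model uses full within-module density.

Richness trends activate taxa from a dormant pool (expected abundance 0
before activation), raising observed richness and Chao1 without perturbing
the correlation engine; evenness trends temper the static dominance profile
(dividing base log-means by 1 + rate·year), preserving the rank-driving
noise exactly. Soil properties are linear per-treatment year trends plus
Gaussian noise around baselines typical of slightly alkaline agricultural
soil. Treatment defaults order the trends as straw ≳ manure/biochar > NPK >
control. All draws flow from one `default_rng(seed)` in fixed order, so equal
seed and configuration give byte-identical output.

What the generator does **not** emulate: mechanistic population dynamics,
phylogenetic or taxonomic structure, time-lagged interactions, sample
contamination, or sequencing-run batch effects. Passing recovery benchmarks
therefore shows the inference chain is faithful to planted monotone
dependence under compositional counting noise — not that it is robust to
every failure mode of real amplicon data.

## Benchmarks and problem sizes

The recovery benchmarks run at deliberately modest sizes — 40 taxa, 4
modules, 30 samples per network, 10 seeds (20 for the zero-trend condition);
cohesion nulls of 100–200; robustness at 200 repetitions on 20-node graphs —
chosen so the full suite and the reproduction script each complete in
seconds while leaving wide statistical margins. Edge recovery is scored by
precision (planted among detected); the trajectory-clustering benchmark
plants increasing/decreasing/flat classes directly in standardized profile
space, because a flat raw trajectory z-scores to pure noise and is not a
recoverable *shape* class by construction.

## Known limitations

- Spearman co-occurrence on compositions is subject to closure-induced
  negative bias; no compositional correction (e.g. SparCC-style) is applied,
  matching the thresholded-correlation recipe this package implements.
- The average-path-length convention (connected pairs only) is not comparable
  across networks with very different fragmentation.
- Cohesion's null model permutes taxa independently, preserving each taxon's
  abundance distribution but not sample totals.
- Fuzzy c-means finds a local optimum; different seeds can permute or, for
  poorly separated data, alter clusters. Only same-seed determinism is
  guaranteed.
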