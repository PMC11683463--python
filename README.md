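# phodnet

Temporal network-stability analysis of soil alkaline-phosphomonoesterase
(ALP)-producing bacterial communities.

Soil bacteria carrying the *phoD* gene mineralize organic phosphorus via ALP
and are tracked by *phoD* amplicon sequencing. In long-term fertilization
trials (no-fertilizer control CK; NPK fertilizer N; NPK plus straw NS, straw +
manure NSM, or straw biochar NB), the interesting question is not just *who is
there* but whether the community's co-occurrence network becomes more stable
over years of straw amendment. `phodnet` implements that analysis chain as a
tested, reusable library and CLI for taxon-by-sample OTU count tables:

- **Diversity and niche trajectories** — Shannon index H = −Σ pᵢ ln pᵢ, Chao1
  richness S_obs + F₁²/(2F₂) (bias-corrected when F₂ = 0), Levins niche
  breadth B_j = 1/Σᵢ p²ᵢⱼ, Pianka niche overlap
  O_jk = Σᵢ pᵢⱼpᵢₖ/√(Σᵢp²ᵢⱼ Σᵢp²ᵢₖ), OLS index-versus-year slopes with a Welch
  t-test on per-replicate slopes, and the phosphorus activation coefficient
  PAC = AP/TP.
- **Signed co-occurrence networks** — pairwise Spearman correlation between
  taxa; an edge requires |r| > 0.8 and p < 0.01 (both configurable, BH
  correction optional); topology panel: average degree *avgK*, clustering
  *avgCC*, average path length, density, modularity, and the
  negative:positive edge ratio NPE.
- **Stability metrics** — natural connectivity ln((1/N) Σᵢ exp λᵢ) of the
  adjacency spectrum; robustness as the natural-connectivity trajectory under
  random taxon removal; vulnerability max_i (E − E_i)/E via global efficiency
  E; Herren–McMahon cohesion with a taxon-shuffle null model and the
  |negative|:positive cohesion ratio (NPC).
- **Temporal trajectory clustering** — fuzzy c-means on z-scored yearly mean
  profiles per treatment, with a membership/amplitude rule counting
  temporally responsive OTUs.
- **Synthetic community generator** — a Gaussian-copula, negative-binomial
  simulator of the treatment × year × replicate design with planted
  positive/negative taxon dependence, richness/evenness year trends and soil
  property trends, giving every downstream stage ground truth.

## Worked example

Simulate the default design (5 treatments × 7 years × 3 replicates, 60 taxa,
4 planted interaction modules at latent r = 0.9 with 20 % negative
associations), then analyze the straw (NS) treatment:

```python
import numpy as np
from phodnet import (build_interaction_model, SimulationConfig, simulate_dataset,
                     spearman_matrix, threshold_network, topology_metrics,
                     natural_connectivity, robustness_curve, vulnerability, cohesion)

model = build_interaction_model(n_taxa=60, n_modules=4, within_density=1.0,
                                frac_negative=0.2, target_latent_r=0.9, seed=1)
table, meta, soil = simulate_dataset(model, SimulationConfig(n_taxa=60, seed=1))

ns = table.select_samples([m.sample_id for m in meta
                           if m.treatment == "NS"]).drop_empty_taxa()
net = threshold_network(spearman_matrix(ns, min_prevalence=1/3))
topo = topology_metrics(net)
curve = robustness_curve(net, n_reps=100, seed=1)
coh = cohesion(ns, n_null=200, seed=1)
```

This prints (via the obvious f-strings):

```
NS network: 43 nodes, 90 edges (87+ / 3-), NPE=0.034
avgK=4.19  avgCC=0.49  APL=1.64  modularity=0.55
natural connectivity = 5.973
robustness AUC = 2.249; connectivity at f=0.5 = 1.823
vulnerability = 0.0853
mean NPC ratio = 0.548
```

Reading: of the 60 simulated taxa, 43 pass the prevalence filter and carry at
least one strong, significant correlation; the 90 edges are dominated by the
planted positive within-module associations (NPE ≈ 0.03). Natural
connectivity of 5.97 reflects the dense planted modules; it decays to 1.82
when half the taxa are removed at random (the area under that decay curve,
2.25, is the robustness summary). The low vulnerability (0.085) says no
single taxon's loss collapses the network's efficiency, and the NPC ratio of
0.55 means negative cohesion carries about half the weight of positive
cohesion in this community.

The same pipeline is available from the shell:

```bash
phodnet simulate --seed 1 --out-dir data/
phodnet network data/otu_table.tsv --out-network net.graphml --out-metrics topo.json
phodnet stability net.graphml --otu-table data/otu_table.tsv --seed 1 --out stab.json
phodnet cluster data/otu_table.tsv data/metadata.tsv --treatment NS --n-clusters 3
```

## Input formats

OTU tables are TSV (taxa as rows by default, first column taxon id; a
`samples-rows` orientation flag accepts the transpose). Sample metadata is a
TSV with `sample_id`, `treatment`, `year`, `replicate`; soil properties are a
TSV with `sample_id` plus any of pH, SOC, TN, TP, TK (g/kg), AN, AP, AK
(mg/kg). Networks are written as GraphML or CSV edge lists with `weight` and
`sign` attributes. See `docs/methods.md` for the model details, defaults and
known limitations.
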