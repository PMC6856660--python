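# phylosym

A study-shaped analysis pipeline for host-associated (skin) microbiome
surveys: given an OTU count table, sample metadata, a bacterial phylogeny and
a host phylogeny, it runs control-based decontamination, phylogenetic
diversity estimation, permutation inference on locality / microhabitat /
host-species effects, discriminant and core taxa extraction, and a
host-phylogeny congruence (phylosymbiosis) battery. A first-class synthetic
data generator emulates a two-locality, multi-host amphibian survey with
ground-truth effect injection, so every stage is verifiable without access to
real sequence data.

## Who it is for

Microbial ecologists comparing 16S community surveys across host species,
sites and microhabitats — in particular designs where host species are nested
in sites, negative controls (blank swabs, rinse water, reagents) were
sequenced, and the question is whether community *composition*
(presence/absence) and *structure* (relative abundance) track the
environment, the host's ecology, or the host phylogeny.

## What it computes

- **Decontamination** — an OTU observed in controls is flagged iff it is at
  least as prevalent in controls as in skin AND (mean relative abundance in
  controls ≥ skin, OR a Kruskal–Wallis test on per-sample relative abundances
  gives p < α with controls ranking higher). OTUs absent from controls are
  never flagged. Filters run organelle → rare (<0.001% of total counts) →
  contaminant → rarefaction (3,000 reads, without replacement).
- **Diversity** — Faith's PD (root-inclusive) and Shannon H = −Σ pᵢ log₂ pᵢ;
  unweighted UniFrac d = (unique branch length)/(union branch length) and raw
  weighted UniFrac d = Σᵢ bᵢ |pᵢᴬ − pᵢᴮ| (normalized variant available);
  PCoA for ordination.
- **Inference** — ANOSIM R = (r̄_between − r̄_within)/(M/2); PERMANOVA
  pseudo-F and R² from the Gower-centered distance matrix, including a
  sequential (Type-I) `dist ~ Locality + Microhabitat + Species` model where
  term order matters under nesting; Kruskal–Wallis; a permutation t-test;
  pairwise batteries with Benjamini–Hochberg FDR. All permutation p-values
  use the add-one rule (1 + #{perm ≥ obs})/(m + 1) and an explicit seed.
- **Discriminant & core taxa** — a simplified LDA-effect-size procedure
  (Kruskal–Wallis screen, then a bootstrapped one-dimensional discriminant
  scored as log₁₀ of the between-class mean difference in parts-per-million;
  features reported above score 3.0), and per-category core OTUs at ≥90%
  prevalence plus their cross-category intersection.
- **Phylosymbiosis** — group-collapsed UPGMA dendrograms with jackknife
  supports; rooted, clade-based normalized Robinson–Foulds distance to the
  host tree with a uniform random-topology null (p = (1 + #{null ≤ obs})/(N + 1));
  partial Mantel of host patristic vs community distances controlling for
  locality; phylogenetic eigenvector regression of the dendrogram with MANOVA
  (Pillai's trace) on locality and microhabitat.

## Worked example

```python
from phylosym import (SimulationConfig, simulate_community, preprocess_pipeline,
                      beta_diversity_matrix, anosim)

cfg = SimulationConfig(seed=42)          # default two-locality, 7-species survey
ds = simulate_community(cfg)
table, report = preprocess_pipeline(ds.otu_table, ds.metadata, depth=3000, seed=42)
print(f"flagged contaminants: {len(report.flagged)}  (injected: {len(ds.truth.contaminant_ids)})")
print(f"rarefied table: {table.shape[0]} samples x {table.shape[1]} OTUs")

skin = ds.metadata.loc[table.sample_ids].query("sample_type == 'skin'")
dm = beta_diversity_matrix(table.select_samples(list(skin.index)),
                           ds.bacterial_tree, "unweighted_unifrac")
res = anosim(dm, skin["locality"], n_perm=999, seed=42)
print(f"locality ANOSIM: R = {res.statistic:.3f}, p = {res.p_value:.3f}")
```

prints

```
flagged contaminants: 10  (injected: 10)
rarefied table: 160 samples x 445 OTUs
locality ANOSIM: R = 0.889, p = 0.001
```

All ten injected contaminants are recovered; the low-depth control samples
drop out at rarefaction; and the locality effect written into the generator
comes back as a large ANOSIM R on unweighted UniFrac with the smallest
p-value 999 permutations can produce.

The same analyses are available from a shell via the `phylosym` console
script (`simulate`, `preprocess`, `diversity`, `anosim`, `permanova`,
`adonis`, `pairwise`, `lefse-like`, `core`, `congruence`, `run`).

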