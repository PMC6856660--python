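# Methods

This note documents the models, conventions and numerical choices behind the
pipeline, and what the synthetic generator does and does not emulate.

## The synthetic survey generator

The generator is the package's stand-in for a field survey of skin
microbiota across congeneric hosts: seven host species distributed over two
nearby localities (one generalist species present at both, giving eight
species-by-locality groups), each species tied to one nocturnal microhabitat
(arboreal, terrestrial, herbaceous, cave/rock), 15 skin swabs per group, 40
environmental samples (20 per locality) and 8 low-biomass negative controls.
Simulation starts at the OTU-table level; no sequences or reads are modeled.

**Trees.** Host and bacterial phylogenies are drawn from a pure-birth (Yule)
process: exponential waiting times with rate proportional to the number of
extant lineages, a uniformly chosen lineage splitting at each event, and all
tips extended to the present. This yields rooted, binary, ultrametric trees;
tree shape is not an inferential target here, only a carrier of path-length
structure.

**Skin communities.** The expected relative abundance of OTU *j* in a sample
of species *s* at locality *l* is built multiplicatively on the log scale:

    log w_sj = base_j + m_sj + λ · z_sj

- `base_j ~ Normal(0, 1.5)` is a log-normal community baseline (a realistic
  steep rank-abundance curve: a few dominant OTUs, a long rare tail);
- `m_sj ~ Normal(0, species_effect)` is a per-species multiplier — the
  *structure* effect recovered by weighted UniFrac;
- `z_sj` is a Brownian motion evolved on the host tree (covariance = shared
  root-to-ancestor path length, tree height normalized to 1 so tip marginals
  are standard normal), applied to a designated half of the OTU pool and
  scaled by `phylosymbiosis_strength` (λ). The same offsets also act on
  *composition*: where `z_sj` falls below the presence threshold (−0.5 by
  default) the OTU is absent from that species entirely. Abundance and
  presence channels make phylosymbiosis separately recoverable from weighted
  and unweighted UniFrac.
- A fraction `locality_effect` of OTUs is locality-restricted: zero expected
  abundance in skin and environmental samples outside a randomly assigned
  home locality — the *composition* effect recovered by unweighted UniFrac.

Counts are multinomial draws at a Poisson(`depth_mean`, default 4000) depth
per sample. The default depth keeps post-filter sample totals above the
3,000-read rarefaction cut; configurations with lower depth exercise the
low-coverage dropping path.

**Environment.** Environmental samples draw from the full pool of
`n_otus + environment_extra_otus` OTUs (skin-pool baselines perturbed by
Normal(0, 0.5), extras with their own baseline), with locality restriction
applied but no host effects. The larger pool reproduces the qualitative
pattern that environmental communities are richer than skin communities.

**Controls and contaminants.** `n_contaminants` dedicated OTUs are enriched
in controls at weight `contaminant_boost / n_otus` each, on top of a
near-empty base: each control sees an independent random ~15% sliver
(`control_carryover`) of the mean skin profile at a shallow Poisson(300)
depth. Sporadic, shallow carry-over is the realistic behavior of blank
swabs; it also means that without injected contaminants almost no OTU is
consistently prevalent across controls, which is what makes a
prevalence-based decontamination rule specific. Contaminants leak back into
every skin sample at 10% of their control relative abundance
(`contaminant_leak`) — the hard case for decontamination, since naive
"remove everything in controls" would discard real taxa while a pure
abundance rule would miss partial leakage.

A `truth` record (contaminant ids, locality-restricted ids and homes,
Brownian/species log-offsets, designated phylogeny-tracking OTUs)
accompanies every dataset.

**What the generator does not emulate.** Sequencing error, chimeras,
compositional count correlation beyond the multinomial, overdispersion
(gamma/log-normal depth heterogeneity within a group), taxonomy-correlated
phylogeny (taxonomy strings are decorative), and spatial structure within a
locality. Passing tests therefore demonstrate that the *statistical
machinery* recovers known effects under a clean generative model — not that
the pipeline is robust to every artifact of real amplicon data.

## Preprocessing conventions

Filter order: organelle → rare OTU → contaminant → rarefaction.

- Organelle removal matches the substrings `chloroplast` / `mitochondri`
  case-insensitively at any taxonomy rank.
- The rare filter removes OTUs with total count strictly below 0.001% of the
  grand total, computed before rarefaction over all sample types jointly.
- The contaminant rule (per OTU present in ≥1 control): flag iff
  `prev_control ≥ prev_skin` AND (`mean_relabund_control ≥ mean_relabund_skin`
  OR Kruskal–Wallis on per-sample relative abundances has p < α with the
  control mean rank higher). Relative abundance is computed per sample
  before averaging, because the KW test operates on per-sample observations.
  The disjunction is recorded per OTU in a `reason` column for audit. α
  defaults to 0.05; the directional check makes the KW branch effectively
  one-sided.
- Rarefaction subsamples without replacement (multivariate hypergeometric)
  to exactly the target depth; samples below depth are dropped. Controls,
  being shallow, normally exit the analysis here — after they have served
  their purpose in decontamination.

## Diversity conventions

- Shannon uses log base 2 by default (bits); the base is a parameter.
- Faith's PD is root-inclusive: the minimal spanning subtree always contains
  the root, so single-tip PD equals the root-to-tip path length.
- Weighted UniFrac defaults to the raw (unnormalized) form
  Σ bᵢ|pᵢᴬ − pᵢᴮ|; `normalized=True` divides by Σ bᵢ(pᵢᴬ + pᵢᴮ). Both are
  reported where structure conclusions depend on the variant.
- Multifurcating trees are supported everywhere; all quantities are defined
  over edges. The scikit-bio backend is called with its own validation
  disabled (it would reject multifurcating roots); tip membership and branch
  lengths are validated in-package. Because the backend integer-casts
  abundances, float relative-abundance profiles (group-collapsed tables) are
  rescaled to a 10⁹ integer grid first — UniFrac depends only on per-sample
  fractions, so this is exact to ~10⁻⁹.

## Permutation inference

All permutation tests use the add-one estimate p = (1 + #{perm ≥ obs})/(m+1),
which is unbiased and cannot return zero, with m = 999 by default and an
explicit integer seed. ANOSIM ranks all n(n−1)/2 distances once (average
ranks on ties) and permutes labels. PERMANOVA partitions the Gower-centered
squared-distance matrix; the sequential model computes Type-I sums of
squares tr(H_k G) − tr(H_{k−1} G) from nested hat matrices built by
cumulative dummy coding, permuting raw observations (rows/columns of G).
Terms fully aliased by earlier terms (e.g. locality after species when
species is nested in locality) are reported with df 0 and no test. Pairwise
batteries derive per-pair seeds from one master seed and correct with
Benjamini–Hochberg.

The permutation t-test uses the pooled-variance two-sample t statistic with
a two-sided tail; a zero-variance pooled sample with equal means returns
p = 1.

## Discriminant taxa

The effect-size procedure is a deliberately simplified reimplementation of
the LDA-effect-size idea for designs with a single class factor and no
subclasses: (1) Kruskal–Wallis screen per OTU at α; (2) for survivors, 30
bootstrap resamples within classes; per resample the effect is the largest
between-class difference of class means. For a single feature the
one-dimensional discriminant axis coincides with the feature axis, so the
projected mean difference equals the raw mean difference; abundances are
scaled to parts-per-million before log₁₀, putting the conventional score
threshold 3.0 on its usual scale (a score of 3 ≈ a 0.1% absolute
difference). The score is log₁₀ of the bootstrap-mean effect; features are
reported strictly above the threshold. Classes with fewer than three samples
are excluded with a warning.

Core OTUs use inclusive prevalence (≥ 90% of a category's samples counts
9/10) and report the intersection across categories under the label
`__all__`.

## Congruence battery

- Group collapse averages per-sample relative-abundance vectors (equal
  weight per individual); pooled-count collapse is available.
- UPGMA merge height is half the average inter-cluster distance, so
  cophenetic distances equal the average distances and an ultrametric input
  is reproduced exactly; labels are sorted before clustering so ties break
  lexicographically.
- Jackknife support subsamples every sample without replacement at
  ⌊0.75 × rarefied depth⌋ (fraction configurable), recollapses, recomputes
  the group distance matrix and UPGMA tree, 100 times; a clade's support is
  the fraction of replicate trees containing it.
- Robinson–Foulds is rooted and clade-based — |C_a Δ C_b| / (|C_a| + |C_b|)
  over nontrivial clades — because UPGMA dendrograms are rooted; for binary
  trees the denominator is 2(n−2), so 5-tip comparisons move in steps of
  1/6.
- The topology null is uniform over rooted binary labeled topologies (PDA by
  random stepwise addition: leaf k+1 attaches above any of the 2k−1 existing
  nodes with equal probability), the least-informative choice given no
  stated null model; branch lengths are irrelevant since nRF uses topology
  only. p = (1 + #{null nRF ≤ observed})/(N + 1), N = 1000 by default.
- The partial Mantel statistic is the three-correlation closed form on
  off-diagonal entries (Pearson by default, Spearman available), one-sided
  for positive association (closely related hosts → similar communities),
  permuting the community matrix. The locality control matrix is binary
  (0 same site, 1 different); two populations of one species are assigned
  host patristic distance 0.
- PVR double-centers the dendrogram's cophenetic distance matrix,
  eigendecomposes, and retains positive-eigenvalue coordinates up to
  min(95% cumulative variance, n_tips − levels − 1); MANOVA uses Pillai's
  trace with the standard F approximation, one factor at a time, computed
  from explicit H/E projection matrices (validated against one-way ANOVA F
  in the univariate case). When the retained coordinates separate the factor
  perfectly in-sample (Pillai at its maximum), the result is reported as
  p = 0 with a `perfect_separation` flag. At 8 tips this overfitting
  boundary makes the test mildly anti-conservative (empirical type-I ~8% at
  nominal 5%); at 10–12 tips calibration is nominal. This is an inherent
  small-n limitation of regressing on tree eigenvectors, not a tuning knob.
- Per-locality congruence compares the UPGMA subtree of a locality's groups
  (tips renamed to species) against the host tree pruned to those species;
  localities with fewer than three groups are skipped. Leave-one-group-out
  reanalysis is supported via `exclude_groups`.

## Problem sizes and determinism

Default analysis parameters: rarefaction depth 3,000; 999 permutations;
1,000 random trees; 100 jackknife replicates; LDA threshold 3.0; core
prevalence 0.90; α 0.05. Simulation-backed test batteries run on scaled-down
surveys (3–8 species, 4–6 samples per group, 50–200 OTUs, depths 600–2,000)
— sizes chosen so that effects of interest remain comfortably detectable
while whole-suite runs stay fast; calibration checks use 200 replicates at
199 permutations. Every random draw (simulation, rarefaction, permutations,
bootstraps, topology nulls) flows from an explicit seed; pipeline stage
seeds derive from the run seed via a stable CRC of the stage name, so a
rerun with the same configuration is byte-identical across processes.

## Known limitations

- The decontamination rule is a literal operationalization of a
  prevalence-plus-abundance heuristic; it is not a mixture model and has no
  uncertainty quantification.
- Sequential PERMANOVA permutes raw observations, not residuals, and no
  strata-restricted permutations are offered; at strongly unbalanced designs
  residual-permutation schemes would be preferable.
- The LDA-effect-size stage omits the subclass/Wilcoxon machinery of the
  original tool and the exact normalization of its published implementation.
- nRF on ≤5 tips is very coarse (multiples of 1/6); null rejection at such
  sizes requires near-perfect congruence.
- Alpha-diversity group comparisons use nonparametric tests only; no
  mixed-effects models are fitted.
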