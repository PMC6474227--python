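# Methods

`mycorrnet` analyses paired (dual RNA-seq) count matrices from a host
plant and its fungal symbiont measured on a shared crossed design —
host genotypes × fungal treatments (two symbiont genotypes plus a
non-inoculated mock control) — and builds a cross-kingdom network of
co-expressed gene modules. This note records the models, the defaults
and the reasoning behind the open design choices.

## Normalization and response classification

Counts are normalized to log2-counts-per-million with a prior count:

    log2cpm = log2( (count + c) / (library + 2c) * 1e6 ),  c = 0.5

The prior keeps zeros finite; the `2c` library offset makes the value
of a gene at exactly half the library independent of `c`. Genes with
CPM ≥ 1 in fewer than 3 samples are removed. Mock samples are dropped
from the symbiont matrix before filtering and never re-enter symbiont
analyses: mock roots contain no fungus, only trace contamination reads.

Each gene is then fit by ordinary least squares with a two-factor
model (cultivar + treatment + cultivar × treatment) on log2-CPM,
vectorized across genes. Per-term F statistics use the classical
nested comparisons (main effect: reduced vs additive model;
interaction: additive vs cell-means model) over the full-model mean
squared error; on a balanced factorial these coincide with textbook
two-way ANOVA, and the per-gene p-values are verified against
`statsmodels.anova_lm` in the test suite. Benjamini–Hochberg FDR
control is applied per term across genes (default level 0.05).
Classes are assigned with the priority interaction →
treatment-conserved → cultivar-only; a significant treatment term is
labelled a conserved mycorrhizal response when the single-df
mock-vs-pooled-AMF contrast has the smaller p-value, and a conserved
genotype (isolate) response when the isolate-vs-isolate contrast does.
The tie rule is needed because both categories exist in the field's
vocabulary but no published rule separates them; the smaller contrast
p-value is the least arbitrary choice. Fold-change gene sets
(|log2FC| above 2 for the host, 4 for the symbiont, between the two
isolate treatments) are computed as raw group-mean differences of
log2-CPM, overall and within each cultivar; a gene is selected when
its largest per-cultivar |log2FC| exceeds the threshold, optionally
intersected with the interaction class.

Noise-free inputs are handled explicitly: when a gene's full-model
residual SS is numerically zero, term significance is decided by the
extra SS alone, so planted-pattern recovery is exact rather than
dependent on float ratios.

## Module detection

The network construction is the standard weighted co-expression
pipeline: Pearson correlation across samples → soft-thresholded
adjacency (`|cor|^β`, unsigned, β = 12 by default; a signed variant
`((1+cor)/2)^β` is available) → topological overlap matrix

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    L_ij = Σ_{u≠i,j} a_iu a_uj,   k_i = Σ_{u≠i} a_iu

→ average-linkage hierarchical clustering of `1 − TOM` → tree cut →
module eigengenes → merging of modules whose eigengenes are nearly
collinear (dissimilarity `1 − cor(ME)` below 0.1). Zero-variance
genes are dropped with a warning before the correlation step.

**Tree cut.** At β = 12 the TOM dissimilarity between unrelated genes
saturates smoothly at ~1, so merge heights carry no large parent–child
gaps; a branch-gap criterion finds no modules at all in this regime.
The cut used here is a single height cut at
`hmin + q (hmax − hmin)` of the merge-height range with `q = 0.995`:
genuine modules are complete just below the saturation plateau while
unrelated genes only join on it. Clusters of at least `min_size`
leaves (default 50) become modules, renumbered by decreasing size;
everything else is unassigned (label 0). On i.i.d. noise genes the
largest cluster below the cut stays an order of magnitude under the
size threshold, so noise yields no modules; this is exercised in the
tests.

**Eigengenes.** A module eigengene is the first principal component of
the per-gene standardized member submatrix, scaled to unit variance
over samples. The PC sign is arbitrary, so it is anchored to make the
mean correlation with member genes positive. Variance explained is
the first squared singular value over the total. `kME` (module
membership) is the Pearson correlation of each gene with each
eigengene. The estimator form (`CoexpressionModules`) stores the
fitted gene standardization and PC weights, so `transform` maps new
samples onto the module axes.

**Merging** recomputes eigengenes after each round and repeats until
no pair of eigengenes is closer than the cut, so the operation is
idempotent and the module count never increases.

## Cross-kingdom network, key genes, permutation control

Host and symbiont eigengenes are correlated pairwise over the
inoculated samples only — fungal expression does not exist in mock
roots, and including mock columns would manufacture correlation out
of the presence/absence contrast. Two-sided p-values come from the
exact t transform `t = r sqrt((n−2)/(1−r²))`; module pairs with raw
`p < 0.001` are edges of the bipartite network (BH-adjusted values
are reported alongside). Gene significance (GS) of a gene toward a
partner module is its Pearson correlation with the partner eigengene.
Within each significant pair, key genes are the members in the top
10% quantile of |GS| (linear-interpolation quantile, boundary ties
included; the absolute value is used because strong negative
co-expression is as informative as positive) that also have
`kME > 0.8` in their own module.

The relabeling control reassigns genes to modules uniformly at random
(preserving each organism's module-size spectrum), recomputes
eigengenes and counts significant edges; the empirical p-value of the
observed network is `(1 + #{null ≥ observed}) / (n_perm + 1)`.

Trait association applies the same machinery with a trait column in
place of a partner eigengene: pairwise-complete Pearson correlation
of eigengenes with each quantitative trait (host modules over all
samples, symbiont modules over inoculated samples), and the identical
key-gene rule for trait-correlated modules. The shared code path is
asserted by a test that runs both routes on the same input.

## The synthetic dual dataset

The generator emulates post-read-separation count data for a
5-cultivar × (2 isolates + mock) greenhouse design, 3 replicates
(45 samples), with planted ground truth. It is a log-linear
negative-binomial factor model:

- **Design**: full factorial, seeded shuffle, blocks round-robin.
- **Module factors**: one unit-variance latent factor per planted
  module; a share `effect_strength = 0.6` of its variance is a design
  effect (cultivar offsets, mock-vs-AMF contrast, isolate contrast,
  or a double-centered random cell pattern for genotype × genotype
  interaction — double-centering makes the pattern purely
  non-additive), the rest is sample-level biological noise. No two
  modules of one organism share the same binary contrast: factors on
  an identical contrast are collinear, which would make their planted
  labels meaningless as separate modules.
- **Cross-links**: for a linked pair the symbiont factor is
  `sign (s f_host + sqrt(1−s²) f_own)` built on the inoculated-sample
  restriction, so the planted strength *is* the factor correlation in
  the subset where cross-organism correlation is measured. Defaults:
  three links of strength 0.9 (one negative).
- **Counts**: gene mean = baseline share × `exp(λ · factor)` × library
  size (drawn uniformly in 0.5–2 M), negative-binomial with dispersion
  0.2. The denominator of the share is the fixed baseline total
  (the convention of standard RNA-seq count simulators), so one
  gene's regulation does not compositionally drag every other gene.
  The loading λ is sized per gene so the expected within-module
  log-CPM correlation is `within_module_cor = 0.6`, using the exact
  gamma-Poisson log-variance (`trigamma(1/dispersion) + 1/μ`).
  Normalization still attenuates realized correlations slightly when
  module genes hold a large share of the library; at the default
  geometry (16% of genes in modules) the realized within-module
  correlation is ≈ 0.55.
- **Individually responsive genes**: 10% each of the non-module genes
  get a private cultivar, conserved, or interaction profile at a weak
  signal share (0.15) — the long tail of small effects. Their truth
  module label is 0, but genes sharing a one-dimensional contrast
  with a module are genuinely co-expressed with it, so module-recovery
  scores are computed over genes assigned in *both* the planted truth
  and the detected partition.
- **Unwanted variation**: three organism-specific latent sample axes
  with random per-gene loadings (25% of a null gene's log-scale
  variance) emulate RUV/sva-type technical and tissue-composition
  variation. They are what makes the relabeling control meaningful:
  without them the strongest axis in any random gene set is a planted
  factor and random "modules" inherit real cross-organism signal.
- **Mock symbiont counts** are i.i.d. Poisson contamination (mean 0.1
  counts/gene), matching the near-zero fungal transcript recovery
  from non-inoculated roots. **Traits** are linear combinations of
  module factors plus Gaussian noise (sd 0.3); the colonization-like
  trait is affinely rescaled into [0, 1] and exactly 0 for mock.

Total pool size defaults to 2500 genes per organism with five planted
modules of 100/90/80/70/60 genes. The geometry matters: planted
modules must be large and coherent enough to recover (ARI ≈ 1 against
truth at these defaults), while random relabelings must be
noise-dominated so the permutation control reproduces the
no-network-by-chance outcome (null median 0 edges at p < 0.001).
Denser geometries (module genes ≳ 40% of the pool) put real factor
signal into every random gene set and the control degrades — that is
a property of relabeling controls generally, not of this
implementation.

What the generator does **not** emulate: read-level artifacts
(mapping bias, multi-mapping, in-silico separation errors), gene
length effects, correlated dispersion, batch structure confounded
with the design, and annotation. Passing tests therefore demonstrate
the correctness and calibration of the analysis machinery under the
stated generative assumptions, not performance on any real dataset.

## Pipeline defaults and reproducibility

`run_all` chains simulation (optional), normalization/filtering,
response classification (host over all samples, symbiont over
inoculated samples), module detection, the cross network with key
genes and the permutation control, and trait association. Host
modules are built only from the AMF-responsive gene pool (genes whose
class involves the treatment term), mirroring the practice of
restricting the host network to symbiosis-responsive genes; symbiont
modules use all retained genes. A consequence worth knowing: with
moderate per-gene effect sizes roughly a third of planted module
genes fall below per-gene significance, so DE-pool filtering can thin
planted host modules below the size threshold — a known limitation of
building networks on DE pools, and the reason the validation
experiments run module detection on the full expression matrix.

All randomness flows from the single configured seed through named
`SeedSequence` substreams (design, factors, counts, traits,
permutations). Reruns with the same configuration and seed are
byte-identical for every output table; the manifest records a hash of
the analysis-relevant configuration (the output directory is
excluded).

Defaults in one place: soft power 12, unsigned adjacency, minimum
module size 50, eigengene merge cut 0.1, tree-cut quantile 0.995,
edge threshold p < 0.001, key-gene quantile 0.90 with kME > 0.8,
DE level 0.05 (BH), fold-change thresholds 2 (host) and 4 (symbiont),
CPM prior 0.5, expression filter 1 CPM in 3 samples, 100 permutations.

Problem sizes used by the validation scripts — ten replicate datasets
at the default geometry for recovery and cross-link checks, 200
replicates for edge-rate calibration, 20 × 1000 genes for the
all-null classification check, 100 permutations for the relabeling
control — keep a full validation run in the low minutes on one core
while leaving the binomial error bands narrow enough to be
informative.
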