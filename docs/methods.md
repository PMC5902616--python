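# Methods

This note documents the models and procedures pancanhub implements, the
parameters that matter, the synthetic-data generator the tests rest on, and
the numerical and design choices that were genuinely open.

## Mutation filtering

Somatic calls pass four stages, in order: sample type, aliquot annotation,
read depth, release intersection.

- **Sample types kept** (default): `Primary Blood Derived Cancer -
  Peripheral Blood`, `Primary Tumour`, `Additional - New Primary`. The
  filter is record-local.
- **Annotation filter.** An aliquot is removed iff it carries at least one
  annotation category outside the benign whitelist (`Acceptable treatment
  for TCGA tumour`, `Alternate sample pipeline`, `Item in special subset`,
  `Item is noncanonical`). An aliquot with a mix of whitelisted and
  non-whitelisted categories is removed — the conservative reading; the
  whitelist is configurable. Annotations key on aliquot barcodes; whether
  real annotation tables key on aliquots, samples or cases is ambiguous, so
  the keying level is whatever the supplied metadata table uses.
- **Depth filter.** A call is removed iff t_depth < 14 or n_depth < 8;
  the boundary pair (14, 8) survives. Strictly record-local, so it commutes
  with the sample-type filter (property-tested).
- **Release intersection.** Genes outside the supplied
  release-intersection set are dropped. The set is an input, not computed.

All variant classifications are retained, including synonymous calls:
mutation association here is a gene-level signal, not a driver call.

Burden statistics: calls/aliquot divides the per-(dataset, gene) count by
the dataset's aliquot count; the per-kb variant additionally divides by the
gene's summed exon length in kb (exon length is a required annotation
column; genes without one get NaN with a warning).

## Expression preparation

- **Profile selection.** Sample-type and annotation filters (same semantics
  as above) run first; then exactly one profile per case is kept, chosen
  uniformly under the run seed when a case has several.
- **Quantile normalisation** maps every sample onto the across-sample mean
  of order statistics. Ties within a sample receive the mean of the
  reference values over the tied rank block. For tie-free data the transform
  is exactly idempotent and all sorted columns are identical to the last
  bit; with ties, per-column tie structure makes sorted columns differ at
  tied positions — this is inherent to rank-based normalisation, not a
  defect. Normalisation operates on FPKM as given (no prior log transform).
- **Missing/variance filter.** Genes with more than 10% missing values (or
  zero variance) and samples with more than 50% missing values are removed.
- **Outlier samples.** Average-linkage clustering of samples on Euclidean
  distance; static cut at mean merge height + 3 sd; the largest cluster is
  kept. The threshold is a heuristic and configurable; fewer than 3 samples
  skips the step.

## Co-expression network

- **Input scale.** Correlations are computed on log2(FPKM + 1e-3)
  (`log_transform=True` by default). Pearson correlation on raw FPKM is
  dominated by the largest observations: for log-normal data with unit log
  variance, a latent correlation of 0.81 attenuates to roughly 0.73 on the
  raw scale, degrading both module detection and kME. Correlation networks
  over FPKM are conventionally built on the log scale; the pseudo-count
  matches the ECDF summary convention and keeps zero FPKM finite.
- **Signed adjacency** a_ij = ((1 + r_ij)/2)^β, diagonal 1. Anti-correlated
  pairs get adjacency 0 instead of folding onto positive correlation.
- **Soft threshold.** For each candidate β the connectivities
  k_i = Σ_{j≠i} a_ij are binned into 10 equal-width bins; log10 frequency is
  regressed on log10 mean connectivity over non-empty bins, and the fit
  index is R² × (−sign(slope)). The chosen power is the smallest candidate
  with fit ≥ 0.8, else the best-fitting candidate with a warning.
  (Equal-count binning would make every bin frequency identical and the
  regression undefined; equal-width binning is what the standard
  scale-free-fit implementations use.)
- **TOM.** TOM_ij = (ℓ_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij) with
  ℓ_ij = Σ_{u≠i,j} a_iu a_uj, diagonal 1 by convention; verified against an
  O(n³) direct-evaluation oracle to 1e-12.
- **Module detection.** Average linkage on 1 − TOM with a static cut.
  The `"auto"` cut sits at the midpoint of the largest gap in the sorted
  merge heights: members of a tight module finish merging well below the
  band where unrelated genes join, so the widest gap separates the two
  regimes. A fixed fraction of the maximum merge height was tried first and
  discarded — on planted-module benchmarks it either merged everything or
  inflated modules with noise genes, while the largest-gap rule recovered
  planted modules exactly across soft-thresholding powers 4–12. Clusters
  below the minimum module size (30) stay unassigned (label 0); modules are
  relabelled by decreasing size with ties broken by smallest member id. No
  eigengene-similarity merging is performed.
- **Eigengenes and kME.** The module eigengene is the first right singular
  vector of the members' per-gene z-scored expression, scaled to unit
  variance and oriented so the mean member correlation is positive.
  kME is the Pearson correlation of a gene with an eigengene; its p-value is
  two-sided, from t = r√((n−2)/(1−r²)) on n−2 df (two-sided is the stricter
  and conventional choice; the direction of membership is signed anyway).

## Hub selection and PSG integration

The per-dataset hub quota is target = round(5% × n genes), allocated to
modules as cap_m = ceil(target × size_m / Σ sizes) — a proportional reading
of "restrict the maximum rank per module by its size"; both the fraction
and the rule are configurable. Within a module, genes rank by own-module
kME (ties by gene id); quota is applied first, then the kME ≥ 0.9 and
p ≤ 0.01 cut-offs, so the 5% is an upper bound. Unassigned genes are never
hubs.

A dataset's selected genes are hubs ∩ mutation-associated genes. The PSG
set is the union over datasets with membership counts m_g; the coding split
follows the annotation biotype, and non-coding PSGs map onto four
categories (pseudogene, short non-coding, long non-coding, problematic)
through a fixed 19-biotype table; unknown biotypes fall into
`problematic` with a warning.

## PPI network and complex detection

Edges at combined score ≥ 900 (duplicates keep the max score; self-loops
dropped). The single-depth network is the induced subgraph on representors
(pcPSGs with interactions) plus first neighbours — edges among interactors
included, i.e. network rather than star-forest semantics.

Complex detection follows the molecular-complex-detection scheme:

- vertex weight = (highest core number k of the closed neighbourhood) ×
  (density of that k-core); isolated vertices weigh 0. Verified against an
  exhaustive peeling oracle on random graphs.
- seeds in decreasing weight order (ties by id); breadth-first growth
  includes unvisited vertices with weight ≥ w_seed × (1 − vwp), vwp = 0.2;
  core members are globally visited once, so cores are disjoint.
- post-processing per candidate: discard unless it contains a k-core with
  k ≥ 10 (the K-core filter, standard semantics: an 8-clique's maximal core
  is 7 and is rejected, a 12-clique's is 11 and passes); haircut removes
  core members with in-complex degree < 2; fluff adds boundary neighbours
  whose closed-neighbourhood density exceeds 0.1 and is the only source of
  overlap between complexes. Score = core density × core size.
- a caveat on expansion: when two equally dense complexes are joined by a
  bridge edge, the weight threshold cannot stop the growth at the bridge
  and they merge — this is inherent to the greedy expansion rule. Unequal
  densities separate cleanly (a 15-clique seed's threshold 11.2 excludes a
  bridged 12-clique's weight-11 vertices).

vwp = 0.2 and fluff density = 0.1 are tool defaults, declared rather than
inferred. Complex recovery is evaluated with fluff off, since fluff adds
boundary members by design; the fluff-overlap property is tested separately.

## Enrichment and occupation

- **Fisher tests** are one-tailed in the enrichment direction: the exact
  hypergeometric upper tail P(X ≥ a), evaluated in log space; significance
  at p ≤ 0.05. Verified exactly against full enumeration for all tables
  with total ≤ 60. The battery mirrors the published comparisons: each
  complex vs the network, each complex vs the union of other complexes
  (overlapping complexes make several readings possible; the comparison set
  is recorded with each row), complexes vs network, network vs universe,
  PSGs vs universe. The universe is an explicit argument everywhere.
- **Over-representation**: per-term hypergeometric upper tail with
  Bonferroni factor = number of reported terms (terms with ≥ 1 query
  member), capped at 1.
- **Occupation ratios**: occ(c, d) = Σ_{g ∈ c ∩ PSG(d)} (1/m_g) / |c ∩ PSG|.
  Genes selected by several datasets are attributed fractionally — the
  declared reading of "taking shared genes into account". Rows sum to 1
  whenever the complex has a PSG member; otherwise the row is zero and
  flagged.
- **Expression summaries**: per gene and dataset, log10(mean FPKM + 1e-3);
  ECDFs per node-role group with two-sample Kolmogorov–Smirnov distances,
  descriptive only.

## Synthetic cohorts

The generator emulates the pipeline's input classes with known truth:

- **Expression**: per module m a latent eigengene e_m ~ N(0,1) per sample;
  a member with loading β has latent β·e_m + ε, ε ~ N(0, 1−β²), so β is
  exactly the latent gene–eigengene correlation; background genes are
  N(0,1). Observed values are exp(latent + per-gene offset), offset ~
  N(1,1): positive, log-normal, FPKM-like. The standard benchmark plants 3
  modules × 50 genes at β = 0.9 among 500 noise genes over 100 samples.
- **Mutations**: per gene × aliquot Poisson counts at base rate 0.02
  (×20 for planted hot genes); pass-records draw t ~ U[14,120], n ~ U[8,80],
  fail-records draw one side uniformly below its threshold — filter
  behaviour, not depth realism, is under test. Aliquots carry disqualifying
  annotations at the configured rate; some aliquots get benign annotations
  to exercise the whitelist; sample types include a non-primary minority.
- **PPI**: within-complex pairs get edges with probability p_in and scores
  in [900, 1000]; background pairs with probability p_out and scores in
  [150, 949], so only a minority of background edges survive the 900
  threshold. The standard benchmark plants five 12-cliques among 800 genes
  at p_out = 0.002.

What the generator does **not** emulate: mutational signatures, copy
number, batch effects, dataset-specific library sizes, realistic STRING
evidence channels, or correlated annotation failures. Passing recovery
tests therefore demonstrates correctness of the algorithms under the
generative model, not performance on real cohorts, where signal strength,
module sizes and confounding are far less favourable.

## Problem sizes and determinism

Tests and the acceptance script run on desk-scale cohorts (hundreds of
genes, ~100 samples, 2 datasets end to end): large enough for the planted
structure to be identifiable with margin, small enough to iterate quickly.
Every stochastic step draws from a numpy Generator seeded per call; the
pipeline report is byte-identical across reruns with the same seed.

## Known limitations

- The static tree cut (even with the largest-gap rule) assumes a height gap
  between within-module and between-module merges; nested or overlapping
  modules on real data favour dynamic tree-cut methods.
- The quota rule is one reading of size-aware rank restriction; published
  per-dataset hub counts could follow a different allocation.
- Greedy complex expansion merges equally dense bridged complexes (above).
- Headline counts from the published pan-cancer analysis (thousands of
  selected genes, a ~6,800-node network, nine clusters) derive from
  ~10,000 cases and are not reproducible at desk scale; the package's
  claims are correctness and recovery, not replication of those counts.
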