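# Methods

`skinsci` re-implements, as a tested library, the computational chain used
to analyze pooled multi-genotype single-nucleus combinatorial-indexing
RNA-seq of zebrafish skin: barcode quality control, ambient-background-
corrected and batch-aligned embedding, graph clustering, marker/signature
statistics, cell-type abundance comparison, per-cell-type differential
expression, and principal-graph pseudotime. Because the original raw data
require a read-alignment backbone that is out of scope here, every stage is
exercised against a synthetic-data generator with exact ground truth; this
note documents the models, the defaults and why, and what the synthetic
results do and do not establish.

## The synthetic generator

A cell of type *k* in library *s* draws a library size
*L ~ round(LogNormal(meanlog, sdlog))*, floored at 50, and a count vector

    counts ~ Multinomial(L, (1 − ρ) · p_k + ρ · a_s)

where *p_k* is the type's expression program (a probability vector over
genes) and *a_s* the library's ambient profile. Choices and rationale:

- **Programs** (`make_programs`): a shared lognormal per-gene scale
  (σ = 1) gives the common transcriptome; each type deviates by a small
  lognormal jitter (`type_sd`, default 0.15) plus a disjoint marker module
  whose rates are raised to `marker_boost` × the highest rate of that gene
  in any other type. Related cell types in one tissue share most of their
  transcriptome and are told apart by marker modules; making every type
  differ genome-wide instead would give the ambient displacement a
  different direction per type, which no global linear correction can
  address, and is not what tissue data look like.
- **Library sizes**: meanlog 7.1, sdlog 0.5 → ≈1300 mean UMIs per nucleus,
  matching the assay's reported depth. These are calibration choices, not
  ground truth.
- **Ambient profile**: per library, the abundance-weighted mean of that
  library's (genotype-shifted) type programs — free RNA in the supernatant
  pools from the cells actually present.
- **Per-cell contamination**: each cell's ρ is drawn from a Beta
  distribution with the library's mean `ambient_fraction` and a
  concentration parameter (default 6; large values recover a fixed
  fraction). Contamination load varies from nucleus to nucleus in real
  preparations, and the per-barcode truth table records the value used.
- **Doublets**: a configurable fraction of barcodes (default matching the
  study's 11%) are sums of two independently drawn cells, homotypic or
  heterotypic at the abundance-implied rates — the simplest model that
  exercises a doublet detector.
- **Empty barcodes**: ambient-only draws with 1–14 total UMIs, so the
  sub-15-UMI background rule captures exactly the simulated empties.
- **Trajectory**: optional cells interpolate linearly in rate space
  between two type programs with latent time *t ~ Uniform(0,1)*.
- **Differential expression**: listed (gene, type, genotype, fold) entries
  multiply the rate and renormalize the program; renormalization means the
  realized fold change is slightly compressed when shifted genes carry
  substantial rate mass.

What the generator does **not** emulate: gene-level negative-binomial
overdispersion beyond what lognormal depth and program mixing induce,
batch chemistry differences other than ambient composition and level,
barcode collisions, spliced/unspliced structure, or read-level artifacts.
Passing tests therefore demonstrate correctness of the statistical
machinery under a controlled generative model, not performance on any
particular real dataset.

## Quality control

Barcodes are kept when total UMIs lie in **(600, 6000]** — strictly more
than 600 ("greater than 600" keeps, "greater than 6000" discards, so 600
is dropped and 6000 kept); barcodes with **< 15** UMIs are pooled per
library as the ambient background. The knee curve is exported as a
diagnostic only; the thresholds are configuration. Whether the bounds
apply per library or globally is not specified by the source workflow; they
are applied globally (one experiment, shared chemistry).

Doublet flagging is a deliberately simplified stand-in for dedicated
callers: synthetic doublets are built by averaging random cell pairs in
PCA space (averaging, not summing, because the coordinates are
post-normalization), each cell is scored by the fraction of synthetic
doublets among its `knn_k` nearest neighbors in the pooled set, and the
top `doublet_rate_prior` fraction (default 0.11) is flagged by rank with
ties broken by cell index. The full variance-normalized re-projection and
bimodality fit of dedicated tools is intentionally not reproduced.

## Embedding and background correction

1. **Size factors**: per-cell total UMIs divided by the geometric mean of
   totals (geometric mean of factors is exactly 1).
2. **Normalization**: `x = ln(1 + count/sf)`, sparse zeros preserved.
3. **PCA**: gene-centered, unscaled, all genes, top 50 components by
   default, computed by exact SVD (deterministic).
4. **Ambient profiles**: pooled background counts per library, converted
   to proportions, smoothed by a uniform 1e-9 and renormalized (smoothing
   proportions, not counts, keeps the profile invariant to duplicating
   barcodes).
5. **Background loading and residualization**: by default each cell gets
   one scalar loading — the dot product of its normalized expression with
   its *own* library's ambient profile, standardized
   (`loading_mode="own_profile"`). The PCA matrix is regressed on the
   loadings (OLS with intercept, fit per component) and the residuals are
   the background-corrected PCA matrix; residuals are orthogonal to the
   design at machine precision. An alternative mode (`"profile_dot"`)
   scores every cell against every library's profile, one column per
   library. It is not the default because the profiles are
   abundance-weighted mixtures of the type programs: several such columns
   are strongly collinear, and their joint span lies inside the low-rank
   subspace that separates cell types, so residualizing on all of them can
   delete a large share of the discriminative structure when the number of
   types is comparable to the number of libraries. The per-cell scalar
   removes the contamination axis while leaving type geometry intact. The
   correction targets *sample-specific* contamination: it has a visible
   effect precisely when libraries differ in how dirty they are, and it
   cannot undo the uniform compression of all clusters toward the ambient
   point that a shared contamination level causes (that would require
   count-level decontamination, which is out of scope).
6. **MNN alignment**: libraries are merged sequentially in input order
   onto the first (order matters and is part of the contract). Mutual
   k-nearest-neighbor pairs against the accumulated reference define
   correction vectors; each incoming cell moves by a Gaussian-kernel
   (bandwidth `mnn_sigma`, default 20 in PCA units) weighted average of
   pair vectors. MNN assumes the batch offset is small relative to
   between-type separation; with an offset much larger than within-type
   spread the pairs form between cluster edges and the estimated shift is
   attenuated — the constructed-shift checks therefore use tight,
   well-separated type clusters.
7. **UMAP** (min_dist 0.15, 20 neighbors, seeded) is produced for
   visualization only; no downstream statistic reads the 2-D coordinates.
   This quarantine is deliberate: the pseudotime diagnostics below exist
   exactly because apparent continuity in a 2-D embedding can mislead.
8. **Clustering**: Leiden community detection (CPM partition) on an
   undirected exact k-NN graph (default k = 20) of the aligned PCA matrix.
   The CPM resolutions in use are small (2e-4 for a single-genotype
   subset, 1e-4 for the pooled set): at resolution γ, two groups merge
   only if more than γ·n₁·n₂ edges join them.

## Signatures and fractions

- **Specificity** of gene *g* for cluster *c* is the Jensen–Shannon
  complement `1 − JSD(p_g, e_c)/ln 2`, where *p_g* is the gene's
  renormalized vector of per-cluster mean expression and *e_c* the
  indicator distribution; it is 1 exactly for a gene expressed in one
  cluster only and 0 for all-zero genes. Signature genes are selected at a
  strict threshold (default 0.1).
- **Signature score**: mean over signature genes of gene-wise z-scored
  normalized expression (`score_mode="zmean"`); constant genes contribute
  0 and absent genes are dropped, so padding a signature with absent genes
  never changes scores.
- **Score ratio** (e.g., mesenchymal/epithelial): both score vectors are
  shifted by one common constant chosen so each one's minimum is ≥ 0.1,
  then divided; the shift preserves monotone order in numerator and
  denominator separately and is reported with the output.
- **Expressing fraction**: a cell expresses a signature when its summed
  raw UMIs over the signature genes reach 1 (the loosest detection rule,
  exposed as a flag). Group fractions get percentile bootstrap CIs
  (default 100 resamples) using order-statistic (conservative)
  percentiles, because interpolated tails undercover at B = 100; the CI is
  clamped to bracket the point estimate.

## Abundance and differential expression

- **Abundance**: per-library cell totals give sample size factors
  (total / geometric mean); per-type counts are pseudocounted (default 1,
  so a genotype that has lost a cell type entirely still yields a finite,
  strongly negative ratio; 0 available for exact arithmetic) and reported
  as `log2(normalized query / normalized reference)` against a named
  reference library.
- **Differential expression** within one cell type, between two
  genotypes: per gene, UMI counts follow a Poisson log-link GLM with the
  log cell size factor as offset and a genotype indicator. For this
  saturated two-group design the maximum-likelihood fit is closed form
  (group rate = group count sum / group size-factor sum), which the
  implementation uses directly; a quasi-likelihood correction inflates the
  Wald standard error by the Pearson dispersion floored at 1. Genes
  detected in fewer than 10 cells are excluded *before* testing and do not
  enter the BH correction; complete separation is reported with |log-fold|
  capped at 20 and flagged. Benjamini–Hochberg q-values are computed with
  the step-up definition's own arithmetic so they match it bit-for-bit.
  The stringent display threshold interprets "effect > 2" as fold-change
  magnitude > 2 on the linear scale.

## Pseudotime

The principal graph is k-means centroids (default 25 nodes, seeded)
joined by their Euclidean minimum spanning tree — a documented
simplification of elastic principal graphs that is deterministic and
sufficient for rank-based diagnostics. Cells map to their nearest node;
pseudotime is the tree distance from the cell's node to the nearest root
node (roots are given as a cell set; node-resolution, no within-edge
interpolation, since every downstream claim is rank-based). Ordering
diagnostics report Spearman and Kendall correlations of pseudotime
against an independent per-cell score; the package's negative control
shows that when an orthogonal gradient dominates expression variance,
pseudotime tracks that gradient rather than the true lineage order —
pseudotime is an ordering proxy, not a lineage proof.

## Pipeline

`pipeline.run_pipeline` chains simulate → QC → embed (+ doublet removal
and re-embedding) → signatures → abundance → DE → optional trajectory from
one YAML-able config, with one pooled library per genotype (genotypes are
barcoded by RT index in this design). Stage seeds derive from the master
seed via CRC32 of `"{seed}:{stage}"` (31-bit), all thresholds are echoed
into a manifest, every per-cell table is keyed by barcode, and a rerun
with the same config is byte-identical.

## Problem sizes and numerical choices

Benchmark experiments run at desk scale by design: the contaminated
embedding benchmark uses 8 types × 4 libraries × 1000 cells (+300 empties
each) at mean contamination 0.3 split unevenly across libraries
(0.5/0.35/0.25/0.1 — the sample-specific regime the correction targets);
abundance recovery uses 2000 cells per genotype with multipliers
{0.25, 0.5, 1, 2, 4} carried by five equal-abundance types plus a buffer
type that absorbs the complement, keeping expected ratios at exactly
{−2…2}; DE calibration uses 200 genes × 300 cells/side and power 500
genes × 500 cells/side at ≈0.5 mean UMI/gene with 30 four-fold effects;
pseudotime uses 1000 trajectory cells and 25 nodes. Degenerate inputs are
contracts, not surprises: zero-total cells are rejected before size
factors, constant loading columns are dropped with a warning, zero-length
MST edges from duplicate centroids are tolerated, and an absent
background group falls back to the pooled ambient profile with a warning.
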