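# Methods

This note documents the statistical procedures, default parameters and
design choices behind `spacomod`, and what the synthetic benchmarks do and
do not establish about real data.

## Annotation-average projection

Given an scRNA-seq reference annotated in the same cell-type taxonomy as
the SRT dataset, the per-category mean expression of every gene is computed
(streaming over cells in blocks of 8,192 rows, so reference and spatial
matrices never need to be resident simultaneously) and assigned to each
spatial cell by label correspondence. The approach assumes the taxonomy is
fine-grained enough that a category mean represents its cells; with coarse
annotations it smooths away within-type heterogeneity, which is why the
cell-level validation correlation is bounded above by the between-category
share of a gene's variance (law of total variance) while the category-level
correlation of a self-projection is identically 1. Cells whose label has no
reference counterpart receive zero rows and a warning by default; a strict
mode raises instead. Category order is first-appearance order in the data,
never locale-dependent sorting. Expression is used in the stored unit — any
log or CPM transform is an explicit upstream step, not an implicit one.

## Cell selection

Three selection modes produce the same `CellSelection` object: all cells of
an annotation label (dataset order); a breadth-first flood-fill over the
directed k-nearest-neighbour graph built on expression rows; or an explicit,
order-preserving de-duplicated index list. The flood-fill follows each
cell's own out-edges without symmetrizing the graph — this keeps the
traversal well defined for the asymmetric kNN relation; "flood nodes" is the
graph's k and "flood steps" the BFS depth, with defaults k=10, steps=10.
BFS order is recorded so downstream output is deterministic. The kNN search
is exact brute force with a lower-index tie-break up to 5,000 cells
(metrics: euclidean, cosine, correlation); above that a tree-based search is
used and the selection provenance records `exact_knn: false`.

## Gene filtering

All three metrics are computed over the selected cells only.

**Differential.** mean(selection) − mean(whole dataset), ranked signed and
descending: the filter targets genes *high* in the selection, so a gene
depleted in the selection ranks last rather than high by magnitude.

**Moran's I.** Spatial weights are built from Euclidean distances of the
selected cells' coordinates. The default scheme is binary kNN with k=15 —
bounded cost on large selections and standard practice in spatial omics —
with an inverse-distance scheme (1/d up to a cutoff) available; the scheme
is recorded in the output provenance. Weights are used raw with the N/W
prefactor, not row-standardized (a row-standardized variant is a flag). The
Z-score uses the closed-form variance under the normality assumption,

    Var(I) = [N²S₁ − NS₂ + 3W²] / [W²(N²−1)] − E(I)²,
    S₁ = ½ Σᵢⱼ (wᵢⱼ + wⱼᵢ)²,  S₂ = Σᵢ (Σⱼ wᵢⱼ + Σⱼ wⱼᵢ)²,

which the tests anchor two ways: the permutation mean of I equals
−1/(N−1) exactly (verified by full enumeration at N=6), and on spatially
random data the |Z| > 1.96 rule flags ≈5% of genes. Ranking uses |Z| so
clustered and dispersed patterns both survive.

**Spatial axis.** Pearson r between expression and one coordinate axis;
ranking uses |r| so both gradient directions are retained (a
dorsal–ventral module and its ventral–dorsal counterpart).

Genes with zero variance over the selection have an undefined statistic:
they carry a NaN sentinel and are excluded from ranking entirely rather
than scored 0, so constant genes can never displace informative ones. Ties
are broken lexicographically by gene symbol, making the ranking a total
order and re-runs byte-identical. Multiple-testing control is deliberately
absent: the tool ranks and truncates at a user-chosen n_keep, and the
Z = ±1.96 threshold is a guideline, not a gate.

## Gene clustering

Pairwise distances between retained genes are 1 − Pearson r of their
within-selection expression (0 = perfectly correlated, 2 = perfectly
anticorrelated). Agglomerative clustering with average linkage (UPGMA) —
the conventional partner for correlation distances — is cut to exactly k
flat clusters; complete linkage is a flag, and k is always user-chosen (no
automatic model selection, since the right granularity depends on the
question). No re-standardization precedes the distance: Pearson already
centers and scales per gene, which also makes the partition invariant to
per-gene affine rescaling. Module ids are relabeled by descending size,
ties by lexicographically smallest member gene, so module numbering is
reproducible. Each module's mean map is the arithmetic mean over member
genes per selected cell; the normalized map min–max scales it into [0,1]
within the selection (all-zero when constant).

## Enrichment

Online providers are g:Profiler g:GOSt (supports organism and a custom
background; queries from a limited SRT panel send the full measured panel
as background) and ToppGene ToppFun (no custom background or organism, so
it is admitted only for transcriptome-wide queries; a background with this
provider is a config error raised before any network traffic). Requests are
JSON POSTs with a 30 s timeout and 3 attempts under exponential backoff;
correction is requested as Bonferroni. The offline engine computes, per
term, the one-sided hypergeometric tail P(X ≥ overlap) with population =
background, successes = term ∩ background, draws = query size, then
Bonferroni-adjusts by the number of terms tested (terms with at least one
gene in the background), capped at 1. Terms with zero query overlap are
omitted from the result rows — a reported term always has a non-empty gene
list — but still count toward the correction. Term tables load from
two-column TSV or GMT.

## Synthetic data

The generator plants known structure on a jittered integer grid (default
10×10×5; jitter U(−0.3, 0.3) per axis avoids degenerate distance ties):
axis-aligned linear gradients of amplitude 10 scaled to span the grid,
Gaussian hotspots a·exp(−d²/2r²), per-region marker genes a·1[region], and
pure-noise genes. The annotation mosaic is contiguous blocks along the
first axis (default 4 regions), each split in two along the second axis to
give a two-level taxonomy. Additive Gaussian noise (default sd 0.5, i.e.
5% of amplitude) is truncated at zero since expression is non-negative;
count realism (overdispersion, zero inflation) is deliberately not modeled
because every statistic under test is a mean or a correlation and therefore
distribution-agnostic. The pseudo-scRNA companion carries the full gene
panel (default 150 genes vs a 120-gene SRT panel) with cells drawn per
annotation from the same generative rules at fresh in-region positions.

Consequently the benchmarks establish algorithmic correctness — oracle
agreement, exact recovery of planted structure, determinism — under clean
additive noise. They do not establish robustness to segmentation errors,
transcript spillover between neighbouring cells, batch effects, or
count-distribution misspecification in real assays.

## Numerical choices and degenerate inputs

- Undefined statistics (constant vectors) return NaN sentinels, never 0;
  correlation distance on a constant gene is an error because filtering
  must already have excluded it.
- Floats are serialized to CSV/JSON with 17 significant digits so parsed
  values round-trip exactly (`pandas.read_csv(..., float_precision=
  "round_trip")` on the way back).
- Projection round-trips reproduce category averages to ~1e−14 (one
  re-rounding of n identical summands), not bit-exactly.
- k ≥ n in the kNN builder clips to n−1 with a warning; n_keep above the
  number of finite-score genes retains all of them with a warning; a
  dendrogram cut that cannot produce k clusters (fully degenerate
  distances) raises rather than silently returning fewer.
- Coincident points under inverse-distance weights raise with advice to
  use the kNN scheme; a cutoff below all pairwise distances (W = 0) is an
  error.

## Problem sizes

The test suite and `scripts/acceptance.py` run on generated data of a few
hundred cells and 100–200 genes: large enough that the planted-structure
recoveries are non-trivial (500 cells, 100 genes, noise at 5% of signal)
and the Monte-Carlo checks are well powered (1,000 permutations at N=50;
500 random genes at N=100 for the significance guideline; 100 random
instances up to N=200 for each oracle comparison), and small enough that
the whole suite completes in seconds on one CPU.

## Known limitations

- Label-transfer projection cannot recover within-category spatial
  gradients; it is a visualization/exploration bridge, not imputation.
- The Moran's I weight construction (k, cutoff, symmetry, standardization)
  has no single canonical choice; defaults are declared above and recorded
  in output provenance rather than inferred.
- The normality-assumption Z-score is approximate for small selections or
  heavy-tailed expression; a permutation Z is the natural extension.
- Online enrichment results depend on provider database versions and are
  therefore not byte-reproducible; the offline engine is, and is the one
  used in pipelines that must be deterministic.
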