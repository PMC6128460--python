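# Methods

## Ranking model

Alternatives (raster grid cells, indexed row-major as k = (i−1)·J + j) are
compared on M criteria under a minimization convention. Weak Pareto
dominance — every criterion ≤ and at least one strictly < — induces a strict
partial order; ranking peels non-dominated sets: the front of all valid
alternatives gets rank 1, the front of the remainder rank 2, and so on until
all are ranked. Consequences relied on throughout the package and verified
by its property tests:

- dominance implies strictly lower rank;
- ranks over ranked alternatives are contiguous from 1 and the first front
  is never empty (a finite strict partial order always has minimal
  elements);
- identical criteria vectors are mutually non-dominating and co-rank;
- the id → rank map is independent of row order;
- any strictly increasing transform of a single criterion column — hence
  any positive per-column weight — leaves all ranks unchanged. This is the
  formal reason the method needs no elicitation of criteria weights; the
  package exposes `check_weighted_consistency` to demonstrate the pairwise
  version (dominance ⇒ weighted-sum order for every strictly positive
  weight vector). The stronger claim that *every* lower-ranked alternative
  beats every higher-ranked one under any weighted sum does not follow from
  the pairwise argument and is deliberately not asserted or implemented.

### Algorithm and scale

Identical rows provably share a rank, so the ranker deduplicates rows,
ranks unique vectors, and re-expands. Unique vectors are ranked by a
dominance-count peeling scheme: dominator counts are accumulated in
blockwise pairwise passes (block size 256, so peak memory is O(block · K)
rather than O(K²)); each peeled front then decrements the counts of the
rows it dominates. Total work is O(K²M) across all fronts. A single
criterion short-circuits to dense ranking (1-D Pareto ranking is sorting).
The intended scale is up to ~10⁵ unique vectors and M ≤ 12 on one CPU;
the test and acceptance workloads use K ≤ 10⁴ (a 100×100 grid), which ranks
in seconds.

Ties need no special casing beyond dedup-and-reexpand: under the weak
dominance definition equal vectors never dominate each other, so co-ranking
falls out of the definition.

### Composite rank-of-ranks

As M grows, dominance becomes rarer and many cells collapse onto few
fronts. Composite ranking treats the ranks from two (or more) previous
rankings as the criteria of a new decision problem and Pareto-ranks those,
widening the attainable rank range. An alternative unranked in any
component is unranked in the composite, consistent with the rule that only
complete criteria vectors are ranked.

## Value functions and decision matrices

Attributes become criteria via the linear min-max maps f (order-preserving,
for lower-is-priority attributes) and g (order-reversing); both land in
[0, 1] with lower = higher priority and satisfy f + g = 1 on non-constant
columns. Normalization statistics are computed over in-mask, non-missing
cells only; whether to normalize per matrix or globally is configurable in
principle but the per-matrix, non-missing convention is the default and the
one used everywhere here. A constant column would divide by zero; it is
mapped to all zeros with a warning, since a criterion with no variation
expresses no preference and cannot affect dominance.

A decision matrix has one row per in-mask cell; a row is valid only if all
its criteria are non-missing *in that matrix*, so validity patterns may
differ between criteria subsets. Matrices concatenate column-wise
([F′ | S′] etc.) with validity the conjunction of component validities. The
six standard matrices and three composite pairings are named presets; the
direction registry for the twelve standard attributes (g for fire count,
ignition probability, road/development density, the four richness indices
and both genetic layers; f for fire return interval departure and patch
area) ships as a default that users can override.

## Attribute derivations

- **Fire count**: elementwise sum of binary per-fire perimeter rasters.
- **Focal (road) density**: proportion of cells whose centers lie within a
  metric radius (default 500 m at 50 m cells) of the focal cell's center
  that carry the indicator. Window membership is center-to-center distance
  ≤ radius; at grid borders the denominator counts only in-grid cells, so
  border values remain proportions of the truncated window. Implemented as
  two correlations with the disk kernel (indicator and all-ones).
- **Development density**: (n_urban + 0.3 · n_agriculture) / n_total over
  the same window; the 0.3 weight reflects agriculture's lower impact and
  is a parameter. Urban and agriculture must be disjoint per cell.
- **Patch area**: connected-component labeling of open (non-road,
  non-urban, in-mask) cells; every cell receives its component's area in
  hectares; blocking cells are missing. 4-connectivity is the default so a
  rasterized diagonal road still severs patches (8-connectivity available).
  Urban cells block by default alongside roads; configurable via the
  blocking layer passed in.
- **Taxon richness**: sum of per-species habitat-suitability surfaces in
  [0, 1]; for taxa whose models are threshold-calibrated (plants here) each
  surface is first binarized at its threshold. NaN propagates.
- Ignition probability, fire return interval departure, and the genetic
  diversity/divergence surfaces are outputs of external models and are
  consumed as provided.

## Spatial I/O and summaries

Rasters are ESRI ASCII grids (plain text, standard interchange) or
single-band TIFF via tifffile with ESRI world-file (.tfw) georeference; all
grids in a run must align in shape, origin, and cell size. Rank rasters are
integers with nodata 0 (ranks start at 1), and write→read round-trips are
bit-exact.

The priority class is "rank ≤ the q-th percentile rank" (default q = 0.25)
with the threshold computed by the nearest-rank rule on the empirical CDF:
the smallest rank t such that the fraction of ranked cells with rank ≤ t is
≥ q. Interpolating quantile estimators are unsuitable because ranks are
small integers with heavy ties and an interpolated threshold can be a value
no cell attains; with heavy ties the classified fraction can substantially
exceed q, which is expected behavior, not an error. The threshold is
computed per rank map (per decision matrix) over all its ranked cells, then
applied within each (zone × conservation status) stratum; summaries report
cell counts and percentages per stratum, and stratum counts sum to the
global classified count by construction. Median rank profiles per grid row
or column support west–east / north–south gradient reading.

## Simulation design

The rank-range study draws K alternatives from an equicorrelated
multivariate Gaussian (unit variances, common pairwise correlation ρ,
feasible for ρ ∈ (−1/(M−1), 1]; ρ = 1 duplicates a single column) and
rescales each column to [0, 1] with f, which changes no comparisons. Only
qualitative trends are asserted: the mean maximum rank is non-decreasing in
ρ (more positively correlated criteria ⇒ more dominance ⇒ more, smaller
fronts) and decreasing in M at fixed ρ (more criteria ⇒ dominance rarer ⇒
fewer fronts). The analytic limits anchor both ends: with M = 2 and the
second column a strictly decreasing function of the first (ρ → −1, no
duplicates) every alternative is non-dominated and the maximum rank is 1;
with duplicated columns (ρ = +1) the ranking degenerates to dense ranking
of one column and the maximum rank equals the number of distinct values.
The default experiment uses K = 1000, M ∈ {2,…,6}, ρ ∈ {−0.9, 0, 0.9}, 20
replicates; replicate r uses seed + r, and every source of randomness flows
from one explicit seed.

## Synthetic data

Two generators, both deterministic per seed:

- `synthetic_stack`: generic aligned continuous layers built from per-cell
  equicorrelated Gaussian draws smoothed into random fields (identical
  smoothing preserves inter-layer correlation), with random mask holes
  (default 2%), a chosen fraction of in-mask cells missing in one layer,
  contiguous west-to-east zone bands, and blob-shaped conserved areas.
- `synthetic_landscape`: a primitive-layer stack emulating a fire-prone,
  fragmented coastal landscape — binary fire-perimeter blobs biased toward
  the interior, a rectilinear road network and urban/agriculture footprints
  densest in the west, logistic-transformed random fields as per-species
  suitability surfaces, and the four forwarded continuous layers, with
  missingness injected into the forwarded layers (emulating gaps in
  external model coverage, and producing validity patterns that differ
  between criteria subsets as they do with real inputs). Urban cells are
  excluded from the analysis mask. Default: 100×100 cells at 50 m, 6
  fires, 17 species across four taxa, 10% of in-mask cells missing in one
  forwarded layer, 4 zones.

What these emulate — and what they do not: the generators reproduce the
structural features the method interacts with (aligned grids, correlated
spatially smooth layers, binary footprints, missingness, zonal strata) but
not the empirical correlation structure of any real county's threat and
biodiversity layers, real road topology, realistic fire-size distributions,
or SDM error. Passing tests therefore demonstrate the correctness and
invariances of the *method* and pipeline plumbing, not any substantive
claim about where real conservation priorities fall.

## Numerical choices and degenerate inputs

- Missing marker: NaN in memory; file nodata −9999 for float layers, 0 for
  rank rasters.
- A cell missing any criterion of a matrix is excluded from that matrix's
  ranking and carries nodata in its rank map.
- No randomness anywhere in ranking; dedup uses lexicographic row order
  internally but output ranks are order-independent.
- Weighted-consistency checks use a 1e-12 absolute slack against float
  round-off in the weighted sums.
- Constant criteria: all-zero column with a warning (see above).
- Degenerate grids (empty mask, all-blocking patch input, all-missing
  column, no valid alternatives) raise with specific messages rather than
  returning empty results.

## Known limitations

- The ranker is quadratic in the number of unique criteria vectors;
  county-scale problems (millions of cells) need coarser cells, masking, or
  a tiled strategy.
- Rankings ignore spatial relationships between cells (no connectivity or
  adjacency bonus); criteria carry all spatial information.
- No secondary within-rank prioritization is provided; within-front
  trade-offs are left to other MCDA methods or expert judgment.
- Vector inputs (road lines, fire-perimeter polygons) must be rasterized
  upstream; only aligned single-band rasters are consumed.
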