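# Methods

This note documents the models, parameter choices and numerical
decisions behind `flcoder`, and what the synthetic-data experiments do
and do not demonstrate.

## Geometry

Metric grid cells require a metric CRS, so all gridding happens in
projected metres. Geographic (WGS84) input is projected to the UTM zone
of the study-area centroid with an in-package transverse-Mercator
(Krüger-series) conversion, accurate to well under a millimetre in-zone
(cross-checked in the tests against the independent USGS series and a
numerically integrated meridian arc). Grids are anchored at the
bounding-box minimum corner with half-open cells
`[x, x+s) × [y, y+s)`, so every point belongs to at most one cell and
boundary points are never double-counted. Partial edge cells are kept
rather than clipped: the audit walks physical blocks, and clipping
slivers would silently shrink the sampling frame. Great-circle distances
use the haversine formula with the IUGG mean Earth radius 6371.0088 km.

## Deduplication

Cross-source duplicates are detected pairwise: two place records are
duplicates when they lie within **25 m** *and* their canonical names
reach **0.85** token-set similarity. Both thresholds are configurable;
the values are design choices at urban-storefront scale (GPS and
source-coordinate scatter of a few metres to tens of metres; name
spellings that differ in token order, accents or extra tokens). When
either name is empty, location alone within 10 m decides. Groups are
formed by single-linkage union-find, which is deterministic and
independent of input order; the representative record comes from the
highest-priority source (curated file > places API > OSM), ties broken
by tag richness and then record ids. Candidate pairs are found with a
KD-tree on a local equirectangular projection, so deduplication is
near-linear in practice. The name score is the classic token-set ratio
computed with the standard library sequence matcher, symmetrized
explicitly because the underlying ratio is argument-order dependent.

## Classification

Each facility receives exactly one of four food categories — fast-food
restaurant, bar/restaurant, supermarket, convenience store & others —
or `non_food`. Curated source tags (e.g. `shop=supermarket`) outrank
storefront-name evidence, since tags are vocabulary-controlled while
names are free text. Names are normalized (NFKD accent stripping,
lower-casing, punctuation removal) and scanned for whole-token keyword
phrases from a YAML lexicon with Spanish, Catalan and English blocks.
On multiple hits the precedence order **fast_food > supermarket >
bar_restaurant > convenience_other** applies: the more specific
categories first, so "restaurante kebab" codes as fast food rather than
the generic bar/restaurant. The shipped lexicon is a reconstruction
assembled from common storefront vocabulary and OSM tagging practice
(its header says so); it is meant to be edited per study.

## Access metrics

Network distance is the shortest path on an undirected road graph
(edges carry lengths in metres), with both endpoints snapped to the
nearest node within 200 m and the snap offsets added. Without a
network, great-circle distance times a **1.3 detour factor** is used —
the standard street-grid correction. Travel times assume walking at
5 km/h and cycling at 15 km/h; all three constants are parameters.
Density counts facilities within a radius (boundary inclusive) and
reports the nearest facility even when it lies beyond the radius.

## Sampling design

The audit sample of grid cells is sized by the finite-population
Cochran formula for a proportion,
`n = ceil(N z² p(1−p) / (e²(N−1) + z² p(1−p)))`, capped at N, with the
two-sided normal quantile z for the confidence level. Ceil-rounding and
the cap are conservative choices. At N = 1375, p = 0.5, e = 0.05 and
95% confidence this gives n = 301 (22% of the frame); the
infinite-population limit is 385. The defaults p = 0.5 (maximum
variance) and e = 0.05 are the conventional design values and reproduce
that sample size. Cell selection is simple random sampling without
replacement from a seeded generator; a chi-square test in the suite
confirms uniform inclusion probabilities.

## Audit comparison

Coder facilities and audit records are compared cell by cell over the
sampled cells. Matching is greedy one-to-one, consuming candidate pairs
best-name-similarity first (distance breaks ties), where candidates
must pass **50 m** and **0.75** similarity gates — deliberately looser
than deduplication, because auditor GPS fixes and hand-typed storefront
names are noisier than source metadata. Unmatched coder records are
false positives, unmatched audit records false negatives, and

    fp_rate = FP / (matched + FP)      fn_rate = FN / (matched + FN)

i.e. the share of coder output not physically present, and the share of
on-the-ground facilities the coder missed. Degenerate denominators
yield flagged undefined values, never exceptions, so batch reports do
not abort. The market correction replaces all facilities inside a
market polygon by a single facility at the polygon centroid (modal
member category, precedence breaking ties), matching the fieldwork
convention of counting a covered market once; overlapping market
polygons are rejected.

## Agreement statistics

With rows = grid cells and columns = the two methods, a two-way ANOVA
gives MS_R, MS_C, MS_E and

    ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1)MS_E + k(MS_C − MS_E)/n)
    ICC(A,k) = (MS_R − MS_E) / (MS_R + (MS_C − MS_E)/n)

the absolute-agreement forms of the two-way mixed model (the mixed and
random variants share these estimators). The F statistic for the test
against a true value of 0 is MS_R/MS_E with df1 = n−1; the reported
denominator df is the Satterthwaite approximation evaluated at the
single-measure estimate — the same ν used by the confidence interval —
which is why df2 is generally non-integer and differs from
(n−1)(k−1). The CI is the standard absolute-agreement interval for
ICC(A,1), stepped up to k by the Spearman–Brown relation. The suite
verifies estimate, CI, F and dfs to 1e-8 against an independently coded
reference and against `pingouin.intraclass_corr`. Bands: < 0.5 poor,
0.5–0.75 moderate, 0.75–0.9 good, ≥ 0.9 excellent, boundaries assigned
upward.

Krippendorff's alpha is computed from the coincidence matrix:
`alpha = 1 − D_o/D_e` with the interval difference `δ(v,v′) = (v−v′)²`
by default — counts are numeric, and the interval metric is the natural
choice; ratio and nominal metrics are available because the choice is
not forced by the design. Units with fewer than two codings contribute
nothing to D_o; if all pooled values are identical, D_e = 0 and alpha
is returned as flagged-undefined. The paired t-test uses the n−1 sample
SD of differences; a zero-variance difference vector is flagged rather
than raised. Bland–Altman reports bias and bias ± 1.96·SD limits with
the per-pair (mean, difference) points.

In reports, significance is printed to three decimals, so "0.000" means
p < 0.0005. Note that with n sampled cells the paired t-test has
df = n−1 (300 for a 301-cell sample); published applications of this
design sometimes show larger df from pooling across strata, which this
package does not do.

## Synthetic data

`CitySpec` defaults describe the emulated study conditions: a
5500 m × 2500 m rectangle (exactly 1375 cells of 100 m), 935
facilities, and a category mix of 26% bars/restaurants, 19% fast food,
10% supermarkets, 25% convenience & others, 20% non-food — the two
leading shares and their ordering follow the validated case study; the
split of the remainder is this package's choice of a plausible Catalan
urban mix. Names are built from a true-category lexicon keyword plus
filler tokens disjoint from the lexicon, so noiseless names are
classifiable by construction; `name_noise` introduces typos/extra
tokens. Duplicate listings from a second source are injected at 5%
within a few metres. Clustered mode draws facilities around Gaussian
cluster centres (SD 150 m).

`simulate_audit` injects the comparison's error structure from the
coder's perspective: with probability `fp_rate` a facility is treated
as a coder phantom (present in the sources, absent on the street, hence
omitted from the audit and a false positive for the coder); audit-only
spurious records are added so their expected share of the audit is
`fn_rate` (facilities the coder missed); audit coordinates get Gaussian
GPS jitter (default 5 m) while grid ids always come from true
locations, as fieldwork assigns the cell being walked. Defaults
fp = 0.14, fn = 0.08 mirror the error rates the design is meant to
detect.

What passing the synthetic experiments shows: the pipeline recovers
injected error rates without bias at realistic sizes, the statistics
respond monotonically to injected noise, and a noiseless run is exactly
perfect end to end. What it does not show: robustness to real-world
phenomena the generator omits — systematic coverage gaps of the
sources, multilingual names outside the lexicon, clustered GPS error in
street canyons, auditor transcription variants of the same name, or
opening/closure churn between source snapshot and fieldwork.

## Problem sizes in the test suite

The recovery experiment uses 100 seeds of a 500-cell city with 935
facilities (so the binomial standard error of the estimated rates,
~0.013, is comfortably inside the ±0.03 recovery band); the ICC noise
monotonicity experiment averages 200 seeds of 500-cell count tables per
noise level; the oracle equivalence check uses 100 random 50×2 tables.
These sizes make the whole suite run in well under a minute while
keeping every stochastic conclusion stable across seeds.

## Known limitations

- Live source adapters (places API, Overpass) are stubs; the package
  operates on exported GeoJSON/CSV. This keeps the method fully
  reproducible offline.
- The keyword lexicon is a reconstruction; classification quality on
  real data depends on curating it for the study region.
- Routing ignores one-way streets, turn restrictions and elevation.
- The UTM conversion covers WGS84 only, which is what the target data
  sources provide.
- Greedy matching is near-optimal at block scale but is not a global
  assignment; at densities far beyond one facility per few metres an
  optimal matcher could differ.
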