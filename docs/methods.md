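# Methods

## Problem and model

A loci combination is appraised by how well its genotypes separate the
varieties in a sample population. The package treats a genotype matrix as
the only evidence: *m* samples × *n* loci of unordered diploid allele pairs
(SSR fragment sizes or SNP bases as opaque labels), with an explicit
missing state. Three steps turn it into a score:

1. **Pairwise differencing.** For each unordered sample pair, count the
   differing loci among the loci called in *both* samples. A locus differs
   iff the unordered allele pairs are unequal — a heterozygote sharing one
   allele with a homozygote (A/T vs A/A) is *different*; the statistics use
   no partial credit. Supported metrics are the count and the fraction of
   differing loci; model-based genetic distances are out of scope.
2. **Threshold classification and chain grouping.** A pair is *different
   varieties* when its difference reaches the threshold M (`count` metric:
   integer ≥ 1; `percentage`: fraction in (0, 1]). M = 1 with the count
   metric is the perfect-match rule. Same-variety pairs are merged
   transitively (the discrimination chain), so repeated groups are the
   connected components of the same-variety relation. Under partial-match
   thresholds (M > 1) transitivity is an assumption, not a theorem — two
   samples in one group may differ by ≥ M — but it is the only grouping
   under which the group-count indices remain well defined across a
   threshold sweep, and it is the rule adopted here. Under perfect match
   on complete data the components coincide with grouping by exact
   genotype-vector identity (property-tested against that oracle).
3. **Index computation.** From the partition's category table
   ({group size R → group count T}, m, t groups, D singletons):
   P-VDP = 1 − ΣC(R,2)·T / C(m,2); C-VDP (chain form)
   = 1 − 2ΣC(R,2)·T / (m(m−1)); R-VDP = t/m. C-VDP is also computed in its
   defining traversal form over all ordered pairs, which is the one valid
   under partial-match thresholds and missing data. TDP = 1 − Π(1 − DPⱼ)
   with DPⱼ = 1 − Σ g² over per-locus genotype-class frequencies
   (unordered diploid pairs as classes, computed over called samples only).
   The genotype-class form of DP — rather than an allele-frequency form —
   is a documented choice: it matches the "different genotypes of two
   random individuals" reading and reproduces the skewed-spectrum value
   (DP = 410/42436 per locus, TDP ≈ 0.09 at ten loci) that anchors the
   terminal simulated population.

### Validity conditions

P-VDP requires the perfect-match rule and complete data; partitions record
both flags and `p_vdp` refuses otherwise. C-VDP and R-VDP accept any
threshold and tolerate missing data. TDP is threshold-invariant by
construction.

### Missing data

Loci missing in either sample of a pair are excluded from numerator and
denominator alike. Masking can therefore only push a pair's observed
difference below the threshold, never above it: C-VDP and R-VDP are biased
downward (a type-II error), never upward — an invariant the suite
property-tests. A pair left with *zero* overlapping loci is undefined; the
default policy raises, and `undefined_pairs='same'|'different'` resolves it
explicitly. The missing-data sweep defaults to `'same'`: with no evidence
of a difference the pair cannot be declared different varieties, consistent
with the underestimation direction of the masking error.

## Simulated populations

The generator reproduces a four-array design grid of 84 populations, each
206 samples at 10 four-allele SNP loci. A row (D, R, T) gives D singleton
varieties plus T groups of R identical samples (D + R·T = 206). Array 1
grows one repeated group (R: 2 → 205); arrays 2–4 grow the number of groups
(T) at fixed sizes R = 2, 5, 10. The 84 rows are hard-coded constants and
checked by the D + R·T invariant.

Variety genotypes are drawn in one of two regimes:

- `all_loci`: varieties differ at every locus. Each four-allele locus has
  C(4,2) + 4 = 10 unordered diploid classes, so at most 10 varieties fit;
  per locus, a random permutation of the classes is assigned to varieties.
  This regime fixes the per-locus class spectrum — e.g. counts (205, 1) in
  the terminal array-1 population — on which TDP depends.
- `at_least_one`: varieties receive unique 10-locus class vectors
  (duplicates are resampled), which suffices for the partition-based
  indices since they depend only on group structure.

`auto` (the default) uses `all_loci` when the variety count permits, else
`at_least_one`. Samples are shuffled so group membership is not encoded in
row order; everything is deterministic given the seed.

What the generator does *not* emulate: realistic allele-frequency spectra,
linkage between loci, genotyping error, or the shared per-locus classes
among varieties that real panels show. Passing tests therefore demonstrate
the correctness of the statistics and their designed sensitivity ordering
on controlled group structures, not performance on any real crop panel.
Missing data are injected as a fixed per-sample quota — every sample loses
exactly round(rate × n_loci) calls at uniform positions — matching a
"proportion per sample" reading rather than a global Bernoulli mask; real
missingness is typically locus-correlated, which this does not model.

## Sensitivity analyses

Sensitivity curves evaluate one index over an ordered family of populations
(x = 1..21 for a design array) and summarise the trend with an ordinary
least-squares slope on the 1-based index — the regression convention that
reproduces the published array slopes (−0.0487, −0.0242, −0.0386, −0.0437
for R-VDP; −0.0021 for P-VDP on array 4). The threshold sweep grids C-VDP
and R-VDP over nested locus subsets × M ∈ {1..4}; the missing-data sweep
masks at rates 0–50% in 10% steps and reports the Pearson correlation of
each rate's series against the complete-data series, paired by subset size
(identical series are reported as r = 1 exactly; constant series give NaN).
Nested subsets come from one seeded permutation of the loci truncated to
each size, so every subset contains the next smaller one.

## Numerical choices

- Index values are computed and returned at full double precision;
  comparisons against printed values round half-away-from-zero to the
  printed decimals.
- TDP accumulates Σ log(1 − DPⱼ) and returns −expm1 of it, keeping
  precision when the value approaches 1 (differences at the 1e-10 level
  are meaningful in the design's early populations).
- Pairwise counting is O(m²·n) with O(m²) memory (one locus at a time);
  the full 84-population regeneration takes ~1–2 s.
- Connected components come from scipy's csgraph on the boolean
  same-variety adjacency; components are unique, so no tie-breaking
  arises and the result is independent of sample order (property-tested
  under shuffles).
- Degenerate inputs: appraisal requires m ≥ 2; ploidy is fixed at 2 and
  haploid cells are rejected at parse time rather than imputed; a locus
  with zero called samples makes DP (hence TDP) undefined and raises.

## Scope and limitations

The grouping under M > 1 is chain (single-linkage-style) merging; complete-
linkage alternatives would give different R-VDP values on threshold sweeps
and are not implemented. Genetic-distance pair metrics, dominant markers,
polyploid data, and combinatorial search over locus subsets (for which
these indices would serve as the fitness function) are out of scope. Real
SSR/SNP panels for sorghum, wheat, maize and rice were used in the original
sensitivity studies; this package reproduces those workflows on synthetic
stand-ins only, so figure-level turning points for real species are not
recomputed here.
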