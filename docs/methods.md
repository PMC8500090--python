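# Methods

## The problem being modelled

Malaise traps collect flying insects spanning three orders of magnitude
in body length.  Metabarcoding reads from a homogenized bulk sample are
roughly proportional to template DNA, hence to tissue biomass, distorted
by species-specific primer efficiency.  Because dry weight scales
super-quadratically with body length, a handful of large specimens can
monopolize a library and push the many small taxa below any sensible
abundance threshold.  Sieving the dried sample into four size fractions
(S < 2 mm, M > 2 mm, L > 4 mm, XL > 8 mm), lysing each fraction with
buffer dosed proportionally to its tissue weight, and pooling the lysates
in chosen volume proportions lets the experimenter re-weight the size
classes before a single extraction.  Because buffer volume tracks tissue
weight, DNA concentration is assumed uniform across lysates, so *volume*
proportions translate directly into *fraction weight* proportions in the
pooled template.  Pooling proportional to fraction dry weight (`g`)
therefore reconstructs the unsorted sample; equal pooling (`equ`) and the
small-favouring schemes (`invg`, `fibo`, `log`, `4x`) progressively
enrich the small fraction.

## Quality filtering

Cleanup is a fixed three-step pass, in the order the steps are applied to
sequenced data:

1. **Negative-control subtraction.** For each OTU the maximum count over
   all negative controls is subtracted from every sample, floored at
   zero.  This removes reagent and cross-talk signal rather than whole
   OTUs.
2. **Relative-abundance threshold** (default 0.01% per sample).  The cut
   is *strict*: a count exactly at the threshold survives.  Column totals
   are computed once, before any zeroing, and not recomputed iteratively;
   a single pass is what the cleanup describes, and iterated recomputation
   would cascade unpredictably.  Comparisons are done on the percent scale
   (`count·100/total ≥ threshold`) because the canonical boundary case —
   1 read in 10,000 — is exact in floating point there.
3. **Replicate consistency + merge.** A count absent from either
   extraction replicate is zeroed in both; the two replicate columns are
   then summed into one library.  Sums (not means) preserve read-depth
   semantics.

All-zero OTU rows are dropped only at the end so that the per-step log of
reads/OTUs removed stays interpretable.

## In silico pooling and the ratio sweep

Pooling operates on relative abundances over the union of the input OTU
sets.  A `PoolingScheme` is a proportion vector over fractions summing to
one; pooling by dry weight is the same operation with normalized weights.
The two-fraction sweep reconstructs S+M and L+XL by dry weight from the
quality-filtered fraction libraries, then mixes them at ratios 0–100% in
5% steps; at each ratio, OTUs below 0.01% mixed relative abundance are
dropped and the survivor count recorded.  Thresholding is applied to the
mixed relative abundance (equivalently fractional expected counts at
10,000 reads, where 0.01% is exactly one read), avoiding arbitrary
integer rounding ties.

The equal quarter-depth pool filters each fraction at 0.04% of its own
total — one read at a quarter of 10,000 — and takes the union of
survivors, emulating pooling the four individually sequenced fractions at
a quarter of the budget each.

Exact proportions of the named small-favouring schemes are configurable;
the defaults are `equ` = (¼,¼,¼,¼), `4x` = (64,16,4,1)/85 (each smaller
fraction four times the next larger), `log` = (1000,100,10,1)/1111,
`fibo` = (8,5,3,2)/18 (descending Fibonacci numbers over S,M,L,XL), `invg`
= normalized reciprocal dry weights (zero-weight fractions get zero
share).  `fibo` has no canonical definition, so the descending-Fibonacci
default was fixed once as a reasonable mid-strength enrichment between
`equ` and `4x`.

## Threshold-based rarefaction

A sequencing depth *d* is simulated by retaining only OTUs whose relative
abundance reaches 100/*d* percent — the abundance one read would have in a
library of *d* reads.  "Not reached" means strict exclusion;
exact-threshold OTUs are retained, consistent with the 0.01% filter, and
at *d* = 10,000 the two operations coincide exactly (tested).  This is
deterministic, monotone in depth (survivor sets are nested), and free of
the stochastic noise of repeated resampling; classical
without-replacement rarefaction and richness extrapolation are
deliberately out of scope.

Recovery curves are computed on a log-spaced grid of 19 depths from 500
to 50,000 by default.  Inputs can be prepared in two modes, recorded in
provenance: `pooled` (negatives subtracted, replicates summed directly,
no consistency or 0.01% filtering — the mode matching how the rarefaction
inputs of the original analysis were prepared) or `filtered` (full quality
filter first).  The **depth-equivalence factor** of a strategy is
reference_depth / d*, where d* is the smallest grid depth at which the
strategy's richness reaches the reference strategy's richness at the
reference depth (default `g` at 50,000).  Grid lookup is used rather than
interpolation: the quantity is an order-of-magnitude statement and
interpolating a step-like curve would imply false precision.  A strategy
that never reaches the target reports "not reached" together with its
maximum grid richness.

## Size-class assignment and dissimilarity

For each OTU, evidence per size class is the *sum* over source samples of
its relative abundance in that sample's fraction library; the class with
the highest combined abundance is assigned.  Summation (not averaging)
was chosen because it is scale-free across libraries of equal design and
identical to averaging in the balanced case; ties resolve toward the
smaller class — deterministic, flagged in the output, and consistent with
the motivating concern of small-taxon detection.  OTUs with zero evidence
in every fraction library (detected only in pooled lysates) are
`unassigned`; spectrum percentages are computed over all OTUs including
unassigned ones.

Jaccard distance is computed on presence/absence, Bray–Curtis on
per-sample relative abundances (both via scipy); libraries emptied by
filtering are excluded from the dissimilarity stage by name.  Dendrograms
use average linkage (UPGMA) by default — no linkage was prescribed, and
UPGMA's monotone merge heights suit distance matrices in [0, 1] — and are
serialized to Newick via scikit-bio.

## The simulator

`SimConfig` defaults describe one study: 3 bulk samples drawn from a
shared 300-species pool, 4 size fractions, duplicate extractions, 6
pooling strategies, 9 negative controls, 10,000 reads per library.

- **Community.** Species mean abundance ~ LogNormal(μ_a = 1.0,
  σ_a = 1.2); per-sample specimen counts are 1 + Poisson(abundance).
  Species mean body length (mm) ~ LogNormal(μ_L = 0.7, σ_L = 0.9)
  truncated to 0.5–30 mm, giving a median near 2 mm — most species small,
  a thin tail of large ones.  Individual lengths scatter around the
  species mean with σ = 0.1 on the log scale (~10% CV, typical adult
  size variation).  Traits (length, efficiency) are species properties
  shared across samples; abundances are redrawn per sample.
- **Allometry.** Dry weight (mg) = 0.0305·L^2.62 with L in mm, a widely
  used general-insect length–weight fit.  Both coefficients are
  configurable.
- **Sieving.** Stacked meshes of 8, 4, 2 mm hole diameter.  A specimen is
  retained by the largest mesh m with k·L ≥ m (else it falls through to
  S), with effective-width factor k = 0.5: round holes retain by body
  cross-section, not length.  With probability 0.05 a retained specimen
  sheds a fragment carrying 2% of its weight into a uniformly chosen
  smaller fraction (its own weight reduced accordingly, so total dry
  weight is conserved exactly).  This one channel stands in for both
  broken-off body parts and small specimens attached to large ones.
- **Sequencing.** One OTU per species.  Read probabilities within a
  library are proportional to (species biomass in the pooled material) ×
  (per-species amplification efficiency, 10^N(0, 0.5) — fixed per species
  because primer bias is sequence-determined).  Counts are multinomial at
  depth 10,000, so every library sums to its depth; empty fractions give
  all-zero columns.  Negative controls draw Poisson(0.05) stray reads per
  OTU.
- **Determinism.** One scenario seed is spawned into per-stage seeds via
  `numpy.random.SeedSequence`; identical configuration and seed give
  bit-identical tables, and the run manifest's SHA-256 digests verify it.

What the simulator does *not* emulate: sequence errors, chimeras, OTU
clustering artifacts (it operates downstream of clustering), PCR
cycle-by-cycle dynamics, mitochondrial copy-number variation, taxonomy.
Passing tests therefore demonstrate that the *analysis* behaves correctly
on data with the assumed biomass/bias structure, not that real libraries
satisfy those assumptions.  Leakage rates and the biomass distribution
are field-realistic guesses, fixed once; conclusions drawn from the
simulator are directional (orderings, interior optima), never numeric
reproductions of any particular sequencing run.

## Problem sizes and acceptance checks

The acceptance script and the directional acceptance test each run twenty
independently seeded studies at the default scenario size (300 species,
69 libraries, 10,000 reads each) — enough for stable orderings while
keeping a full run under a minute on one core.  They check four patterns:
post-filter richness ordering g ≤ equ ≤ each small-favouring scheme
(means over seeds); mean depth-equivalence factor of small-favouring
schemes > 1; the S+M/L+XL sweep's optimum strictly inside (0, 100) with
leakage on; and ≥ 95% agreement between assigned and true size classes
with leakage off.  Exact-arithmetic oracles (rational-number enumeration)
back the sweep and threshold logic on small profiles.

## Known limitations

- The named schemes' exact study proportions (beyond `g` and `equ`) are
  not canonical; users reproducing a specific experiment should supply
  their own vectors.
- Size-class truth is defined by intact-biomass majority; species whose
  individuals straddle a mesh boundary nearly 50/50 are intrinsically
  ambiguous, which bounds assignment accuracy below 100% even without
  leakage.
- The depth-equivalence factor depends on the grid resolution; values
  between grid points are reported at the next deeper grid point
  (conservative, i.e. factors are underestimated).
- `OTUTable` is deliberately plain (pandas-backed, TSV only); BIOM/HDF5
  containers and any sequence-level processing are out of scope.
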