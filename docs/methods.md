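# Methods

This note records the model the package implements, the conventions and
numerical choices behind it, what the synthetic-data generator does and does
not emulate, and the design decisions taken where more than one reading was
defensible.

## Data model and coordinate conventions

A mutation catalog is a table of single-base substitutions (SBS): donor id,
chromosome, 1-based position, reference and alternate allele, one row per
donor-mutation. Indels and identity rows are filtered on read and tallied,
never fatal. Interval annotations are BED-style 0-based half-open spans.
The two conventions meet in exactly one place — overlap and binning
operations convert `pos` to `pos - 1` — so no other module performs
coordinate arithmetic. Chromosome names are normalised (leading `chr`
stripped, upper-cased, `M` → `MT`) because ICGC exports and enhancer
annotations disagree on the dialect. Duplicate rows are retained: public
mutation exports do not always mark multi-sample duplicates, and silently
de-duplicating would change donor totals; callers who need distinct sites
can drop duplicates before analysis.

## Substitution categories and forms

The 12 substitutions collapse into six categories named by their
pyrimidine-reference form (C>A, C>G, C>T, T>A, T>C, T>G). A purine-reference
call (e.g. G>T) is the same biological event read off the opposite strand,
so it maps to the complementary category with `is_pyrimidine_form = False`.
Category-level quantities always pool both forms; the forms are kept
distinguishable because their *difference* is the strand-bias signal.
Trinucleotide (96-channel) contexts are out of scope.

## Density profiles and MPKM

Around each focal point (interval start, midpoint `floor((start+end-1)/2)`,
or end base), mutations are tallied per form into `2·flank/bin_width` bins
(defaults 2000 bp and 100 bp → 40 bins). The window is half-open,
`[-flank, +flank)`, and offset 0 (the focal base) belongs to the first
downstream bin, which makes the boundary deterministic. Counting is **per
focal occurrence**: a mutation inside two overlapping windows contributes to
both, because the profile describes the environment of focal points, not a
partition of mutations. eRNA intervals are treated as unstranded (they are
bidirectionally transcribed and annotations carry no direction);
strand-aware flipping exists only in the composition profiler for
comparisons against stranded features such as protein-coding TSSs.

Bin densities are normalised as

    mpkm(form, bin) = count / (n_focal · bin_width/1e6 · f(category) · K)

with `K` the cohort total in thousands. This mirrors the per-donor burden
formula at bin granularity: the profiled span of one bin across the cohort
is `n_focal · bin_width` bases. The composition factor `f` defaults to 0.2
for C-rooted and 0.3 for T-rooted categories — the per-strand frequency of
the substrate base under a ≈41% GC genome — and can instead be recomputed
from a reference as `gc/2` and `(1-gc)/2` over the profiled windows. The
defaults are applied genome-agnostically so results are identical with and
without a FASTA.

Per-donor burden uses the same formula with `C` the donor's
region-overlapping count, `M` the *merged* region size in Mb, and `K` the
donor's genome-wide category total in thousands. Overlap counting is by
membership against the merged region (duplicated or mutually overlapping
intervals cannot double-count), consistent with how `M` is measured. A
combined per-donor row pools the six categories' `C` and `K` with
`f = 0.25`, the composition-weighted mean of 0.2 and 0.3 under the implied
40/60 base split. MPKM is reported at full precision; one-decimal display is
a formatting concern (the published worked example's C-rooted one-decimal
values are not reachable from its printed inputs under exact evaluation,
which recomputes 1.8/2.9/2.3 where 1.7/2.8/2.2 were quoted — the T-rooted
values match exactly).

## Peak/dip test

The background rate for a category is estimated from mutations with
`|offset| ∈ [min_dist, max_dist)` of any focal point (default 5–50 kb;
simulation studies in this repository use 5–20 kb so that synthetic
chromosomes stay small), counted per occurrence and rescaled to one bin:
`λ = n_bg · bin_width / (2·(max_dist − min_dist))`. An empty window falls
back to a 0.5 pseudo-count and is flagged. The maximum-count bin is scored
with the exact upper Poisson tail `P(X ≥ obs | λ)` and the minimum-count bin
with the lower tail; a peak or dip is called when the tail falls below the
nominal threshold (default 1e-5, deliberately stringent because the profile
offers 40 candidate bins). Both candidate tests are always reported, and a
per-bin mode (all bins, both tails, BH-ready) is available for callers who
prefer a familywise treatment.

## Strand-bias test

Within a category and region (left half of the bins, right half, or all),
the per-bin counts of the pyrimidine form are paired with the purine form
and the differences tested with a two-sided Wilcoxon signed-rank test. Zero
differences are dropped. For ≤ 25 informative bins the exact null is built
by dynamic programming over sign assignments with tie-averaged ranks
(doubled to integers); beyond that a normal approximation with tie-corrected
variance and 0.5 continuity correction is used. The two forms share an
identical normaliser, so testing counts and testing MPKM are the same test;
differences are taken on counts to keep the tie structure exact. Families of
tests run together (categories × regions, and across cohorts/sources when
batched) are adjusted with an in-package Benjamini–Hochberg step-up,
cross-checked against statsmodels in the test suite. All tests are
two-sided; both flanks and the whole window are always computed, and callers
interested specifically in transcription-coupled asymmetry can subset to the
downstream region.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: i.i.d. reference
chromosomes at a configurable GC fraction (default 0.41, GRCh38-like);
non-overlapping uniform-length intervals (defaults 500–1999 bp, passing the
< 2000 bp bidirectional-proxy size filter) placed uniformly with a margin
wide enough for the background window; per-donor totals drawn log-normal
(median 500, σ = 0.5 — a mid-sized WGS cohort's spread); categories drawn
from a C>T-dominant weight vector (0.10/0.10/0.40/0.10/0.20/0.10). Positional
effects enter through a triangular-kernel intensity (midpoint dip, boundary
peaks); the compact support guarantees the background window is unaffected
by the injected effects. Strand asymmetry assigns the pyrimidine form with
probability `0.5 + β/2` downstream of an interval midpoint and `0.5 − β/2`
upstream; `strand_extent` widens the bias zone from the interval itself to
± a fixed span around the midpoint (used when the study condition is a
uniform 65:35 split across the whole downstream flank), and
`strand_categories` restricts the effect to chosen categories, emulating
cohort findings where a single category carries the bias. Sampled reference
bases are overwritten with the drawn ref allele so classification from
`(ref, alt)` stays consistent with the reference.

What the generator does **not** emulate: chromatin context, mutational
signatures' trinucleotide preferences, regional mutation-rate covariates
(replication timing, expression), interval length/GC heterogeneity of real
enhancer atlases, or inter-donor spectrum heterogeneity. Passing statistical
tests on these cohorts therefore demonstrates the *operating
characteristics* of the estimators under their stated model — calibration
under the null, power against clean injected effects — not performance on
real tumor genomes.

## Simulation study sizes

The repository's statistical checks run at deliberately small geometry so
the full suite executes in well under a minute per study: one 120 kb
chromosome, 12 intervals ≥ 5 kb apart, 20 kb edge margins, background window
5–20 kb. Null calibration uses 500 replicates (~7 k mutations each; one
C>T whole-flank test per replicate, matching the n = 500 binomial band
0.027–0.078 around α = 0.05). Power studies use 200 replicates each: strand
bias at β = 0.3 over the full downstream flank with a median ≥ 2000
downstream C>T mutations (right-region test, BH at FDR 0.05 over the 18
tests of a run), and a 50% midpoint dip of 200 bp half-width with a median
≥ 5000 flank C>T mutations (call at p < 1e-5). Both exceed their required
recovery rates (≥ 90% and ≥ 95%) with margin at these sizes.

## Numerical choices and degenerate inputs

* Midpoints use floor on the last-covered-base convention — deterministic
  for even lengths; single-base intervals collapse all three anchors.
* The size filter is strictly `length < max_len`.
* Pairwise overlap is asymmetric (covered bases of A / size of A), the most
  informative superset when no symmetry is specified; a Jaccard mode is
  provided. Empty sets yield missing (NaN) rows, not zeros, and both
  ordered- and unordered-pair off-diagonal means are available.
* Ties in extreme-bin selection break toward the lowest bin index
  (`argmax`/`argmin` convention).
* Zero cohort total makes MPKM undefined and raises; zero region-overlap
  counts report MPKM 0 even when the donor's `K` is 0; `C > 0` with `K = 0`
  is inconsistent input and raises.
* Composition fractions at offsets with no coverage are NaN, never 0.
* Result tables round-trip exactly (floats written at `repr` precision).

## Known limitations

* Only SBS calls are handled; indels and MNVs are filtered out, and silent
  vs non-silent annotation is the caller's concern.
* Overlap counting and binning are exact but not streaming; catalogs are
  held in memory (a pandas frame), adequate for per-cohort ICGC-scale TSVs
  but not for pan-cancer aggregates in one pass.
* The Poisson background assumes local homogeneity 5+ kb from focal points;
  strong regional covariates in real data would need a covariate-adjusted
  background, which is not implemented.
* Survival modelling on burden (e.g. Cox regression) is a designed hand-off:
  the per-donor burden table is the interface, the regression itself is left
  to standard packages.
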