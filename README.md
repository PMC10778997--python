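# ernadens

Somatic mutation density, transcriptional strand bias, and regional mutation
burden around enhancer-RNA (eRNA) loci.

Enhancer RNAs are short, bidirectionally transcribed non-coding transcripts
produced from active enhancers. Somatic mutations in cancer genomes are not
spread uniformly around such regulatory elements: published analyses of
ICGC cohorts report a density *dip* at the eRNA midpoint, density *peaks* at
the eRNA start and end, and cohort-specific strand asymmetries between
complementary substitution forms. `ernadens` implements that analysis as a
tested, reusable library for anyone who wants to profile single-base
substitution (SBS) catalogs against an interval annotation: cancer genomics
groups working with ICGC-style mutation exports, and anyone studying mutation
topography around regulatory elements.

## What it computes

* **Six-category SBS spectra.** The 12 substitutions collapse to C>A, C>G,
  C>T, T>A, T>C, T>G; each category pools a pyrimidine-reference form and its
  reverse-complement purine form (e.g. C>A pools C>A and G>T).
* **Density profiles.** Mutations are tallied per form in 40 bins of 100 bp
  across ±2000 bp of each focal point (interval start, midpoint, or end;
  configurable grid), once per focal occurrence, and normalised to **MPKM** —
  *mutations per kilo total mutations per megabase*:

  `MPKM = C / (M · f · K)`

  with `C` the mutation count, `M` the profiled span in Mb, `f` a
  base-composition adjusting factor (0.2 for C-rooted categories, 0.3 for
  T-rooted, reflecting a ≈40/60 GC/AT split), and `K` the total mutation
  count in thousands.
* **Peak/dip detection.** The most extreme bins are scored with exact Poisson
  tails against a background rate estimated from mutations 5–50 kb away
  (nominal threshold 1e-5).
* **Strand bias.** Per-bin densities of the two complementary forms are
  compared with a paired two-sided Wilcoxon signed-rank test (exact tie-aware
  null for ≤ 25 informative bins) in the left, right, and whole flank, with
  Benjamini–Hochberg control at FDR 0.05 across the pooled family.
* **Per-donor burden.** The same MPKM formula at donor level, per category
  plus a combined row, from interval-overlap counts against the merged
  region set.
* **Region utilities and synthetic cohorts.** BED interval handling, merged
  region sizes, pairwise overlap proportions, nucleotide-content profiles,
  and a seeded generator for cohorts with configurable spectra, positional
  intensity (midpoint dip, boundary peaks), and strand asymmetry — so every
  stage is testable without controlled-access data.

## Worked example

`examples/worked_example_burden.py` rebuilds the published single-donor
worked example — an ovarian-cancer donor against 14,522,866 bp of ovary
enhancer regions — and runs the burden pipeline end to end:

```
 category    C      K     f   MPKM
      C>A    7  1.342  0.20   1.80
      C>G   10  1.178  0.20   2.92
      C>T   12  1.770  0.20   2.33
      T>A    0  0.912  0.30   0.00
      T>C    2  1.160  0.30   0.40
      T>G    5  0.503  0.30   2.28
 combined   36  6.865  0.25   1.44

modal by raw count: C>T  |  modal by MPKM: C>G
```

`C` is the enhancer-overlapping count, `K` the donor's genome-wide category
total in thousands. C>T dominates raw counts both genome-wide and inside the
enhancers, but after normalising by region size, composition, and mutational
load, C>G carries the highest enhancer burden (2.92) — the normalisation is
the point of the statistic. The other examples
(`density_and_peakdip.py`, `strand_bias.py`, `overlap_and_content.py`) each
simulate a cohort with one injected effect and show the corresponding test
recovering it.

There is also a thin CLI mirroring the library
(`ernadens simulate|density|peakdip|strandbias|burden|content|overlap`);
every run writes its result tables plus a `manifest.json` with resolved
parameters and input digests.

## Layout

```
src/ernadens/        io_formats, spectrum, regions, density_profile,
                     stats_tests, donor_burden, synthetic_data, cli
examples/            one narrative script per capability
tests/               unit, property, and end-to-end statistical tests
docs/methods.md      model, assumptions, parameter choices, limitations
```
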