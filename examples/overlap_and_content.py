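"""Tissue-style interval comparison: overlap proportions and base content.

Generates two synthetic 'tissue' eRNA annotation sets on a shared synthetic
genome, computes their pairwise overlapping proportions (fraction of one
source's bases covered by the other — asymmetric, as annotation sizes
differ), and profiles nucleotide content around eRNA midpoints.  Real eRNA
annotations are strongly tissue-specific (~11% average overlap); unrelated
random placements here should overlap far less.
"""

import numpy as np

from ernadens.io_formats import IntervalSet
from ernadens.regions import focal_points, nucleotide_profile, pairwise_overlap, region_size
from ernadens.synthetic_data import SynthConfig, generate_ernas, generate_reference

cfg_a = SynthConfig(seed=3, chrom_length=200_000, n_ernas=40, edge_margin=5000)
cfg_b = cfg_a.replace(seed=4, n_ernas=25)
tissue_a = IntervalSet(list(generate_ernas(cfg_a)), source_label="tissueA")
tissue_b = IntervalSet(list(generate_ernas(cfg_b)), source_label="tissueB")

mat = pairwise_overlap([tissue_a, tissue_b])
print(f"region sizes: {region_size(tissue_a)} bp (A), {region_size(tissue_b)} bp (B)")
print(f"overlap A covered by B: {mat.proportions[0, 1]:.3f}")
print(f"overlap B covered by A: {mat.proportions[1, 0]:.3f}")
print(f"mean off-diagonal: {mat.mean_offdiagonal():.3f} (ordered), "
      f"{mat.mean_offdiagonal(unordered=True):.3f} (unordered)\n")

reference = generate_reference(cfg_a.replace(gc_fraction=0.41))
points = focal_points(tissue_a, "midpoint")
profile = nucleotide_profile(points, reference, flank=2000)
centre = slice(1900, 2101)  # +/-100 bp of the midpoint
print(f"GC fraction near the midpoint: {np.nanmean(profile.gc[centre]):.3f}")
print(f"GC fraction overall window:    {np.nanmean(profile.gc):.3f}")
print("(an i.i.d. reference is flat at its configured GC; real eRNA sources"
      "\nshow tissue-specific GC enrichment toward the midpoint)")
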