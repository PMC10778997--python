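"""Mutation density profiling and Poisson peak/dip detection.

Simulates a cohort whose positional intensity carries a 50% depletion at
every eRNA midpoint and enrichments at the interval boundaries, bins the
mutations into the standard 40 x 100 bp grid around each focal point, and
tests the most extreme bins against a Poisson background estimated from
mutations 5-20 kb away.  The midpoint profile should call a dip near bin
19/20 (the centre) and the start/end profiles should call peaks.
"""

from ernadens.density_profile import BinGrid, bin_counts
from ernadens.regions import focal_points
from ernadens.stats_tests import detect_peak_dip, poisson_background
from ernadens.synthetic_data import SynthConfig, generate_cohort

config = SynthConfig(
    seed=1, chrom_length=120_000, n_ernas=12, edge_margin=20_000, min_spacing=5000,
    n_donors=10, donor_total_median=6000.0,
    dip_depth=0.5, dip_halfwidth=300, peak_height=0.8, peak_halfwidth=300,
)
cohort = generate_cohort(config, with_reference=False)
grid = BinGrid()  # 2000 bp flanks, 40 bins of 100 bp
print(f"cohort: {len(cohort.mutations)} mutations, {len(cohort.ernas)} eRNA-like intervals\n")

for anchor in ("start", "midpoint", "end"):
    points = focal_points(cohort.ernas, anchor)
    profile = bin_counts(cohort.mutations, points, grid)
    bg = poisson_background(cohort.mutations, points, "C>T", grid, bg_window=(5000, 20000))
    res = detect_peak_dip(profile, "C>T", bg.lambda_bg)
    print(f"{anchor:>9}: {res.direction:>4} at bin {res.extreme_bin} "
          f"(observed {res.observed}, background {res.lambda_bg:.1f}/bin, "
          f"p = {res.p_nominal:.2e})")

print("\nbins 18-21 are the central 400 bp; a dip there at the midpoint anchor")
print("with peaks at start/end mirrors the enhancer mutation-density shape.")
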