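"""Transcriptional strand-bias testing between complementary mutation forms.

Simulates a cohort in which C>A mutations downstream of each eRNA midpoint
prefer the pyrimidine-reference form 65:35 (strand_beta = 0.3), profiles
densities around the midpoints, and runs paired Wilcoxon signed-rank tests
(pyrimidine vs purine form, per 100-bp bin) for every category in the left,
right, and whole flanks, pooled under a Benjamini-Hochberg adjustment.
Only the biased category/region combinations should reach FDR 0.05.
"""

from ernadens.density_profile import BinGrid, bin_counts, normalize_mpkm
from ernadens.regions import focal_points
from ernadens.stats_tests import run_strand_bias
from ernadens.synthetic_data import SynthConfig, generate_cohort

config = SynthConfig(
    seed=2, chrom_length=120_000, n_ernas=12, edge_margin=20_000, min_spacing=5000,
    n_donors=10, donor_total_median=2600.0,
    strand_beta=0.3, strand_extent=2000, strand_categories=("C>A",),
    category_weights=(0.40, 0.10, 0.20, 0.10, 0.10, 0.10),
)
cohort = generate_cohort(config, with_reference=False)
points = focal_points(cohort.ernas, "midpoint")
profile = bin_counts(cohort.mutations, points, BinGrid())
profile = normalize_mpkm(profile, cohort_total=len(cohort.mutations))

results = run_strand_bias(profile)  # 6 categories x 3 regions, BH-pooled
print(f"{'category':>9} {'region':>6} {'W+':>6} {'p':>10} {'p_adj':>10}")
for r in results:
    flag = " *" if r.p_adjusted < 0.05 else ""
    print(f"{r.category:>9} {r.region:>6} {r.statistic:>6.0f} {r.p:>10.2e} {r.p_adjusted:>10.2e}{flag}")
print("\n* significant at FDR 0.05; the injected bias sits in C>A (downstream"
      "\nexcess of the pyrimidine form), so C>A right/whole rows should flag.")
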