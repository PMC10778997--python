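import math

import numpy as np
import pandas as pd
import pytest

from ernadens.density_profile import BinGrid, bin_counts
from ernadens.io_formats import read_mutations, write_mutations
from ernadens.regions import filter_by_size, focal_points
from ernadens.spectrum import CATEGORIES, classify_arrays
from ernadens.synthetic_data import (
    SynthConfig,
    generate_cohort,
    generate_ernas,
    generate_mutations,
    generate_null_batch,
    generate_reference,
    load_config,
    replicate_seeds,
    save_config,
)

SMALL = SynthConfig(
    seed=77, chrom_length=80_000, n_ernas=8, edge_margin=10_000,
    n_donors=6, donor_total_median=400.0,
)


class TestReference:
    def test_gc_fraction_recovered_within_binomial_error(self):
        cfg = SynthConfig(seed=1, chrom_length=200_000, gc_fraction=0.4)
        ref = generate_reference(cfg)
        seq = ref.fetch("1", 0, cfg.chrom_length)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        se = math.sqrt(0.4 * 0.6 / cfg.chrom_length)
        assert abs(gc - 0.4) < 3 * se

    def test_identical_seeds_identical_sequences(self):
        cfg = SynthConfig(seed=9, chrom_length=5_000)
        a = generate_reference(cfg).fetch("1", 0, 5_000)
        b = generate_reference(cfg).fetch("1", 0, 5_000)
        assert a == b

    def test_gc_one_yields_only_strong_bases(self):
        cfg = SynthConfig(seed=2, chrom_length=2_000, gc_fraction=1.0)
        seq = generate_reference(cfg).fetch("1", 0, 2_000)
        assert set(seq) <= {"G", "C"}

    def test_fasta_round_trip_via_pyfaidx(self, tmp_path):
        import pyfaidx

        cfg = SynthConfig(seed=3, chrom_length=1_000, n_chroms=2)
        ref = generate_reference(cfg)
        ref.write_fasta(tmp_path / "r.fa")
        fa = pyfaidx.Fasta(str(tmp_path / "r.fa"))
        assert str(fa["1"][100:200]) == ref.fetch("1", 100, 200)
        assert len(fa["2"]) == 1_000


class TestErnas:
    def test_intervals_disjoint_sorted_and_margin_respecting(self):
        ivs = generate_ernas(SMALL)
        assert len(ivs) == SMALL.n_ernas
        prev_end = 0
        for iv in ivs:
            assert iv.start >= prev_end
            assert iv.start >= SMALL.edge_margin
            assert iv.end <= SMALL.chrom_length - SMALL.edge_margin
            assert SMALL.erna_length_min <= iv.length <= SMALL.erna_length_max
            prev_end = iv.end

    def test_lengths_pass_the_size_filter(self):
        ivs = generate_ernas(SMALL)
        assert len(filter_by_size(ivs, 2000)) == len(ivs)

    def test_infeasible_density_raises(self):
        cfg = SynthConfig(chrom_length=30_000, n_ernas=50, edge_margin=10_000)
        with pytest.raises(ValueError):
            generate_ernas(cfg)

    def test_seed_reproducibility(self):
        assert generate_ernas(SMALL) == generate_ernas(SMALL)


class TestMutations:
    def test_category_mixture_recovered_within_three_se(self):
        cfg = SynthConfig(
            seed=4, chrom_length=200_000, n_ernas=10, edge_margin=20_000,
            n_donors=20, donor_total_median=800.0,
        )
        co = generate_cohort(cfg, with_reference=False)
        n = len(co.mutations)
        assert n >= 10_000
        idx = classify_arrays(co.mutations["ref"].to_numpy(), co.mutations["alt"].to_numpy())
        for ci, w in enumerate(cfg.category_weights):
            frac = (idx // 2 == ci).mean()
            se = math.sqrt(w * (1 - w) / n)
            assert abs(frac - w) < 3 * se, (CATEGORIES[ci], frac)

    def test_null_config_has_flat_bins_within_poisson_noise(self):
        cfg = SMALL.replace(seed=6, donor_total_median=3000.0)
        co = generate_cohort(cfg, with_reference=False)
        pts = focal_points(co.ernas, "midpoint")
        prof = bin_counts(co.mutations, pts, BinGrid())
        per_bin = prof.counts.sum(axis=0)
        mean = per_bin.mean()
        assert per_bin.std() < 3 * math.sqrt(mean)

    def test_strand_beta_sets_downstream_form_ratio(self):
        cfg = SynthConfig(
            seed=8, chrom_length=200_000, n_ernas=20, edge_margin=20_000,
            n_donors=30, donor_total_median=2000.0, strand_beta=0.3,
        )
        co = generate_cohort(cfg, with_reference=False)
        df = co.mutations
        pyr = df["ref"].isin(["C", "T"]).to_numpy()
        pos0 = df["pos"].to_numpy() - 1
        down = np.zeros(len(df), dtype=bool)
        up = np.zeros(len(df), dtype=bool)
        for iv in co.ernas:
            mid = (iv.start + iv.end - 1) // 2
            down |= (pos0 >= mid) & (pos0 < iv.end)
            up |= (pos0 >= iv.start) & (pos0 < mid)
        for sel, target in ((down, 0.65), (up, 0.35)):
            n = sel.sum()
            assert n > 500
            se = math.sqrt(target * (1 - target) / n)
            assert abs(pyr[sel].mean() - target) < 3 * se

    def test_strand_bias_can_be_restricted_to_categories(self):
        cfg = SynthConfig(
            seed=12, chrom_length=200_000, n_ernas=20, edge_margin=20_000,
            min_spacing=5_000, n_donors=30, donor_total_median=2000.0,
            strand_beta=0.5, strand_extent=2000, strand_categories=("C>A",),
        )
        co = generate_cohort(cfg, with_reference=False)
        df = co.mutations
        idx = classify_arrays(df["ref"].to_numpy(), df["alt"].to_numpy())
        pos0 = df["pos"].to_numpy() - 1
        down = np.zeros(len(df), dtype=bool)
        for iv in co.ernas:
            mid = (iv.start + iv.end - 1) // 2
            down |= (pos0 >= mid) & (pos0 < mid + 2000)
        pyr = df["ref"].isin(["C", "T"]).to_numpy()
        biased = down & (idx // 2 == 0)
        unbiased = down & (idx // 2 != 0)
        assert pyr[biased].mean() > 0.68
        assert abs(pyr[unbiased].mean() - 0.5) < 3 * math.sqrt(0.25 / unbiased.sum())

    def test_dip_halves_intensity_at_the_midpoint(self):
        from ernadens.synthetic_data import _intensity

        cfg = SMALL.replace(dip_depth=0.5)
        ernas = generate_ernas(cfg)
        lam = _intensity(cfg, ernas, "1")
        iv = ernas[0]
        mid = (iv.start + iv.end - 1) // 2
        assert lam[mid] == pytest.approx(0.5 * cfg.baseline_rate)
        assert lam[mid - cfg.dip_halfwidth - 10] == pytest.approx(cfg.baseline_rate)

    def test_reference_overwritten_with_sampled_ref_base(self):
        cfg = SMALL.replace(seed=10)
        co = generate_cohort(cfg, with_reference=True)
        df = co.mutations.drop_duplicates(subset=["chrom", "pos"], keep="last")
        sample = df.head(200)
        for row in sample.itertuples(index=False):
            assert co.reference.fetch(row.chrom, row.pos - 1, row.pos) == row.ref

    def test_catalog_survives_write_read_with_zero_drops(self, tmp_path):
        co = generate_cohort(SMALL, with_reference=False)
        p = tmp_path / "muts.tsv"
        write_mutations(co.mutations, p)
        back = read_mutations(p)
        assert len(back) == len(co.mutations)
        pd.testing.assert_frame_equal(
            back.sort_values(["donor_id", "chrom", "pos", "ref", "alt"]).reset_index(drop=True),
            co.mutations.sort_values(["donor_id", "chrom", "pos", "ref", "alt"]).reset_index(drop=True),
        )

    def test_zero_mutation_config_runs_cleanly(self):
        cfg = SMALL.replace(donor_total_median=0.0)
        co = generate_cohort(cfg, with_reference=False)
        assert len(co.mutations) == 0
        pts = focal_points(co.ernas, "midpoint")
        prof = bin_counts(co.mutations, pts, BinGrid())
        assert prof.counts.sum() == 0


class TestBatchesAndConfig:
    def test_replicate_seeds_distinct_and_reproducible(self):
        a = replicate_seeds(123, 50)
        b = replicate_seeds(123, 50)
        assert np.array_equal(a, b)
        assert len(set(a.tolist())) == 50
        assert a.max() < 2**31

    def test_null_batch_zeroes_effects(self):
        cfg = SMALL.replace(dip_depth=0.4, strand_beta=0.2, peak_height=1.0)
        cohorts = list(generate_null_batch(cfg, 3))
        assert len(cohorts) == 3
        for co in cohorts:
            assert co.config.dip_depth == 0.0
            assert co.config.strand_beta == 0.0
            assert co.config.peak_height == 0.0
        assert len({co.config.seed for co in cohorts}) == 3

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = SMALL.replace(strand_extent=1500, category_weights=(0.2, 0.2, 0.2, 0.2, 0.1, 0.1))
        save_config(cfg, tmp_path / "c.yaml")
        assert load_config(tmp_path / "c.yaml") == cfg

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(category_weights=(0.5, 0.5, 0, 0, 0, 0.1))
        with pytest.raises(ValueError):
            SynthConfig(dip_depth=1.5)
        with pytest.raises(ValueError):
            SynthConfig(strand_beta=2.0)
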