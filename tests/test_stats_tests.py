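import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from ernadens.density_profile import BinGrid, DensityProfile, bin_counts, normalize_mpkm
from ernadens.io_formats import MutationRecord
from ernadens.regions import FocalPoint
from ernadens.stats_tests import (
    bh_adjust,
    detect_peak_dip,
    poisson_background,
    run_strand_bias,
    strand_bias_test,
    wilcoxon_signed_rank,
)


def profile_with_category_counts(values, category_index=0, grid=BinGrid()):
    counts = np.zeros((12, grid.n_bins), dtype=np.int64)
    counts[2 * category_index] = np.asarray(values, dtype=np.int64)
    return DensityProfile(grid=grid, n_focal=10, counts=counts, anchor="midpoint")


class TestPoissonBackground:
    def test_uniform_rate_recovers_expected_lambda(self, rng):
        # homogeneous mutations at rate r per bp: lambda ~= r * bin_width * n_focal
        r = 0.02
        length = 200_000
        n = rng.poisson(r * length)
        pos = np.sort(rng.integers(1, length + 1, size=n))
        muts = [MutationRecord("d", "1", int(p), "C", "A") for p in pos]
        pts = [FocalPoint("1", x, "midpoint") for x in (60_000, 100_000, 140_000)]
        grid = BinGrid()
        bg = poisson_background(muts, pts, "C>A", grid, bg_window=(5000, 20000))
        expect = r * grid.bin_width * len(pts)
        se = math.sqrt(expect / (2 * 15000 / grid.bin_width))  # rate est from 30kb/bin span
        assert abs(bg.lambda_bg - expect) < 3 * se * math.sqrt(len(pts))
        assert not bg.pseudo_count_used

    def test_widening_window_leaves_lambda_stable(self, rng):
        r = 0.02
        length = 400_000
        pos = rng.integers(1, length + 1, size=rng.poisson(r * length))
        muts = [MutationRecord("d", "1", int(p), "C", "A") for p in np.sort(pos)]
        pts = [FocalPoint("1", 200_000, "midpoint")]
        narrow = poisson_background(muts, pts, "C>A", BinGrid(), bg_window=(5000, 20000))
        wide = poisson_background(muts, pts, "C>A", BinGrid(), bg_window=(5000, 50000))
        assert narrow.lambda_bg == pytest.approx(wide.lambda_bg, rel=0.15)

    def test_empty_background_uses_flagged_pseudo_count(self):
        muts = [MutationRecord("d", "1", 10_000, "C", "A")]
        pts = [FocalPoint("1", 10_000, "midpoint")]
        bg = poisson_background(muts, pts, "C>A", BinGrid(), bg_window=(5000, 6000))
        assert bg.pseudo_count_used and bg.lambda_bg == pytest.approx(0.5 * 100 / 2000)

    def test_window_must_clear_the_flank(self):
        with pytest.raises(ValueError):
            poisson_background([], [FocalPoint("1", 0, "start")], "C>A", BinGrid(), (1000, 5000))


class TestPeakDip:
    def test_flat_profile_calls_nothing(self):
        lam = 10.0
        profile = profile_with_category_counts([round(lam)] * 40)
        res = detect_peak_dip(profile, "C>A", lam)
        assert res.direction == "none"

    def test_extreme_peak_detected_with_exact_upper_tail(self):
        lam, obs = 10.0, 30
        values = [round(lam)] * 40
        values[13] = obs
        res = detect_peak_dip(profile_with_category_counts(values), "C>A", lam)
        # independent oracle: direct summation of the Poisson upper tail
        tail = sum(
            math.exp(k * math.log(lam) - lam - math.lgamma(k + 1)) for k in range(obs, 200)
        )
        assert res.direction == "peak" and res.extreme_bin == 13
        assert res.p_nominal == pytest.approx(tail, rel=1e-10)
        assert res.p_nominal < 1e-5

    def test_zero_count_dip_has_closed_form_tail(self):
        lam = 20.0
        values = [round(lam)] * 40
        values[7] = 0
        res = detect_peak_dip(profile_with_category_counts(values), "C>A", lam)
        assert res.direction == "dip" and res.extreme_bin == 7
        assert res.p_nominal == pytest.approx(math.exp(-20.0), rel=1e-10)

    def test_both_candidates_always_reported(self):
        values = [10] * 40
        values[0], values[39] = 2, 25
        res = detect_peak_dip(profile_with_category_counts(values), "C>A", 10.0)
        assert (res.peak_bin, res.dip_bin) == (39, 0)
        assert 0 < res.p_peak < 1 and 0 < res.p_dip < 1

    def test_requires_positive_background(self):
        with pytest.raises(ValueError):
            detect_peak_dip(profile_with_category_counts([1] * 40), "C>A", 0.0)


def enumerate_signed_rank_p(diffs):
    """Brute-force two-sided p over all 2^n sign assignments (tie-aware)."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(d))
    ]
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_identical_vectors_give_p_one(self):
        res = wilcoxon_signed_rank(np.zeros(20))
        assert res.p == 1.0 and res.n_informative == 0

    def test_twenty_positive_differences_exact_p(self):
        res = wilcoxon_signed_rank(np.arange(1.0, 21.0))
        assert res.method == "exact"
        assert res.p == pytest.approx(2 * 2.0**-20, rel=1e-12)

    def test_three_bin_case_matches_enumeration(self):
        diffs = [3.0, 2.0, -1.0]
        res = wilcoxon_signed_rank(diffs)
        assert res.p == pytest.approx(enumerate_signed_rank_p(diffs), abs=1e-12)

    def test_random_small_cases_match_enumeration(self, rng):
        for _ in range(40):
            n = int(rng.integers(1, 11))
            d = rng.integers(-4, 5, size=n).astype(float)  # ties and zeros likely
            res = wilcoxon_signed_rank(d)
            assert res.p == pytest.approx(enumerate_signed_rank_p(d), abs=1e-12)

    def test_exact_path_agrees_with_scipy_when_tie_free(self, rng):
        d = rng.normal(size=20)
        ours = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, alternative="two-sided", method="exact")
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_path_tracks_scipy_approx(self, rng):
        d = rng.normal(0.3, 1.0, size=60)
        ours = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, alternative="two-sided", method="approx", correction=True)
        assert ours.method == "normal"
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-6)


class TestStrandBias:
    def grid_profile(self, pyr, pur):
        counts = np.zeros((12, 40), dtype=np.int64)
        counts[4] = pyr  # C>T pyrimidine form
        counts[5] = pur
        profile = DensityProfile(grid=BinGrid(), n_focal=10, counts=counts, anchor="midpoint")
        return normalize_mpkm(profile, cohort_total=int(counts.sum()) or 1)

    def test_identical_forms_give_p_one(self):
        p = self.grid_profile(np.full(40, 7), np.full(40, 7))
        assert strand_bias_test(p, "C>T", "whole").p == 1.0

    def test_region_selection_left_right_whole(self, rng):
        pyr = np.concatenate([np.full(20, 30), np.full(20, 10)])
        pur = np.full(40, 10)
        p = self.grid_profile(pyr, pur)
        left = strand_bias_test(p, "C>T", "left")
        right = strand_bias_test(p, "C>T", "right")
        assert left.p < 1e-4 and right.p == 1.0
        assert left.n_informative == 20 and right.n_informative == 0

    def test_mpkm_and_counts_give_identical_p(self):
        rng = np.random.default_rng(3)
        pyr = rng.poisson(20, 40)
        pur = rng.poisson(20, 40)
        with_mpkm = self.grid_profile(pyr, pur)
        counts_only = DensityProfile(
            grid=BinGrid(), n_focal=10, counts=with_mpkm.counts, anchor="midpoint"
        )
        assert (
            strand_bias_test(with_mpkm, "C>T", "whole").p
            == strand_bias_test(counts_only, "C>T", "whole").p
        )

    def test_run_strand_bias_pools_adjustment(self):
        p = self.grid_profile(np.full(40, 30), np.full(40, 10))
        results = run_strand_bias(p)
        assert len(results) == 18
        assert all(r.p_adjusted >= r.p - 1e-15 for r in results)
        sig = [r for r in results if r.category == "C>T" and r.region == "whole"][0]
        assert sig.p_adjusted < 0.05


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_textbook_step_up_case(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_monotone_in_raw_p(self, rng):
        p = rng.random(50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(int(rng.integers(1, 40)))
            ours = bh_adjust(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, theirs, atol=1e-12)

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
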