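"""Peak/dip detection against a Poisson background and strand-bias testing.

Peaks and dips: a background per-bin rate is estimated from mutations far
from the focal points, and the most extreme bins of the observed profile are
scored with exact Poisson tail probabilities (upper tail for the maximum bin,
lower tail for the minimum bin), called at a stringent nominal threshold
(default 1e-5).

Strand bias: within a category, the per-bin densities of the pyrimidine-
reference form are paired with those of the purine-reference form and
compared with a two-sided Wilcoxon signed-rank test (exact tie-aware null for
n <= 25 informative bins, normal approximation with tie correction and
continuity correction beyond).  Families of tests are controlled with the
Benjamini-Hochberg step-up at FDR 0.05.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .density_profile import BinGrid, DensityProfile
from .io_formats import as_frame
from .regions import FocalPoint
from .spectrum import CATEGORIES, classify_arrays

REGIONS = ("left", "right", "whole")

DEFAULT_BG_WINDOW = (5000, 50000)
DEFAULT_ALPHA_NOMINAL = 1e-5


@dataclass(frozen=True)
class BackgroundEstimate:
    """Expected mutations per bin (summed over focal occurrences) far from the points."""

    lambda_bg: float
    n_background: int
    span_bp: int
    pseudo_count_used: bool


def poisson_background(
    mutations,
    points: Sequence[FocalPoint],
    category: str,
    grid: BinGrid = BinGrid(),
    bg_window: Tuple[int, int] = DEFAULT_BG_WINDOW,
) -> BackgroundEstimate:
    """Estimate the per-bin background rate for one category.

    Mutations of the category with ``|offset|`` in ``[min_dist, max_dist)`` of
    any focal point are counted per occurrence and rescaled to the bin span:
    ``lambda_bg = n_bg * bin_width / (2 * (max_dist - min_dist))``.  An empty
    background window falls back to a 0.5 pseudo-count and is flagged.
    """
    min_dist, max_dist = bg_window
    if min_dist < grid.flank:
        raise ValueError("background window must start at or beyond the profiling flank")
    if max_dist <= min_dist:
        raise ValueError("background window must have positive span")
    df = as_frame(mutations)
    ci = CATEGORIES.index(category)
    n_bg = 0
    if len(df):
        forms = classify_arrays(df["ref"].to_numpy(), df["alt"].to_numpy())
        keep = forms // 2 == ci
        pos0 = df["pos"].to_numpy(dtype=np.int64)[keep] - 1
        chroms = df["chrom"].to_numpy()[keep]
        by_chrom = {}
        for c in np.unique(chroms):
            by_chrom[str(c)] = np.sort(pos0[chroms == c])
        for fp in points:
            p = by_chrom.get(fp.chrom)
            if p is None:
                continue
            for lo, hi in (
                (fp.position - max_dist + 1, fp.position - min_dist),
                (fp.position + min_dist, fp.position + max_dist - 1),
            ):
                # offsets with |d| in [min_dist, max_dist): left side covers
                # d in (-max_dist, -min_dist], right side d in [min_dist, max_dist)
                n_bg += int(
                    np.searchsorted(p, hi, side="right") - np.searchsorted(p, lo, side="left")
                )
    span = 2 * (max_dist - min_dist)
    pseudo = n_bg == 0
    eff = 0.5 if pseudo else float(n_bg)
    return BackgroundEstimate(
        lambda_bg=eff * grid.bin_width / span,
        n_background=n_bg,
        span_bp=span,
        pseudo_count_used=pseudo,
    )


@dataclass(frozen=True)
class PeakDipResult:
    """Poisson test of the most extreme bins of one category's profile."""

    anchor: Optional[str]
    category: str
    direction: str               # "peak", "dip", or "none"
    extreme_bin: int
    observed: int
    lambda_bg: float
    p_nominal: float
    peak_bin: int
    peak_observed: int
    p_peak: float
    dip_bin: int
    dip_observed: int
    p_dip: float
    alpha_nominal: float


def detect_peak_dip(
    profile: DensityProfile,
    category: str,
    lambda_bg: float,
    alpha_nominal: float = DEFAULT_ALPHA_NOMINAL,
) -> PeakDipResult:
    """Score the maximum bin (upper Poisson tail) and minimum bin (lower tail).

    ``direction`` is set only when the corresponding tail probability falls
    below ``alpha_nominal``; when both do, the smaller tail wins.  Both
    candidate tests are always reported.
    """
    if lambda_bg <= 0:
        raise ValueError("lambda_bg must be positive")
    counts = profile.category_counts()[CATEGORIES.index(category)]
    peak_bin = int(np.argmax(counts))
    dip_bin = int(np.argmin(counts))
    peak_obs = int(counts[peak_bin])
    dip_obs = int(counts[dip_bin])
    p_peak = float(sps.poisson.sf(peak_obs - 1, lambda_bg))  # P(X >= obs)
    p_dip = float(sps.poisson.cdf(dip_obs, lambda_bg))       # P(X <= obs)
    direction = "none"
    extreme_bin, observed, p_nominal = peak_bin, peak_obs, p_peak
    peak_sig, dip_sig = p_peak < alpha_nominal, p_dip < alpha_nominal
    if peak_sig and (not dip_sig or p_peak <= p_dip):
        direction = "peak"
    elif dip_sig:
        direction = "dip"
        extreme_bin, observed, p_nominal = dip_bin, dip_obs, p_dip
    elif p_dip < p_peak:
        extreme_bin, observed, p_nominal = dip_bin, dip_obs, p_dip
    return PeakDipResult(
        anchor=profile.anchor,
        category=category,
        direction=direction,
        extreme_bin=extreme_bin,
        observed=observed,
        lambda_bg=float(lambda_bg),
        p_nominal=p_nominal,
        peak_bin=peak_bin,
        peak_observed=peak_obs,
        p_peak=p_peak,
        dip_bin=dip_bin,
        dip_observed=dip_obs,
        p_dip=p_dip,
        alpha_nominal=alpha_nominal,
    )


def detect_peak_dip_per_bin(
    profile: DensityProfile, category: str, lambda_bg: float
) -> pd.DataFrame:
    """Optional per-bin mode: both Poisson tails for every bin (BH-ready)."""
    counts = profile.category_counts()[CATEGORIES.index(category)]
    upper = sps.poisson.sf(counts - 1, lambda_bg)
    lower = sps.poisson.cdf(counts, lambda_bg)
    return pd.DataFrame(
        {
            "bin": np.arange(profile.grid.n_bins),
            "bin_start_offset": profile.grid.bin_start_offsets(),
            "observed": counts,
            "p_peak": upper,
            "p_dip": lower,
        }
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float      # W+ (sum of ranks of positive differences)
    n_informative: int
    p: float
    method: str           # "exact", "normal", or "degenerate"


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p under the signed-rank null, tie-aware.

    Ranks may be half-integers (average ranks under ties); doubling makes them
    integers and the null distribution of 2*W+ is built by dynamic programming
    over the 2^n equiprobable sign assignments.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(2 * w_plus))
    p_le = float(dist[: w2 + 1].sum())
    p_ge = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(differences: Iterable[float]) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test on a vector of differences.

    Zero differences are dropped (Wilcoxon convention).  The exact tie-aware
    null is used for n <= 25 informative pairs; beyond that a normal
    approximation with tie-corrected variance and a 0.5 continuity correction.
    """
    d = np.asarray(list(differences), dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(statistic=float("nan"), n_informative=0, p=1.0, method="degenerate")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        p = _exact_signed_rank_p(ranks, w_plus)
        return WilcoxonResult(statistic=w_plus, n_informative=n, p=p, method="exact")
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts) / 2.0).sum())
    var = (n * (n + 1) * (2 * n + 1) - tie_term) / 24.0
    if var <= 0:
        return WilcoxonResult(statistic=w_plus, n_informative=n, p=1.0, method="degenerate")
    z = (abs(w_plus - mu) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * float(sps.norm.sf(max(z, 0.0))))
    return WilcoxonResult(statistic=w_plus, n_informative=n, p=p, method="normal")


@dataclass(frozen=True)
class StrandBiasResult:
    """Wilcoxon comparison of the two complementary forms of one category."""

    anchor: Optional[str]
    category: str
    region: str
    statistic: float
    n_informative: int
    p: float
    p_adjusted: float = float("nan")


def _region_slice(region: str, n_bins: int) -> slice:
    if region == "left":
        return slice(0, n_bins // 2)
    if region == "right":
        return slice(n_bins // 2, n_bins)
    if region == "whole":
        return slice(0, n_bins)
    raise ValueError(f"region must be one of {REGIONS}, got {region!r}")


def strand_bias_test(
    profile: DensityProfile, category: str, region: str = "whole"
) -> StrandBiasResult:
    """Paired two-sided Wilcoxon on per-bin densities, pyrimidine vs purine form.

    ``left`` is the upstream half of the bins, ``right`` the downstream half,
    ``whole`` all bins.  The two forms of a category share an identical
    normaliser, so the signed-rank test on per-bin MPKM is the signed-rank
    test on per-bin counts; the differences are taken on counts to keep the
    tie structure exact.
    """
    pyr, pur = profile.form_vectors(category, use="counts")
    sel = _region_slice(region, profile.grid.n_bins)
    res = wilcoxon_signed_rank(np.asarray(pyr[sel], dtype=float) - np.asarray(pur[sel], dtype=float))
    return StrandBiasResult(
        anchor=profile.anchor,
        category=category,
        region=region,
        statistic=res.statistic,
        n_informative=res.n_informative,
        p=res.p,
    )


def run_strand_bias(
    profile: DensityProfile,
    categories: Sequence[str] = CATEGORIES,
    regions: Sequence[str] = REGIONS,
    adjust: bool = True,
) -> List[StrandBiasResult]:
    """All (category x region) strand-bias tests for a profile, BH-adjusted together."""
    results = [strand_bias_test(profile, c, r) for c in categories for r in regions]
    return adjust_strand_bias(results) if adjust else results


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def adjust_strand_bias(results: Sequence[StrandBiasResult]) -> List[StrandBiasResult]:
    """Fill ``p_adjusted`` across a pooled family of strand-bias results."""
    adj = bh_adjust([r.p for r in results])
    return [dataclasses.replace(r, p_adjusted=float(a)) for r, a in zip(results, adj)]
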