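"""Per-donor regional mutation burden (MPKM) for a target region set.

For each donor and SBS category, the mutations falling inside the (merged)
target regions are counted (C) and normalised three ways: by the merged
region size in megabases (M), by a base-composition adjusting factor (f; 0.2
for C-rooted categories, 0.3 for T-rooted), and by the donor's genome-wide
mutation count of the category in thousands (K):

    MPKM = C / (M * f * K)

A per-donor "combined" row pools all six categories with f = 0.25 (the
composition-weighted mean of the per-category factors under the implied
40/60 GC/AT split).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .io_formats import IntervalSet, as_frame
from .regions import merge_intervals, region_size
from .spectrum import CATEGORIES, adjusting_factor, classify_arrays

F_COMBINED = 0.25


@dataclass(frozen=True)
class DonorBurden:
    """Eq-style burden inputs and the resulting MPKM for one donor x category."""

    donor_id: str
    category: str        # one of the six categories or "combined"
    C: int               # region-overlapping mutations (both forms)
    M_mb: float          # merged region size, megabases
    f: float             # composition adjusting factor
    K_kilo: float        # donor's genome-wide mutations of the category, thousands
    mpkm: float


def count_overlaps(mutations, intervals: IntervalSet) -> Dict[Tuple[str, str], int]:
    """Count region-overlapping mutations per (donor, category).

    A mutation at 1-based ``pos`` overlaps ``[start, end)`` iff
    ``start <= pos - 1 < end``.  Membership, not multiplicity: duplicated or
    mutually overlapping intervals never double-count a mutation (counting is
    done against the merged region, consistent with how M is measured).
    """
    df = as_frame(mutations)
    out: Dict[Tuple[str, str], int] = {}
    if not len(df):
        return out
    merged = merge_intervals(intervals).by_chrom()
    pos0 = df["pos"].to_numpy(dtype=np.int64) - 1
    chroms = df["chrom"].to_numpy()
    inside = np.zeros(len(df), dtype=bool)
    for c, (starts, ends) in merged.items():
        sel = chroms == c
        if not sel.any():
            continue
        p = pos0[sel]
        idx = np.searchsorted(starts, p, side="right") - 1
        ok = (idx >= 0) & (p < ends[np.clip(idx, 0, len(ends) - 1)])
        inside[sel] = ok
    if not inside.any():
        return out
    sub = df.loc[inside]
    cats = np.asarray(CATEGORIES)[
        classify_arrays(sub["ref"].to_numpy(), sub["alt"].to_numpy()) // 2
    ]
    grouped = (
        pd.DataFrame({"donor_id": sub["donor_id"].to_numpy(), "category": cats})
        .groupby(["donor_id", "category"], sort=True)
        .size()
    )
    for (donor, cat), n in grouped.items():
        out[(str(donor), str(cat))] = int(n)
    return out


def donor_mpkm(
    C: int, M_bases: int, category: str, K_total: int, f: Optional[float] = None
) -> float:
    """Regional MPKM from raw inputs: C / ((M/1e6) * f * (K/1000)).

    ``K_total`` is the donor's genome-wide mutation count for the category
    (``C <= K_total`` necessarily).  ``C = 0`` yields 0; ``K_total = 0`` with
    ``C > 0`` is inconsistent and raises.
    """
    if M_bases <= 0:
        raise ValueError("M_bases must be positive")
    if C < 0 or K_total < C:
        raise ValueError(f"require 0 <= C <= K_total, got C={C}, K_total={K_total}")
    if f is None:
        f = adjusting_factor(category)
    if C == 0:
        return 0.0
    return C / ((M_bases / 1e6) * f * (K_total / 1000.0))


def cohort_burden(
    mutations, intervals: IntervalSet, include_combined: bool = True
) -> List[DonorBurden]:
    """Per-donor, per-category MPKM over a cohort, plus combined rows.

    One row per donor per category (C = 0 rows included), ordered by donor
    then category; the combined row pools the six categories' C and K with
    f = 0.25.  M is the merged region size, computed once.
    """
    df = as_frame(mutations)
    M_bases = region_size(intervals)
    if M_bases == 0:
        raise ValueError("cohort_burden requires a non-empty target region set")
    M_mb = M_bases / 1e6
    overlaps = count_overlaps(df, intervals)
    # genome-wide per-donor per-category totals (all records, in or out of regions)
    K: Dict[Tuple[str, str], int] = {}
    if len(df):
        cats = np.asarray(CATEGORIES)[
            classify_arrays(df["ref"].to_numpy(), df["alt"].to_numpy()) // 2
        ]
        grouped = (
            pd.DataFrame({"donor_id": df["donor_id"].to_numpy(), "category": cats})
            .groupby(["donor_id", "category"], sort=True)
            .size()
        )
        for (donor, cat), n in grouped.items():
            K[(str(donor), str(cat))] = int(n)
    donors = sorted(df["donor_id"].astype(str).unique()) if len(df) else []
    rows: List[DonorBurden] = []
    for donor in donors:
        c_sum = k_sum = 0
        for cat in CATEGORIES:
            C = overlaps.get((donor, cat), 0)
            k = K.get((donor, cat), 0)
            c_sum += C
            k_sum += k
            f = adjusting_factor(cat)
            rows.append(
                DonorBurden(
                    donor_id=donor,
                    category=cat,
                    C=C,
                    M_mb=M_mb,
                    f=f,
                    K_kilo=k / 1000.0,
                    mpkm=donor_mpkm(C, M_bases, cat, k, f=f),
                )
            )
        if include_combined:
            rows.append(
                DonorBurden(
                    donor_id=donor,
                    category="combined",
                    C=c_sum,
                    M_mb=M_mb,
                    f=F_COMBINED,
                    K_kilo=k_sum / 1000.0,
                    mpkm=donor_mpkm(c_sum, M_bases, "combined", k_sum, f=F_COMBINED),
                )
            )
    return rows


def burden_frame(rows: List[DonorBurden]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.donor_id, r.category, r.C, r.M_mb, r.f, r.K_kilo, r.mpkm) for r in rows],
        columns=["donor_id", "category", "C", "M_mb", "f", "K_kilo", "mpkm"],
    )
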