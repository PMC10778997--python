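"""Binned mutation density around focal points, normalised to MPKM.

A window of ``flank`` bases either side of every focal point is divided into
fixed-width bins (default 2 x 2000 bp in 40 bins of 100 bp).  Counts are
per-occurrence: a mutation inside the windows of several focal points
contributes once to each.  Densities are expressed as MPKM — mutations per
kilo total mutations per megabase — so that cohorts of different sizes and
regions of different base composition are comparable:

    mpkm(form, bin) = count / (n_focal * bin_width/1e6 * f(category) * K)

with K the cohort total in thousands and f the composition adjusting factor
(0.2 for C-rooted categories, 0.3 for T-rooted under GRCh38-like composition).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import as_frame
from .regions import FocalPoint, nucleotide_profile
from .spectrum import CATEGORIES, DEFAULT_F, FORMS, adjusting_factor, classify_arrays


@dataclass(frozen=True)
class BinGrid:
    """Symmetric bin layout around a focal point."""

    flank: int = 2000
    bin_width: int = 100

    def __post_init__(self) -> None:
        if self.flank <= 0 or self.bin_width <= 0:
            raise ValueError("flank and bin_width must be positive")
        if self.flank % self.bin_width:
            raise ValueError("flank must be divisible by bin_width")

    @property
    def n_bins(self) -> int:
        return 2 * self.flank // self.bin_width

    def bin_start_offsets(self) -> np.ndarray:
        """Left edge (offset from focal point) of each bin."""
        return -self.flank + np.arange(self.n_bins) * self.bin_width


@dataclass
class DensityProfile:
    """Per-form, per-bin counts (and optionally MPKM) around a focal-point set."""

    grid: BinGrid
    n_focal: int
    counts: np.ndarray                      # (12, n_bins) int64, FORMS order
    anchor: Optional[str] = None
    mpkm: Optional[np.ndarray] = None       # (12, n_bins) float, filled by normalize_mpkm
    cohort_total: Optional[int] = None
    f: Optional[Dict[str, float]] = None
    counting: str = "per-occurrence"

    def category_counts(self) -> np.ndarray:
        """(6, n_bins) counts with the two complementary forms summed."""
        return self.counts.reshape(6, 2, -1).sum(axis=1)

    def form_vectors(self, category: str, use: str = "mpkm") -> Tuple[np.ndarray, np.ndarray]:
        """Per-bin (pyrimidine form, purine form) vectors for one category."""
        ci = CATEGORIES.index(category)
        src = self.mpkm if use == "mpkm" and self.mpkm is not None else self.counts
        return src[2 * ci], src[2 * ci + 1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: form, bin_start_offset, count, mpkm."""
        offsets = self.grid.bin_start_offsets()
        rows = []
        for i, form in enumerate(FORMS):
            for b in range(self.grid.n_bins):
                rows.append(
                    (
                        form.category,
                        form.label,
                        int(offsets[b]),
                        int(self.counts[i, b]),
                        float(self.mpkm[i, b]) if self.mpkm is not None else np.nan,
                    )
                )
        return pd.DataFrame(
            rows, columns=["category", "form", "bin_start_offset", "count", "mpkm"]
        )


def bin_counts(
    mutations, points: Sequence[FocalPoint], grid: BinGrid = BinGrid()
) -> DensityProfile:
    """Tally mutations into the bin grid around every focal point.

    The offset of a mutation from a focal point is ``(pos - 1) - position``
    (both 0-based); offsets in the half-open window ``[-flank, +flank)`` fall
    into bin ``(offset + flank) // bin_width`` (offset 0 — the focal base —
    goes to the first downstream bin).  Counting is per focal occurrence.
    """
    if not points:
        raise ValueError("bin_counts requires a non-empty focal point collection")
    df = as_frame(mutations)
    counts = np.zeros((12, grid.n_bins), dtype=np.int64)
    anchors = {fp.anchor for fp in points}
    anchor = anchors.pop() if len(anchors) == 1 else None
    if len(df):
        forms = classify_arrays(df["ref"].to_numpy(), df["alt"].to_numpy())
        pos0 = df["pos"].to_numpy(dtype=np.int64) - 1
        chroms = df["chrom"].to_numpy()
        by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for c in np.unique(chroms):
            sel = np.flatnonzero(chroms == c)
            order = np.argsort(pos0[sel], kind="stable")
            by_chrom[str(c)] = (pos0[sel][order], forms[sel][order])
        for fp in points:
            if fp.chrom not in by_chrom:
                continue
            p, frm = by_chrom[fp.chrom]
            lo = np.searchsorted(p, fp.position - grid.flank, side="left")
            hi = np.searchsorted(p, fp.position + grid.flank, side="left")
            if hi > lo:
                bins = (p[lo:hi] - fp.position + grid.flank) // grid.bin_width
                np.add.at(counts, (frm[lo:hi], bins), 1)
    return DensityProfile(grid=grid, n_focal=len(points), counts=counts, anchor=anchor)


def normalize_mpkm(
    profile: DensityProfile,
    cohort_total: int,
    f: Optional[Dict[str, float]] = None,
    reference=None,
    points: Optional[Sequence[FocalPoint]] = None,
) -> DensityProfile:
    """Fill the MPKM layer of a counted profile.

    ``cohort_total`` is the cohort-wide mutation count (K = total / 1000).
    ``f`` defaults to the GRCh38-style constants; passing a reference plus the
    focal points instead recomputes f from the observed GC fraction over the
    profiled windows.
    """
    if cohort_total <= 0:
        raise ValueError("cohort_total must be positive (MPKM undefined otherwise)")
    if f is None:
        if reference is not None:
            if points is None:
                raise ValueError("recomputing f from a reference requires the focal points")
            comp = nucleotide_profile(points, reference, profile.grid.flank)
            cov = comp.coverage
            gc = float(np.nansum(comp.gc[cov > 0] * cov[cov > 0]) / cov.sum())
            f = {c: adjusting_factor(c, gc) for c in CATEGORIES}
        else:
            f = dict(DEFAULT_F)
    K = cohort_total / 1000.0
    span_mb = profile.n_focal * profile.grid.bin_width / 1e6
    denom = np.array([f[form.category] for form in FORMS])[:, None] * span_mb * K
    mpkm = profile.counts / denom
    return dataclasses.replace(
        profile, mpkm=mpkm, cohort_total=int(cohort_total), f=dict(f)
    )
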