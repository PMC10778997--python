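"""Interval-set utilities: focal points, merged sizes, overlap, base composition.

Enhancer-RNA loci are transcribed bidirectionally and the annotations carry no
direction, so eRNA focal points are unstranded by default; strand-aware
flipping (offsets negated, bases complemented) is available for comparison
profiles around stranded features such as protein-coding TSSs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .io_formats import GenomicInterval, IntervalSet

log = logging.getLogger("ernadens")

ANCHORS = ("start", "midpoint", "end")
_ANCHOR_ALIASES = {"start": "start", "mid": "midpoint", "midpoint": "midpoint", "end": "end"}

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {ord(b): i for i, b in enumerate(BASES)}


def normalize_anchor(anchor: str) -> str:
    try:
        return _ANCHOR_ALIASES[anchor.lower()]
    except KeyError:
        raise ValueError(f"anchor must be one of start/mid(point)/end, got {anchor!r}")


@dataclass(frozen=True)
class FocalPoint:
    """The anchor base (0-based) around which density is profiled."""

    chrom: str
    position: int
    anchor: str
    strand: Optional[str] = None


def focal_points(intervals: IntervalSet, anchor: str) -> List[FocalPoint]:
    """One focal point per interval at its start, midpoint, or end.

    Conventions (0-based): start -> ``start``; end -> ``end - 1`` (the last
    covered base); midpoint -> ``floor((start + end - 1) / 2)``, i.e. the
    floor midpoint between the first and last covered bases, deterministic
    for even-length intervals.
    """
    anchor = normalize_anchor(anchor)
    if len(intervals) == 0:
        raise ValueError("focal_points requires a non-empty IntervalSet")
    out = []
    for iv in intervals:
        if anchor == "start":
            p = iv.start
        elif anchor == "end":
            p = iv.end - 1
        else:
            p = (iv.start + iv.end - 1) // 2
        out.append(FocalPoint(iv.chrom, p, anchor, strand=iv.strand))
    return out


def merge_intervals(intervals: IntervalSet) -> IntervalSet:
    """Union of the intervals: overlapping/adjacent-overlapping spans merged."""
    merged: List[GenomicInterval] = []
    cur: Optional[GenomicInterval] = None
    for iv in intervals:  # already sorted by (chrom, start, end)
        if cur is not None and iv.chrom == cur.chrom and iv.start < cur.end:
            if iv.end > cur.end:
                cur = GenomicInterval(cur.chrom, cur.start, iv.end)
        else:
            if cur is not None:
                merged.append(cur)
            cur = GenomicInterval(iv.chrom, iv.start, iv.end)
    if cur is not None:
        merged.append(cur)
    return IntervalSet(merged, source_label=intervals.source_label)


def region_size(intervals: IntervalSet) -> int:
    """Number of distinct bases covered by the set (merged before summing)."""
    if len(intervals) == 0:
        return 0
    return int(merge_intervals(intervals).lengths().sum())


def filter_by_size(intervals: IntervalSet, max_len: int) -> IntervalSet:
    """Keep intervals strictly shorter than ``max_len`` bases."""
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    return IntervalSet(
        [iv for iv in intervals if iv.length < max_len],
        source_label=intervals.source_label,
    )


def _intersection_size(a: IntervalSet, b: IntervalSet) -> int:
    """Bases covered by both merged sets (two-pointer sweep per chromosome)."""
    am, bm = merge_intervals(a).by_chrom(), merge_intervals(b).by_chrom()
    total = 0
    for c in set(am) & set(bm):
        s1, e1 = am[c]
        s2, e2 = bm[c]
        i = j = 0
        while i < len(s1) and j < len(s2):
            lo = max(s1[i], s2[j])
            hi = min(e1[i], e2[j])
            if hi > lo:
                total += int(hi - lo)
            if e1[i] < e2[j]:
                i += 1
            else:
                j += 1
    return total


@dataclass
class OverlapMatrix:
    """Pairwise overlap proportions between interval sources.

    ``proportions[i, j]`` is the fraction of source i's bases covered by
    source j (asymmetric, row-normalised); NaN rows/columns mark empty sets.
    """

    labels: List[str]
    proportions: np.ndarray
    mode: str = "asymmetric"

    def mean_offdiagonal(self, unordered: bool = False) -> float:
        """Mean overlap over ordered pairs (default) or unordered-pair averages."""
        p = self.proportions
        n = len(self.labels)
        if unordered:
            vals = [
                0.5 * (p[i, j] + p[j, i])
                for i in range(n)
                for j in range(i + 1, n)
                if np.isfinite(p[i, j]) and np.isfinite(p[j, i])
            ]
        else:
            vals = [
                p[i, j]
                for i in range(n)
                for j in range(n)
                if i != j and np.isfinite(p[i, j])
            ]
        return float(np.mean(vals)) if vals else float("nan")


def pairwise_overlap(
    sets: Sequence[IntervalSet], mode: str = "asymmetric"
) -> OverlapMatrix:
    """Pairwise overlapping proportions between >= 2 interval sources.

    ``asymmetric``: entry (A, B) = covered(A by B) / size(A).
    ``jaccard``: entry (A, B) = size(A intersect B) / size(A union B) (symmetric).
    Empty sets get NaN rows and columns rather than zeros.
    """
    if len(sets) < 2:
        raise ValueError("pairwise_overlap needs at least two interval sets")
    if mode not in ("asymmetric", "jaccard"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = [s.source_label or f"set{i}" for i, s in enumerate(sets)]
    n = len(sets)
    sizes = [region_size(s) for s in sets]
    mat = np.full((n, n), np.nan)
    for i in range(n):
        if sizes[i] == 0:
            continue
        for j in range(n):
            if sizes[j] == 0:
                continue
            if i == j:
                mat[i, j] = 1.0
                continue
            inter = _intersection_size(sets[i], sets[j])
            if mode == "asymmetric":
                mat[i, j] = inter / sizes[i]
            else:
                union = sizes[i] + sizes[j] - inter
                mat[i, j] = inter / union if union else np.nan
    return OverlapMatrix(labels=labels, proportions=mat, mode=mode)


# ---------------------------------------------------------------------------
# nucleotide composition around focal points
# ---------------------------------------------------------------------------

def _fetch(reference, chrom: str, start: int, end: int) -> Optional[str]:
    """Fetch reference sequence [start, end); supports pyfaidx and mappings."""
    fetch = getattr(reference, "fetch", None)
    if callable(fetch):
        try:
            return fetch(chrom, start, end)
        except KeyError:
            return None
    try:
        seq = reference[chrom]
    except KeyError:
        return None
    return str(seq[start:end])


def _chrom_length(reference, chrom: str) -> Optional[int]:
    try:
        return len(reference[chrom])
    except KeyError:
        return None


@dataclass
class CompositionProfile:
    """Per-offset base fractions across a set of focal windows."""

    offsets: np.ndarray          # shape (2*flank + 1,)
    fractions: Dict[str, np.ndarray]
    coverage: np.ndarray         # number of windows contributing at each offset

    @property
    def gc(self) -> np.ndarray:
        return self.fractions["G"] + self.fractions["C"]

    @property
    def at(self) -> np.ndarray:
        return self.fractions["A"] + self.fractions["T"]


def nucleotide_profile(
    points: Sequence[FocalPoint],
    reference,
    flank: int,
    strand_aware: bool = False,
) -> CompositionProfile:
    """Base-composition fractions at every offset in [-flank, +flank].

    Windows truncated at chromosome edges contribute only at the offsets they
    cover; points on chromosomes absent from the reference are skipped with a
    warning.  With ``strand_aware``, minus-strand points have their offsets
    negated and bases complemented.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    width = 2 * flank + 1
    counts = np.zeros((4, width), dtype=np.int64)
    coverage = np.zeros(width, dtype=np.int64)
    comp = bytes.maketrans(b"ACGT", b"TGCA")
    n_skipped = 0
    for fp in points:
        clen = _chrom_length(reference, fp.chrom)
        if clen is None:
            n_skipped += 1
            continue
        a = max(0, fp.position - flank)
        b = min(clen, fp.position + flank + 1)
        seq = _fetch(reference, fp.chrom, a, b)
        if seq is None:
            n_skipped += 1
            continue
        raw = seq.upper().encode()
        col0 = a - (fp.position - flank)  # first covered column
        if strand_aware and fp.strand == "-":
            raw = raw.translate(comp)[::-1]
            col0 = (fp.position + flank) - (b - 1)
        arr = np.frombuffer(raw, dtype=np.uint8)
        cols = np.arange(col0, col0 + len(arr))
        for bi, base in enumerate(BASES):
            sel = arr == ord(base)
            if sel.any():
                np.add.at(counts[bi], cols[sel], 1)
        known = np.isin(arr, [ord(b_) for b_ in BASES])
        np.add.at(coverage, cols[known], 1)
    if n_skipped:
        log.warning("nucleotide_profile: skipped %d points missing from reference", n_skipped)
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = {
            base: np.where(coverage > 0, counts[i] / np.maximum(coverage, 1), np.nan)
            for i, base in enumerate(BASES)
        }
    return CompositionProfile(
        offsets=np.arange(-flank, flank + 1), fractions=fractions, coverage=coverage
    )
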