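"""Six-category SBS classification and mutation spectra.

The 12 possible single-base substitutions collapse into six categories, each
named by its pyrimidine-reference form: C>A, C>G, C>T, T>A, T>C, T>G.  Every
category owns two reciprocally complementary forms — e.g. the C>A category
pools the C>A (pyrimidine-reference) and G>T (purine-reference) calls, which
are the same event read off opposite strands.  Keeping the two forms apart is
what makes transcriptional strand-bias testing possible downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .io_formats import IntervalSet, as_frame

CATEGORIES: Tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = frozenset("CT")

#: composition adjusting factor f per category: C-rooted categories can only
#: occur on C:G base pairs (~40% of GRCh38, halved per strand -> 0.2), T-rooted
#: on A:T pairs (~60%, halved -> 0.3)
DEFAULT_F: Dict[str, float] = {c: (0.2 if c[0] == "C" else 0.3) for c in CATEGORIES}


@dataclass(frozen=True)
class MutationForm:
    """One of the 12 substitution forms: a category plus which strand reading it is."""

    category: str
    is_pyrimidine_form: bool

    @property
    def label(self) -> str:
        """The literal substitution, e.g. ``G>T`` for the purine form of C>A."""
        if self.is_pyrimidine_form:
            return self.category
        ref, alt = self.category[0], self.category[2]
        return f"{COMPLEMENT[ref]}>{COMPLEMENT[alt]}"


def classify(ref: str, alt: str) -> MutationForm:
    """Collapse a substitution to its category, remembering the strand form.

    Pyrimidine-reference substitutions (ref C or T) map to themselves; purine
    references map to the reverse-complement category with
    ``is_pyrimidine_form = False``.
    """
    if ref not in COMPLEMENT or alt not in COMPLEMENT or ref == alt:
        raise ValueError(f"malformed substitution {ref!r}>{alt!r}")
    if ref in PYRIMIDINES:
        return MutationForm(f"{ref}>{alt}", True)
    return MutationForm(f"{COMPLEMENT[ref]}>{COMPLEMENT[alt]}", False)


#: canonical ordering of the 12 forms: category-major, pyrimidine form first
FORMS: Tuple[MutationForm, ...] = tuple(
    MutationForm(c, p) for c in CATEGORIES for p in (True, False)
)

_PAIR_TO_FORM_INDEX: Dict[Tuple[str, str], int] = {}
for _i, _f in enumerate(FORMS):
    _PAIR_TO_FORM_INDEX[(_f.label[0], _f.label[2])] = _i


def form_index(form: MutationForm) -> int:
    """Index of a form in the canonical 12-slot layout (category*2 + strand)."""
    return CATEGORIES.index(form.category) * 2 + (0 if form.is_pyrimidine_form else 1)


def classify_arrays(ref: np.ndarray, alt: np.ndarray) -> np.ndarray:
    """Vectorised classification: (ref, alt) arrays -> form indices 0..11."""
    return np.fromiter(
        (_PAIR_TO_FORM_INDEX[(r, a)] for r, a in zip(ref, alt)),
        dtype=np.int64,
        count=len(ref),
    )


@dataclass
class SpectrumTally:
    """Counts over the 12 (category, form) cells plus the grand total."""

    counts: Dict[Tuple[str, bool], int]
    total: int

    def category_totals(self) -> Dict[str, int]:
        return {
            c: self.counts[(c, True)] + self.counts[(c, False)] for c in CATEGORIES
        }

    def modal_category(self) -> Optional[str]:
        totals = self.category_totals()
        if self.total == 0:
            return None
        return max(CATEGORIES, key=lambda c: totals[c])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c, MutationForm(c, p).label, self.counts[(c, p)])
            for c in CATEGORIES
            for p in (True, False)
        ]
        return pd.DataFrame(rows, columns=["category", "form", "count"])


def _in_scope_mask(df: pd.DataFrame, scope: IntervalSet) -> np.ndarray:
    """True where a 1-based mutation position lies inside any scope interval."""
    from .regions import merge_intervals  # late import to avoid a cycle

    merged = merge_intervals(scope).by_chrom()
    mask = np.zeros(len(df), dtype=bool)
    pos0 = df["pos"].to_numpy(dtype=np.int64) - 1
    chroms = df["chrom"].to_numpy()
    for c, (starts, ends) in merged.items():
        sel = chroms == c
        if not sel.any():
            continue
        p = pos0[sel]
        idx = np.searchsorted(starts, p, side="right") - 1
        inside = (idx >= 0) & (p < ends[np.clip(idx, 0, len(ends) - 1)])
        mask[sel] = inside
    return mask


def tally_spectrum(
    mutations, scope: Optional[IntervalSet] = None
) -> SpectrumTally:
    """Tally the 12-cell mutation spectrum, optionally restricted to a region set."""
    df = as_frame(mutations)
    if scope is not None and len(df):
        df = df.loc[_in_scope_mask(df, scope)]
    counts = {(c, p): 0 for c in CATEGORIES for p in (True, False)}
    if len(df):
        idx = classify_arrays(df["ref"].to_numpy(), df["alt"].to_numpy())
        binned = np.bincount(idx, minlength=12)
        for i, f in enumerate(FORMS):
            counts[(f.category, f.is_pyrimidine_form)] = int(binned[i])
    return SpectrumTally(counts=counts, total=int(len(df)))


def adjusting_factor(category: str, gc_fraction: Optional[float] = None) -> float:
    """Composition factor f for a category (or ``combined``).

    With no reference composition supplied, the GRCh38-style defaults are used
    (0.2 for C-rooted, 0.3 for T-rooted, 0.25 combined).  Given an observed GC
    fraction g, the factors become g/2 (C-rooted) and (1-g)/2 (T-rooted) —
    the per-strand frequency of the substrate base.
    """
    if category == "combined":
        return 0.25
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if gc_fraction is None:
        return DEFAULT_F[category]
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must lie in (0, 1)")
    return gc_fraction / 2.0 if category[0] == "C" else (1.0 - gc_fraction) / 2.0
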