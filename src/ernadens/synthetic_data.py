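"""Reproducible synthetic cohorts: chromosomes, eRNA intervals, SBS catalogs.

The generator emulates the statistical structure the analysis assumes so that
every stage is testable without controlled-access data:

* i.i.d. reference chromosomes with a configurable GC fraction;
* non-overlapping eRNA-like intervals with uniform lengths and placement;
* per-donor SBS catalogs whose positions follow an intensity

      lambda(x) = baseline * (1 - dip_depth * g(x; mid, dip_halfwidth)
                                + peak_height * (g(x; start, peak_halfwidth)
                                                 + g(x; end,  peak_halfwidth)))

  with ``g`` a triangular kernel (compact support, so a distant background
  window is provably unaffected by the injected effects);
* a strand effect: mutations take the pyrimidine-reference form with
  probability 0.5 + strand_beta/2 downstream of an interval midpoint and
  0.5 - strand_beta/2 upstream (0.5 elsewhere).  ``strand_extent`` bounds the
  bias zone: ``None`` confines it to the interval itself, a length in bp
  extends it symmetrically around the midpoint.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from .io_formats import MUTATION_COLUMNS, GenomicInterval, IntervalSet
from .spectrum import CATEGORIES, COMPLEMENT, FORMS

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SynthConfig:
    """All knobs of the synthetic cohort, with the study-condition defaults."""

    seed: int = 0
    n_chroms: int = 1
    chrom_length: int = 300_000
    n_ernas: int = 25
    erna_length_min: int = 500
    erna_length_max: int = 1999
    n_donors: int = 20
    donor_total_median: float = 500.0   # per-donor mutation totals ~ log-normal
    donor_total_sigma: float = 0.5
    category_weights: Tuple[float, ...] = (0.10, 0.10, 0.40, 0.10, 0.20, 0.10)
    baseline_rate: float = 1.0          # relative positional intensity baseline
    dip_depth: float = 0.0              # in [0, 1], depletion at interval midpoints
    dip_halfwidth: int = 200            # bp, triangular kernel half-width
    peak_height: float = 0.0            # >= 0, enrichment at interval start/end
    peak_halfwidth: int = 200
    strand_beta: float = 0.0            # in [-1, 1], pyrimidine-form excess downstream
    strand_extent: Optional[int] = None  # bp around the midpoint; None = the interval
    strand_categories: Optional[Tuple[str, ...]] = None  # None = bias all categories
    gc_fraction: float = 0.41
    edge_margin: int = 50_000           # keep intervals this far from chromosome ends
    min_spacing: int = 0                # minimum gap between intervals

    def __post_init__(self) -> None:
        if abs(sum(self.category_weights) - 1.0) > 1e-9 or len(self.category_weights) != 6:
            raise ValueError("category_weights must be a 6-vector summing to 1")
        if any(w < 0 for w in self.category_weights):
            raise ValueError("category_weights must be non-negative")
        if not 0.0 <= self.dip_depth <= 1.0:
            raise ValueError("dip_depth must lie in [0, 1]")
        if not -1.0 <= self.strand_beta <= 1.0:
            raise ValueError("strand_beta must lie in [-1, 1]")
        if self.peak_height < 0 or self.baseline_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 < self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in (0, 1]")
        if not 0 < self.erna_length_min <= self.erna_length_max:
            raise ValueError("need 0 < erna_length_min <= erna_length_max")
        if self.strand_categories is not None:
            unknown = set(self.strand_categories) - set(CATEGORIES)
            if unknown:
                raise ValueError(f"unknown strand_categories {sorted(unknown)}")

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)

    def null(self, seed: Optional[int] = None) -> "SynthConfig":
        """A copy with every injected effect zeroed (homogeneous, symmetric)."""
        return self.replace(
            dip_depth=0.0,
            peak_height=0.0,
            strand_beta=0.0,
            seed=self.seed if seed is None else int(seed),
        )

    def chrom_names(self) -> List[str]:
        return [str(i + 1) for i in range(self.n_chroms)]


def save_config(config: SynthConfig, path: Union[str, Path]) -> None:
    data = dataclasses.asdict(config)
    data["category_weights"] = list(config.category_weights)
    if config.strand_categories is not None:
        data["strand_categories"] = list(config.strand_categories)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_config(path: Union[str, Path]) -> SynthConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "category_weights" in data:
        data["category_weights"] = tuple(data["category_weights"])
    if data.get("strand_categories") is not None:
        data["strand_categories"] = tuple(data["strand_categories"])
    return SynthConfig(**data)


class _SeqView:
    """Sliceable view of one synthetic chromosome (slices return strings)."""

    def __init__(self, buf: bytearray):
        self._buf = buf

    def __len__(self) -> int:
        return len(self._buf)

    def __getitem__(self, key) -> str:
        return self._buf[key].decode() if isinstance(key, slice) else chr(self._buf[key])


class SyntheticReference:
    """In-memory FASTA-like reference with mutable bases."""

    def __init__(self, chroms: Dict[str, bytearray]):
        self._chroms = chroms

    def keys(self):
        return self._chroms.keys()

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def __getitem__(self, chrom: str) -> _SeqView:
        return _SeqView(self._chroms[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self._chroms[chrom][start:end].decode()

    def array(self, chrom: str) -> np.ndarray:
        """Writable uint8 view of a chromosome's bases."""
        return np.frombuffer(self._chroms[chrom], dtype=np.uint8)

    def write_fasta(self, path: Union[str, Path], width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, buf in self._chroms.items():
                fh.write(f">{name}\n")
                for i in range(0, len(buf), width):
                    fh.write(buf[i : i + width].decode() + "\n")


def generate_reference(
    config: SynthConfig, rng: Optional[np.random.Generator] = None
) -> SyntheticReference:
    """I.i.d. chromosomes with P(G) = P(C) = gc_fraction / 2."""
    rng = rng or np.random.default_rng(config.seed)
    gc, at = config.gc_fraction, 1.0 - config.gc_fraction
    p = [at / 2, gc / 2, gc / 2, at / 2]  # A C G T
    chroms = {
        name: bytearray(rng.choice(_ACGT, size=config.chrom_length, p=p).tobytes())
        for name in config.chrom_names()
    }
    return SyntheticReference(chroms)


def generate_ernas(
    config: SynthConfig, rng: Optional[np.random.Generator] = None
) -> IntervalSet:
    """Non-overlapping intervals, uniform lengths and placement, margin-respecting."""
    rng = rng or np.random.default_rng(config.seed)
    names = config.chrom_names()
    per_chrom = [config.n_ernas // len(names)] * len(names)
    for i in range(config.n_ernas % len(names)):
        per_chrom[i] += 1
    intervals: List[GenomicInterval] = []
    for chrom, n in zip(names, per_chrom):
        if n == 0:
            continue
        lengths = rng.integers(
            config.erna_length_min, config.erna_length_max + 1, size=n
        ).astype(np.int64)
        free = (
            config.chrom_length
            - 2 * config.edge_margin
            - int(lengths.sum())
            - (n - 1) * config.min_spacing
        )
        if free < 0:
            raise ValueError(
                f"chromosome {chrom}: cannot place {n} intervals with margin "
                f"{config.edge_margin} and spacing {config.min_spacing}"
            )
        slack = np.floor(np.sort(rng.random(n)) * free).astype(np.int64)
        prev = np.concatenate(([0], np.cumsum(lengths[:-1])))
        starts = config.edge_margin + slack + prev + config.min_spacing * np.arange(n)
        for j, (s, ln) in enumerate(zip(starts, lengths)):
            intervals.append(
                GenomicInterval(chrom, int(s), int(s + ln), name=f"{chrom}_e{j}")
            )
    return IntervalSet(intervals, source_label="synthetic")


def _intensity(config: SynthConfig, ernas: IntervalSet, chrom: str) -> np.ndarray:
    lam = np.full(config.chrom_length, float(config.baseline_rate))
    starts_ends = ernas.by_chrom().get(chrom)
    if starts_ends is None:
        return lam

    def add_kernel(center: int, halfwidth: int, coef: float) -> None:
        if coef == 0.0 or halfwidth <= 0:
            return
        lo = max(0, center - halfwidth + 1)
        hi = min(config.chrom_length, center + halfwidth)
        x = np.arange(lo, hi)
        lam[lo:hi] += (
            config.baseline_rate * coef * (1.0 - np.abs(x - center) / halfwidth)
        )

    for s, e in zip(*starts_ends):
        mid = (int(s) + int(e) - 1) // 2
        add_kernel(mid, config.dip_halfwidth, -config.dip_depth)
        add_kernel(int(s), config.peak_halfwidth, config.peak_height)
        add_kernel(int(e) - 1, config.peak_halfwidth, config.peak_height)
    np.maximum(lam, 0.0, out=lam)
    return lam


def _bias_zone(config: SynthConfig, ernas: IntervalSet, chrom: str) -> np.ndarray:
    """Per-base strand-bias zone: +1 downstream of a midpoint, -1 upstream, 0 outside."""
    zone = np.zeros(config.chrom_length, dtype=np.int8)
    starts_ends = ernas.by_chrom().get(chrom)
    if starts_ends is None or config.strand_beta == 0.0:
        return zone
    for s, e in zip(*starts_ends):
        mid = (int(s) + int(e) - 1) // 2
        if config.strand_extent is None:
            lo, hi = int(s), int(e)
        else:
            lo = max(0, mid - config.strand_extent)
            hi = min(config.chrom_length, mid + config.strand_extent)
        zone[lo:mid] = -1
        zone[mid:hi] = 1
    return zone


def generate_mutations(
    config: SynthConfig,
    ernas: IntervalSet,
    reference: Optional[SyntheticReference] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Per-donor SBS catalogs as a mutation frame (donor_id, chrom, pos, ref, alt).

    Donor totals are log-normal; positions follow the positional intensity;
    categories follow ``category_weights``; the strand form follows the bias
    zone.  When a reference is supplied, its base at each mutated site is
    overwritten with the sampled ref allele so that catalog and reference
    stay consistent.
    """
    import pandas as pd

    rng = rng or np.random.default_rng(config.seed)
    names = config.chrom_names()
    if config.donor_total_median > 0 and config.n_donors > 0:
        totals = np.rint(
            rng.lognormal(
                mean=math.log(config.donor_total_median),
                sigma=config.donor_total_sigma,
                size=config.n_donors,
            )
        ).astype(np.int64)
    else:
        totals = np.zeros(config.n_donors, dtype=np.int64)
    n_total = int(totals.sum())
    empty = pd.DataFrame(
        {c: pd.Series(dtype=(np.int64 if c == "pos" else object)) for c in MUTATION_COLUMNS}
    )
    if n_total == 0:
        return empty

    lam_chrom = [_intensity(config, ernas, c) for c in names]
    weights = np.concatenate(lam_chrom)
    if weights.sum() <= 0:
        return empty
    cum = np.cumsum(weights)
    gidx = np.searchsorted(cum, rng.random(n_total) * cum[-1], side="right")
    chrom_of = gidx // config.chrom_length  # chromosomes share one length
    pos0 = gidx % config.chrom_length

    cat_idx = rng.choice(6, size=n_total, p=np.asarray(config.category_weights))
    zone = np.zeros(n_total, dtype=np.int8)
    for ci, name in enumerate(names):
        sel = chrom_of == ci
        if sel.any():
            zone[sel] = _bias_zone(config, ernas, name)[pos0[sel]]
    if config.strand_categories is not None:
        biased = np.isin(
            cat_idx, [CATEGORIES.index(c) for c in config.strand_categories]
        )
        zone = np.where(biased, zone, 0)
    p_pyr = 0.5 + zone * (config.strand_beta / 2.0)
    is_pyr = rng.random(n_total) < p_pyr

    # per-form ref/alt lookup in FORMS order (category*2 + [pyr, pur])
    form_idx = cat_idx * 2 + (~is_pyr).astype(np.int64)
    refs = np.array([f.label[0] for f in FORMS])
    alts = np.array([f.label[2] for f in FORMS])
    ref = refs[form_idx]
    alt = alts[form_idx]

    if reference is not None:
        ref_ord = np.array([ord(f.label[0]) for f in FORMS], dtype=np.uint8)
        for ci, name in enumerate(names):
            sel = chrom_of == ci
            if sel.any():
                reference.array(name)[pos0[sel]] = ref_ord[form_idx[sel]]

    donor_labels = np.array([f"D{i:04d}" for i in range(config.n_donors)])
    df = pd.DataFrame(
        {
            "donor_id": np.repeat(donor_labels, totals),
            "chrom": np.asarray(names, dtype=object)[chrom_of],
            "pos": pos0 + 1,
            "ref": ref,
            "alt": alt,
        }
    )
    return df


@dataclass
class Cohort:
    """One synthetic study: config, optional reference, intervals, catalog."""

    config: Optional[SynthConfig]
    ernas: IntervalSet
    mutations: object  # pandas DataFrame in the canonical mutation layout
    reference: Optional[SyntheticReference] = None


def cohort_from_spectrum(
    genome_counts: Dict[str, int],
    region_counts: Dict[str, int],
    region_bases: int,
    donor_id: str = "D0000",
    seed: int = 0,
    n_intervals: int = 10,
) -> Cohort:
    """A single-donor catalog realising given genome-wide and in-region spectra.

    Builds a target region set whose merged size is exactly ``region_bases``
    and a mutation frame in which, for every category, ``region_counts``
    mutations fall inside the regions and ``genome_counts - region_counts``
    fall outside; forms are assigned 50/50.  Useful for reproducing printed
    per-donor burden examples end-to-end through the overlap-counting path.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    for cat in CATEGORIES:
        if region_counts.get(cat, 0) > genome_counts.get(cat, 0):
            raise ValueError(f"{cat}: region count exceeds genome-wide count")
    base = region_bases // n_intervals
    lengths = [base] * (n_intervals - 1) + [region_bases - base * (n_intervals - 1)]
    gap = 10_000
    intervals, cursor = [], gap
    for i, ln in enumerate(lengths):
        intervals.append(GenomicInterval("1", cursor, cursor + ln, name=f"wx_{i}"))
        cursor += ln + gap
    ernas = IntervalSet(intervals, source_label="worked-example")
    starts = np.array([iv.start for iv in intervals], dtype=np.int64)
    cum = np.cumsum([iv.length for iv in intervals])
    out_lo, out_hi = cursor + gap, cursor + gap + 50_000_000

    rows = []
    for ci, cat in enumerate(CATEGORIES):
        k_in = int(region_counts.get(cat, 0))
        k_out = int(genome_counts.get(cat, 0)) - k_in
        offs = rng.integers(0, region_bases, size=k_in)
        j = np.searchsorted(cum, offs, side="right")
        pos0_in = starts[j] + offs - (cum[j] - np.asarray(lengths)[j])
        pos0_out = rng.integers(out_lo, out_hi, size=k_out)
        for pos0 in np.concatenate([pos0_in, pos0_out]):
            pyr = bool(rng.random() < 0.5)
            form = FORMS[ci * 2 + (0 if pyr else 1)]
            rows.append((donor_id, "1", int(pos0) + 1, form.label[0], form.label[2]))
    df = pd.DataFrame(rows, columns=list(MUTATION_COLUMNS))
    df["pos"] = df["pos"].astype(np.int64)
    return Cohort(config=None, ernas=ernas, mutations=df)


def generate_cohort(config: SynthConfig, with_reference: bool = True) -> Cohort:
    """Generate reference (optional), intervals, and catalog from one seed."""
    rng = np.random.default_rng(config.seed)
    reference = generate_reference(config, rng) if with_reference else None
    ernas = generate_ernas(config, rng)
    mutations = generate_mutations(config, ernas, reference=reference, rng=rng)
    return Cohort(config=config, ernas=ernas, mutations=mutations, reference=reference)


def generate_null_batch(
    config: SynthConfig, n_replicates: int, with_reference: bool = False
) -> Iterator[Cohort]:
    """Independent all-effects-zero cohorts with seeds derived from the master seed."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seeds = replicate_seeds(config.seed, n_replicates)
    for s in seeds:
        yield generate_cohort(config.null(seed=int(s)), with_reference=with_reference)


def replicate_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic, distinct child seeds below 2**31."""
    rng = np.random.default_rng(master_seed)
    seen: List[int] = []
    taken = set()
    while len(seen) < n:
        for s in rng.integers(0, 2**31 - 1, size=n):
            if int(s) not in taken:
                taken.add(int(s))
                seen.append(int(s))
                if len(seen) == n:
                    break
    return np.asarray(seen, dtype=np.int64)
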