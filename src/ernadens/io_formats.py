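"""Readers and writers for the on-disk formats the pipeline consumes and emits.

Coordinate conventions
----------------------
Mutation positions are 1-based (ICGC / VCF convention); genomic intervals are
0-based half-open (BED convention).  The conversion between the two happens in
exactly one place — inside the overlap / binning operations — so that no
off-by-one drift can accumulate across modules.

Chromosome names are normalised on read: a leading ``chr`` is stripped, the
remainder is upper-cased, and the mitochondrial aliases ``M``/``MT`` are
unified to ``MT``.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import typing
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

log = logging.getLogger("ernadens")
if not log.handlers:  # timestamps + counts to stderr, once
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

VALID_BASES = frozenset("ACGT")

#: canonical column order of the in-memory mutation table
MUTATION_COLUMNS = ("donor_id", "chrom", "pos", "ref", "alt")


def normalize_chrom(name: object) -> str:
    """Normalise a chromosome name: drop ``chr`` prefix, upper-case, ``M`` -> ``MT``."""
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    if s == "M":
        s = "MT"
    return s


@dataclass(frozen=True)
class MutationRecord:
    """A single donor single-base-substitution call (1-based position)."""

    donor_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"ref/alt must be single bases in ACGT, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) is not a substitution")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


class IntervalSet:
    """An immutable, sorted collection of :class:`GenomicInterval`.

    Intervals are kept sorted by ``(chrom, start, end)``; overlapping intervals
    are retained as-is (merging is an explicit operation, see
    :func:`ernadens.regions.merge_intervals`).
    """

    def __init__(self, intervals: Iterable[GenomicInterval], source_label: str = ""):
        ivs = tuple(sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)))
        self._intervals = ivs
        self.source_label = source_label
        self._by_chrom: Optional[dict] = None

    @property
    def intervals(self) -> tuple:
        return self._intervals

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, IntervalSet) and self._intervals == other._intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, source={self.source_label!r})"

    def chroms(self) -> list:
        return sorted({iv.chrom for iv in self._intervals})

    def by_chrom(self) -> Mapping[str, tuple]:
        """Per-chromosome ``(starts, ends)`` int64 arrays (cached)."""
        if self._by_chrom is None:
            out: dict = {}
            for c in self.chroms():
                ivs = [iv for iv in self._intervals if iv.chrom == c]
                out[c] = (
                    np.array([iv.start for iv in ivs], dtype=np.int64),
                    np.array([iv.end for iv in ivs], dtype=np.int64),
                )
            self._by_chrom = out
        return self._by_chrom

    def lengths(self) -> np.ndarray:
        return np.array([iv.length for iv in self._intervals], dtype=np.int64)


@dataclass(frozen=True)
class TableDialect:
    """Column mapping for a tab-separated mutation table."""

    donor_id: str = "donor_id"
    chrom: str = "chromosome"
    pos: str = "position"
    ref: str = "ref"
    alt: str = "alt"
    sep: str = "\t"


DEFAULT_DIALECT = TableDialect()
#: the ICGC simple-somatic-mutation export column names
ICGC_DIALECT = TableDialect(
    donor_id="icgc_donor_id",
    chrom="chromosome",
    pos="chromosome_start",
    ref="mutated_from_allele",
    alt="mutated_to_allele",
)


def validate_mutations(df: pd.DataFrame) -> pd.DataFrame:
    """Check a mutation frame for the SBS invariants; returns the frame unchanged."""
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns {missing}")
    if len(df):
        ref = df["ref"].to_numpy()
        alt = df["alt"].to_numpy()
        ok = (
            np.isin(ref, list(VALID_BASES))
            & np.isin(alt, list(VALID_BASES))
            & (ref != alt)
            & (df["pos"].to_numpy() >= 1)
        )
        if not ok.all():
            raise ValueError(f"{(~ok).sum()} rows violate the SBS invariants")
    return df


def records_to_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    rows = [(r.donor_id, r.chrom, r.pos, r.ref, r.alt) for r in records]
    df = pd.DataFrame(rows, columns=list(MUTATION_COLUMNS))
    df["pos"] = df["pos"].astype(np.int64)
    return df


def frame_to_records(df: pd.DataFrame) -> list:
    return [
        MutationRecord(str(d), str(c), int(p), str(r), str(a))
        for d, c, p, r, a in df[list(MUTATION_COLUMNS)].itertuples(index=False)
    ]


def as_frame(mutations: Union[pd.DataFrame, Iterable[MutationRecord]]) -> pd.DataFrame:
    """Coerce either container (frame or record iterable) to the canonical frame."""
    if isinstance(mutations, pd.DataFrame):
        return mutations
    return records_to_frame(mutations)


def read_mutations(
    path: Union[str, Path], dialect: TableDialect = DEFAULT_DIALECT
) -> pd.DataFrame:
    """Read a somatic mutation table, keeping only single-base substitutions.

    Rows whose ref or alt is not a single A/C/G/T, whose ref equals alt, or
    whose position cannot be parsed as a positive integer are dropped and
    tallied (not fatal).  Chromosome names are normalised.  Returns a frame
    with columns ``donor_id, chrom, pos, ref, alt``.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    for col in (dialect.donor_id, dialect.chrom, dialect.pos, dialect.ref, dialect.alt):
        if col not in raw.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df = pd.DataFrame(
        {
            "donor_id": raw[dialect.donor_id].astype(str),
            "chrom": raw[dialect.chrom].map(normalize_chrom),
            "pos": pd.to_numeric(raw[dialect.pos], errors="coerce"),
            "ref": raw[dialect.ref].str.strip().str.upper(),
            "alt": raw[dialect.alt].str.strip().str.upper(),
        }
    )
    n_total = len(df)
    pos_ok = df["pos"].notna() & (df["pos"] >= 1) & (df["pos"] == df["pos"].round())
    sbs_ok = (
        df["ref"].isin(list(VALID_BASES))
        & df["alt"].isin(list(VALID_BASES))
        & (df["ref"] != df["alt"])
    )
    keep = pos_ok & sbs_ok
    out = df.loc[keep].copy()
    out["pos"] = out["pos"].astype(np.int64)
    out = out.reset_index(drop=True)
    n_bad_pos = int((~pos_ok).sum())
    log.info(
        "read_mutations %s: kept %d SBS records, dropped %d (%d malformed positions)",
        path.name,
        len(out),
        n_total - len(out),
        n_bad_pos,
    )
    return out


def write_mutations(
    mutations: Union[pd.DataFrame, Iterable[MutationRecord]],
    path: Union[str, Path],
    dialect: TableDialect = DEFAULT_DIALECT,
) -> None:
    """Write a mutation table in the given dialect (round-trips through read_mutations)."""
    df = as_frame(mutations)
    out = pd.DataFrame(
        {
            dialect.donor_id: df["donor_id"],
            dialect.chrom: df["chrom"],
            dialect.pos: df["pos"],
            dialect.ref: df["ref"],
            dialect.alt: df["alt"],
        }
    )
    out.to_csv(path, sep=dialect.sep, index=False)


def read_bed(path: Union[str, Path], label: str = "") -> IntervalSet:
    """Read a BED3/BED6 file into a sorted :class:`IntervalSet`.

    Overlapping rows are retained (no merging on read); a row with
    ``start >= end`` is a fatal error reported with its line number.
    """
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED row needs >= 3 fields")
            chrom = normalize_chrom(parts[0])
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            name = parts[3] if len(parts) > 3 and parts[3] not in ("", ".") else None
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else None
            intervals.append(GenomicInterval(chrom, start, end, name=name, strand=strand))
    iset = IntervalSet(intervals, source_label=label or path.stem)
    log.info("read_bed %s: %d intervals", path.name, len(iset))
    return iset


def write_bed(intervals: IntervalSet, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand is not None:
                fields += [iv.name or ".", "0", iv.strand or "."]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# generic result-table round-trip
# ---------------------------------------------------------------------------

def _field_types(record_type: type) -> dict:
    hints = typing.get_type_hints(record_type)
    return {f.name: hints[f.name] for f in dataclasses.fields(record_type)}


def _parse_cell(text: str, typ: object):
    origin = typing.get_origin(typ)
    if origin is Union:  # Optional[...]
        args = [a for a in typing.get_args(typ) if a is not type(None)]
        if text == "":
            return None
        return _parse_cell(text, args[0])
    if typ is int:
        return int(text)
    if typ is float:
        return float(text)
    if typ is bool:
        return text == "True"
    return text


def write_table(records: Sequence, path: Union[str, Path]) -> None:
    """Write a homogeneous collection of result dataclasses as a headed TSV.

    Column order is the dataclass field order, so it is stable across runs;
    floats are written at full ``repr`` precision and round-trip exactly
    through :func:`read_table`.  An empty collection still needs a concrete
    element to derive a header from, so pass a list of at least length zero of
    a known type via :func:`write_empty_table` in that case.
    """
    records = list(records)
    if not records:
        raise ValueError("write_table needs at least one record; use write_empty_table")
    record_type = type(records[0])
    if not all(type(r) is record_type for r in records):
        raise ValueError("write_table requires records of a single type")
    cols = [f.name for f in dataclasses.fields(record_type)]
    df = pd.DataFrame([[getattr(r, c) for c in cols] for r in records], columns=cols)
    df.to_csv(path, sep="\t", index=False, na_rep="")


def write_empty_table(record_type: type, path: Union[str, Path]) -> None:
    cols = [f.name for f in dataclasses.fields(record_type)]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")


def read_table(path: Union[str, Path], record_type: type) -> list:
    """Read a TSV written by :func:`write_table` back into dataclass instances."""
    types = _field_types(record_type)
    cols = list(types)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != cols:
        raise ValueError(f"{path}: columns {list(df.columns)} != expected {cols}")
    out = []
    for row in df.itertuples(index=False):
        kwargs = {c: _parse_cell(getattr(row, c), types[c]) for c in cols}
        out.append(record_type(**kwargs))
    return out
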