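"""Readers and writers for the genomic file formats the pipeline touches.

All coordinates are held internally in the BED convention: 0-based,
half-open ``[start, end)``.  GFF3, which is 1-based inclusive, is converted
at the boundary in both directions.  Sequences are normalised to uppercase
``{A, C, G, T, N}``; anything else becomes ``N`` with a warning and is
excluded from every downstream frequency count.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


_VALID_BASES = frozenset("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A named chromosome sequence over the alphabet {A, C, G, T, N}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise FormatError(f"sequence {self.name!r} is empty")
        if not _VALID_BASES.issuperset(self.seq):
            bad = sorted(set(self.seq) - _VALID_BASES)
            raise FormatError(
                f"sequence {self.name!r} contains invalid symbols {bad}; "
                "normalise with read_fasta or sanitize_sequence"
            )

    def __len__(self) -> int:
        return len(self.seq)


def sanitize_sequence(seq: str, name: str = "<anonymous>") -> str:
    """Uppercase *seq* and map any symbol outside {A,C,G,T,N} to N."""
    up = seq.upper()
    if _NON_ACGTN.search(up):
        warnings.warn(
            f"sequence {name!r}: non-ACGTN symbols replaced with N", stacklevel=2
        )
        up = _NON_ACGTN.sub("N", up)
    return up


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).  ``label`` is
    free text (e.g. an ORI confidence tag or gene identifier).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def shift(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(
            self.chrom, self.start + offset, self.end + offset, self.strand, self.label
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class SignalTrack:
    """Per-base numeric values along chromosomes; NaN marks uncovered bases."""

    def __init__(self, data: Mapping[str, np.ndarray]):
        self.data: dict[str, np.ndarray] = {}
        for chrom, vec in data.items():
            arr = np.asarray(vec, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"track for {chrom!r} must be 1-D")
            with np.errstate(invalid="ignore"):
                if np.isinf(arr).any():
                    raise ValueError(f"track for {chrom!r} contains infinities")
            self.data[chrom] = arr

    @classmethod
    def allocate(cls, genome: Iterable[GenomeSequence]) -> "SignalTrack":
        return cls({g.name: np.full(len(g), np.nan) for g in genome})

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        return self.data[chrom][start:end]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        if self.data.keys() != other.data.keys():
            return False
        return all(
            np.array_equal(self.data[c], other.data[c], equal_nan=True)
            for c in self.data
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into normalised :class:`GenomeSequence` records."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record name {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeSequence(rec.id, sanitize_sequence(str(rec.seq), rec.id)))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(genome: Iterable[GenomeSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for g in genome:
            fh.write(f">{g.name}\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals (native 0-based half-open coordinates)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end} (empty interval)"
                )
            label = cols[3] if len(cols) > 3 and cols[3] != "." else None
            strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "."
            intervals.append(GenomicInterval(chrom, start, end, strand, label))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.label if iv.label is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# GFF3 (genes)


def read_gff3_genes(path: str | Path) -> list[GenomicInterval]:
    """Extract ``gene`` features from GFF3, converting to 0-based half-open.

    Genes must carry an explicit strand; ``.`` or ``?`` is a format error.
    Input order is preserved.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        if feat.strand not in ("+", "-"):
            raise FormatError(
                f"{path}: gene {feat.id!r} has no usable strand ({feat.strand!r})"
            )
        label = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand, label)
        )
    return genes


def write_gff3_genes(genes: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, g in enumerate(genes):
            gid = g.label if g.label is not None else f"gene{i + 1}"
            fh.write(
                f"{g.chrom}\tsynthetic\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={gid}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str | Path, genome: Sequence[GenomeSequence]) -> SignalTrack:
    """Fill a per-base :class:`SignalTrack` from a 4-column bedGraph file.

    Uncovered bases stay NaN.  Overlapping intervals resolve
    last-writer-wins with a warning.
    """
    lengths = {g.name: len(g) for g in genome}
    track = SignalTrack.allocate(genome)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        )
    except pd.errors.EmptyDataError:
        return track
    if df.empty:
        return track
    unknown = set(df["chrom"]) - set(lengths)
    if unknown:
        raise FormatError(f"{path}: unknown chromosome(s) {sorted(unknown)}")
    overlap_warned = False
    for chrom, sub in df.groupby("chrom", sort=False):
        n = lengths[chrom]
        if (sub["start"] < 0).any() or (sub["end"] > n).any():
            raise FormatError(f"{path}: interval outside chromosome {chrom!r} (length {n})")
        vec = track.data[chrom]
        covered = np.zeros(n, dtype=bool)
        for start, end, value in sub[["start", "end", "value"]].itertuples(index=False):
            if not overlap_warned and covered[start:end].any():
                warnings.warn(
                    f"{path}: overlapping bedGraph intervals on {chrom}; "
                    "last writer wins",
                    stacklevel=2,
                )
                overlap_warned = True
            vec[start:end] = value
            covered[start:end] = True
    return track


def write_bedgraph(track: SignalTrack, path: str | Path, decimals: int = 4) -> None:
    """Write a track as run-length-encoded bedGraph (NaN bases omitted)."""
    with open(path, "w") as fh:
        for chrom in track.data:
            vec = np.round(track.data[chrom], decimals)
            n = len(vec)
            finite = np.isfinite(vec)
            # run boundaries: value change or coverage change
            change = np.ones(n, dtype=bool)
            if n > 1:
                same = (vec[1:] == vec[:-1]) | (~finite[1:] & ~finite[:-1])
                change[1:] = ~same
            starts = np.flatnonzero(change)
            ends = np.append(starts[1:], n)
            for s, e in zip(starts, ends):
                if finite[s]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{vec[s]:.{decimals}f}\n")


# ---------------------------------------------------------------------------
# TSV reports


def write_tsv_report(rows: Sequence[Mapping[str, object]], path: str | Path,
                     columns: Sequence[str] | None = None) -> None:
    """Write homogeneous records as a TSV with floats at 6 significant digits."""
    rows = list(rows)
    if columns is None:
        if not rows:
            raise ValueError("cannot infer a header from an empty record set")
        columns = list(rows[0].keys())
    for r in rows:
        if list(r.keys()) != list(columns):
            raise ValueError("records are not homogeneous")

    def fmt(v: object) -> str:
        if isinstance(v, float) and not isinstance(v, bool):
            if np.isnan(v):
                return "NA"
            return f"{v:.6g}"
        return str(v)

    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for r in rows:
            fh.write("\t".join(fmt(r[c]) for c in columns) + "\n")
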