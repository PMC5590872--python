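"""Streaming readers/writers for the formats the pipeline touches.

FASTA and FASTQ (plain or gzip, detected by magic bytes), BED (3- or
6-column), the marker-FASTA header dialect used to serialize marker pairs,
and the per-sample TSV report.  No algorithmics live here.

Coordinates in this package are 1-based inclusive everywhere a position is
user-visible (matching the convention of published marker tables, where
``length == end - start + 1``); BED input is converted from its 0-based
half-open convention on read.  Internal string indices are 0-based; the
conversion happens only at these I/O boundaries.
"""

from __future__ import annotations

import gzip
import io
import itertools
import logging
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence, TextIO

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger("sexmark.seqio")

__all__ = [
    "FormatError",
    "SeqRecord",
    "ReadRecord",
    "Member",
    "MarkerHeader",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_bed",
    "write_bed",
    "BedInterval",
    "parse_marker_header",
    "format_marker_header",
    "write_marker_fasta",
    "read_marker_fasta",
    "write_report",
    "normalize_sequence",
]


class FormatError(ValueError):
    """A malformed input file; carries the path and (when known) the line."""

    def __init__(self, path, line: int | None, message: str):
        self.path = str(path)
        self.line = line
        where = f"{path}" if line is None else f"{path}:{line}"
        super().__init__(f"{where}: {message}")


# --------------------------------------------------------------------------
# sequence normalization
# --------------------------------------------------------------------------

_UPPER = bytes(range(256)).upper()
_TO_N = bytes(c if chr(c) in "ACGTN" else ord("N") for c in range(256))


def normalize_sequence(seq: str, *, context: str = "sequence") -> str:
    """Uppercase and map every non-ACGT character to ``N``.

    A warning is logged when anything other than case was changed; ``N``
    never matches any base downstream, so masked or ambiguous input stays
    inert rather than undefined.
    """
    raw = seq.encode("latin-1").translate(_UPPER)
    out = raw.translate(_TO_N)
    if out != raw:
        a = np.frombuffer(raw, dtype=np.uint8)
        b = np.frombuffer(out, dtype=np.uint8)
        n = int(np.count_nonzero(a != b))
        logger.warning("%s: %d non-ACGTN character(s) replaced with N", context, n)
    return out.decode("latin-1")


def _open_text(path) -> TextIO:
    """Open plain or gzip text transparently (gzip detected by magic bytes)."""
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=fh), encoding="latin-1")
    return io.TextIOWrapper(fh, encoding="latin-1")


# --------------------------------------------------------------------------
# records
# --------------------------------------------------------------------------


@dataclass
class SeqRecord:
    """A named DNA sequence over the alphabet {A,C,G,T,N}."""

    id: str
    description: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


class ReadRecord(NamedTuple):
    """One sequencing read with its Phred+33 quality string."""

    id: str
    sequence: str
    quality: str


def read_fasta(path) -> Iterator[SeqRecord]:
    """Stream records from a FASTA file in file order.

    Multi-line sequences are joined; sequences are uppercased with non-ACGT
    characters mapped to ``N``.  Raises :class:`FormatError` for an empty
    file, a file that does not start with a ``>`` header, a duplicated id,
    or an empty sequence.
    """
    with _open_text(path) as fh:
        lineno = 0
        first = None
        for line in fh:
            lineno += 1
            if line.strip():
                first = line
                break
        if first is None:
            raise FormatError(path, max(lineno, 1), "empty FASTA file")
        if not first.startswith(">"):
            raise FormatError(path, lineno, "malformed FASTA: expected '>' header")
        seen: set[str] = set()
        for title, seq in SimpleFastaParser(itertools.chain([first], fh)):
            fields = title.split(maxsplit=1)
            if not fields:
                raise FormatError(path, None, "FASTA record with empty header")
            rid = fields[0]
            desc = fields[1] if len(fields) > 1 else ""
            if not seq:
                raise FormatError(path, None, f"record {rid!r} has an empty sequence")
            if rid in seen:
                raise FormatError(path, None, f"duplicate record id {rid!r}")
            seen.add(rid)
            yield SeqRecord(rid, desc, normalize_sequence(seq, context=f"{path}:{rid}"))


def write_fasta(records: Iterable[SeqRecord], path, *, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _fastq_stream(path) -> Iterator[ReadRecord]:
    with _open_text(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield ReadRecord(title.split()[0], seq.upper(), qual)
        except ValueError as exc:  # biopython's structural checks
            raise FormatError(path, None, str(exc)) from exc


def _interleave(a: Iterator[ReadRecord], b: Iterator[ReadRecord]) -> Iterator[ReadRecord]:
    for r1, r2 in itertools.zip_longest(a, b):
        if r1 is not None:
            yield r1
        if r2 is not None:
            yield r2


def read_fastq(path, mate_path=None, *, limit: int | None = None) -> Iterator[ReadRecord]:
    """Stream reads from FASTQ, yielding at most ``limit`` reads.

    With a ``mate_path`` the two files are interleaved mate-by-mate and each
    mate counts as one read — the pipeline only ever counts per-read hits,
    so no mate-pair constraint is kept.
    """
    stream = _fastq_stream(path)
    if mate_path is not None:
        stream = _interleave(stream, _fastq_stream(mate_path))
    if limit is not None:
        if limit < 0:
            raise ValueError("limit must be >= 0")
        stream = itertools.islice(stream, limit)
    return stream


def write_fastq(reads: Iterable[ReadRecord], path, *, compress: bool | None = None) -> int:
    """Write reads as FASTQ; gzip when ``compress`` (or the path ends .gz)."""
    path = Path(path)
    if compress is None:
        compress = path.suffix == ".gz"
    opener = gzip.open if compress else open
    n = 0
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")
            n += 1
    return n


# --------------------------------------------------------------------------
# BED
# --------------------------------------------------------------------------


class BedInterval(NamedTuple):
    """A BED interval converted to 1-based inclusive coordinates."""

    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    name: str = ""


def read_bed(path) -> list[BedInterval]:
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(path, lineno, "BED line with fewer than 3 columns")
            try:
                start0, end0 = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(path, lineno, f"non-integer BED coordinate: {exc}") from exc
            if end0 <= start0:
                raise FormatError(path, lineno, "BED end must be > start")
            name = cols[3] if len(cols) >= 4 else ""
            out.append(BedInterval(cols[0], start0 + 1, end0, name))
    return out


def write_bed(intervals: Iterable[BedInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start - 1), str(iv.end)]
            if iv.name:
                fields.append(iv.name)
            fh.write("\t".join(fields) + "\n")


# --------------------------------------------------------------------------
# marker-FASTA dialect
# --------------------------------------------------------------------------


class Member(Enum):
    """Which side of a gametolog pair a sequence comes from.

    RECESSIVE is the shared chromosome (X or Z), DOMINANT the sex-limited
    one (Y or W).  The serialized letter is always X/Y; Z/W are accepted on
    parse so avian marker files read back identically.
    """

    RECESSIVE = "X"
    DOMINANT = "Y"


_MEMBER_LETTERS = {"X": Member.RECESSIVE, "Z": Member.RECESSIVE,
                   "Y": Member.DOMINANT, "W": Member.DOMINANT}


@dataclass(frozen=True)
class MarkerHeader:
    """Parsed marker-FASTA header for one member of a marker pair.

    ``length`` counts alignment columns and ``mismatches`` non-identical
    columns; for substitution-only markers ``end - start + 1 == length``.
    """

    pair_id: str
    member: Member
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    gene: str
    length: int
    mismatches: int

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"{self.pair_id}: end {self.end} < start {self.start}")


_HEADER_RE = re.compile(
    r"^(?P<pair>[^|]+)\|(?P<member>[XYZW])\|(?P<chrom>[^|:]+):(?P<start>\d+)-(?P<end>\d+)"
    r"\|(?P<gene>[^|]*)\|len=(?P<len>\d+)\|mm=(?P<mm>\d+)$"
)


def format_marker_header(h: MarkerHeader) -> str:
    return (
        f"{h.pair_id}|{h.member.value}|{h.chrom}:{h.start}-{h.end}"
        f"|{h.gene}|len={h.length}|mm={h.mismatches}"
    )


def parse_marker_header(text: str) -> MarkerHeader:
    m = _HEADER_RE.match(text.strip())
    if m is None:
        raise FormatError("<marker header>", None, f"unparseable marker header: {text!r}")
    return MarkerHeader(
        pair_id=m.group("pair"),
        member=_MEMBER_LETTERS[m.group("member")],
        chrom=m.group("chrom"),
        start=int(m.group("start")),
        end=int(m.group("end")),
        gene=m.group("gene"),
        length=int(m.group("len")),
        mismatches=int(m.group("mm")),
    )


def write_marker_fasta(pairs: Sequence, path) -> None:
    """Serialize marker pairs: two FASTA records per pair (X then Y member).

    ``pairs`` are :class:`sexmark.markers.MarkerPair` objects (duck-typed:
    anything with header_x/header_y/seq_x/seq_y).  Round-trips losslessly
    through :func:`parse_marker_header`.
    """
    if not pairs:
        raise ValueError("refusing to write an empty marker set")
    recs = []
    for p in pairs:
        recs.append(SeqRecord(format_marker_header(p.header_x), "", p.seq_x))
        recs.append(SeqRecord(format_marker_header(p.header_y), "", p.seq_y))
    write_fasta(recs, path)


def read_marker_fasta(path) -> list[tuple[MarkerHeader, str]]:
    """Read the marker dialect back as (header, sequence) in file order."""
    out = []
    for rec in read_fasta(path):
        header = rec.id if not rec.description else f"{rec.id} {rec.description}"
        out.append((parse_marker_header(header), rec.sequence))
    return out


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------

REPORT_COLUMNS = (
    "sample_id",
    "reads_used",
    "hits_recessive",
    "hits_dominant",
    "total_hits",
    "fraction_dominant",
    "call",
    "sex_label",
    "status",
)


def write_report(calls: Sequence, path) -> None:
    """Write the per-sample TSV report (one row per SexCall, 4-dp fraction)."""
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for c in calls:
            total = c.hits_recessive + c.hits_dominant
            row = (
                c.sample_id,
                str(c.reads_used),
                str(c.hits_recessive),
                str(c.hits_dominant),
                str(total),
                f"{c.fraction_dominant:.4f}",
                c.call.name,
                c.sex_label,
                c.status,
            )
            fh.write("\t".join(row) + "\n")
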