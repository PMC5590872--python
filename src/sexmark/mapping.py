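"""A small k-mer-seeded read mapper for the marker set.

The reference is tiny (tens of sequences, a few hundred bp each), so the
mapper indexes every k-mer of both strands of both members of every pair
and scores each candidate (member, strand, diagonal) by gapless alignment
over the overlapping span: match +1, mismatch -1.  A read hits the best
candidate when its alignment identity is at least ``map_identity_min`` over
the aligned span and the span covers at least 80% of min(read length,
marker length).  Equal best scores on both members of a pair — or across
pairs — make the read AMBIGUOUS, and ambiguous reads are discarded rather
than assigned (arbitrary tie assignment would manufacture spurious
dominant-chromosome hits in homogametic samples).

Two code paths produce identical assignments: :func:`map_read` is the
plain-Python reference, and :func:`count_hits` runs a numba batch kernel
over encoded reads (a test asserts their equivalence).  A read spanning an
indel shows up as two seed diagonals and is scored per diagonal; the
better gapless diagonal wins or the read stays unmapped.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

import numpy as np
from numba import njit

from .markers import MarkerPair, PipelineParams
from .seqio import Member, ReadRecord
from .synteny import Strand, encode_dna, kmer_codes, revcomp

logger = logging.getLogger("sexmark.mapping")

__all__ = [
    "MarkerIndex",
    "HitTable",
    "AssignmentStatus",
    "ReadAssignment",
    "build_marker_index",
    "map_read",
    "count_hits",
]

SPAN_FRACTION = 0.8  # aligned span must cover this much of min(|read|, |marker|)
_EPS = 1e-9  # inclusive float thresholds (0.9 * span is not exact in binary)


class AssignmentStatus(Enum):
    HIT = "hit"
    AMBIGUOUS = "ambiguous"
    UNMAPPED = "unmapped"


@dataclass(frozen=True)
class ReadAssignment:
    status: AssignmentStatus
    pair_id: str | None = None
    member: Member | None = None
    score: int | None = None


UNMAPPED = ReadAssignment(AssignmentStatus.UNMAPPED)
AMBIGUOUS = ReadAssignment(AssignmentStatus.AMBIGUOUS)


@dataclass
class MarkerIndex:
    """k-mer lookup over both strands of both members of every pair.

    ``lookup`` maps a k-mer string to ``(pair_id, member, offset, strand)``
    postings, where ``offset`` is 0-based on the member's forward sequence
    for FWD postings and on its reverse complement for REV postings.
    Member number ``2*i`` is the X/Z member of pair ``i`` and ``2*i + 1``
    its Y/W member; the packed arrays are the batch kernel's view of the
    same data.
    """

    k: int
    lookup: dict[str, list[tuple[str, Member, int, Strand]]]
    markers: list[MarkerPair]
    # packed arrays for the batch kernel
    _mseq: np.ndarray = field(repr=False, default=None)
    _m_fwd: np.ndarray = field(repr=False, default=None)
    _m_rev: np.ndarray = field(repr=False, default=None)
    _m_len: np.ndarray = field(repr=False, default=None)
    _pcodes: np.ndarray = field(repr=False, default=None)
    _pmember: np.ndarray = field(repr=False, default=None)
    _porient: np.ndarray = field(repr=False, default=None)
    _poffset: np.ndarray = field(repr=False, default=None)

    @property
    def n_members(self) -> int:
        return 2 * len(self.markers)

    def member_info(self, number: int) -> tuple[str, Member]:
        pair = self.markers[number // 2]
        member = Member.RECESSIVE if number % 2 == 0 else Member.DOMINANT
        return pair.pair_id, member

    def member_seq(self, number: int, strand: Strand) -> str:
        pair = self.markers[number // 2]
        seq = pair.seq_x if number % 2 == 0 else pair.seq_y
        return seq if strand is Strand.FWD else revcomp(seq)


def build_marker_index(pairs: Sequence[MarkerPair], k: int = 15) -> MarkerIndex:
    """Index every N-free k-mer of both strands of all marker members."""
    if not pairs:
        raise ValueError("no markers: cannot build an index")
    lookup: dict[str, list[tuple[str, Member, int, Strand]]] = {}
    codes_parts, member_parts, orient_parts, offset_parts = [], [], [], []
    seq_parts: list[np.ndarray] = []
    m_fwd = np.zeros(2 * len(pairs), np.int64)
    m_rev = np.zeros(2 * len(pairs), np.int64)
    m_len = np.zeros(2 * len(pairs), np.int64)
    pos = 0
    for i, pair in enumerate(pairs):
        for m, (member, seq) in enumerate(
            ((Member.RECESSIVE, pair.seq_x), (Member.DOMINANT, pair.seq_y))
        ):
            number = 2 * i + m
            rc = revcomp(seq)
            m_len[number] = len(seq)
            for orient, s in ((0, seq), (1, rc)):
                arr = encode_dna(s)
                if orient == 0:
                    m_fwd[number] = pos
                else:
                    m_rev[number] = pos
                seq_parts.append(arr)
                pos += len(arr)
                codes, valid = kmer_codes(arr, k)
                vpos = np.flatnonzero(valid)
                codes_parts.append(codes[vpos])
                member_parts.append(np.full(len(vpos), number, np.int64))
                orient_parts.append(np.full(len(vpos), orient, np.int64))
                offset_parts.append(vpos.astype(np.int64))
                strand = Strand.FWD if orient == 0 else Strand.REV
                for off in vpos:
                    kmer = s[off : off + k]
                    lookup.setdefault(kmer, []).append(
                        (pair.pair_id, member, int(off), strand)
                    )
    codes = np.concatenate(codes_parts)
    order = np.argsort(codes, kind="stable")
    index = MarkerIndex(
        k=k,
        lookup=lookup,
        markers=list(pairs),
        _mseq=np.concatenate(seq_parts),
        _m_fwd=m_fwd,
        _m_rev=m_rev,
        _m_len=m_len,
        _pcodes=codes[order],
        _pmember=np.concatenate(member_parts)[order],
        _porient=np.concatenate(orient_parts)[order],
        _poffset=np.concatenate(offset_parts)[order],
    )
    logger.info("indexed %d marker pairs: %d postings, k=%d",
                len(pairs), len(index._pcodes), k)
    return index


# --------------------------------------------------------------------------
# reference (per-read, pure Python) path
# --------------------------------------------------------------------------


def map_read(read: ReadRecord, index: MarkerIndex, params: PipelineParams) -> ReadAssignment:
    """Assign one read to a marker member, AMBIGUOUS, or UNMAPPED."""
    seq = read.sequence.upper()
    lr = len(seq)
    k = index.k
    if lr < k:
        return UNMAPPED
    cands: dict[tuple[int, int, int], None] = {}
    for p in range(lr - k + 1):
        for pair_id, member, off, strand in index.lookup.get(seq[p : p + k], ()):
            number = next(
                2 * i + (0 if member is Member.RECESSIVE else 1)
                for i, mp in enumerate(index.markers)
                if mp.pair_id == pair_id
            )
            cands[(number, 0 if strand is Strand.FWD else 1, off - p)] = None
    if not cands:
        return UNMAPPED
    best_score = None
    best_number = None
    ambiguous = False
    for number, orient, diag in sorted(cands):
        ms = index.member_seq(number, Strand.FWD if orient == 0 else Strand.REV)
        lm = len(ms)
        r0 = max(0, -diag)
        r1 = min(lr, lm - diag)
        span = r1 - r0
        if span + _EPS < SPAN_FRACTION * min(lr, lm):
            continue
        matches = sum(
            1
            for t in range(r0, r1)
            if seq[t] == ms[t + diag] and seq[t] in "ACGT"
        )
        if matches + _EPS < params.map_identity_min * span:
            continue
        score = 2 * matches - span
        if best_score is None or score > best_score:
            best_score, best_number, ambiguous = score, number, False
        elif score == best_score and number != best_number:
            ambiguous = True
    if best_number is None:
        return UNMAPPED
    if ambiguous:
        return AMBIGUOUS
    pair_id, member = index.member_info(best_number)
    return ReadAssignment(AssignmentStatus.HIT, pair_id, member, best_score)


# --------------------------------------------------------------------------
# batch kernel path
# --------------------------------------------------------------------------

_MAXC = 256  # candidate (member, orient, diagonal) slots per read


@njit(cache=True)
def _map_batch(buf, offs, k, pcodes, pmember, porient, poffset,
               mseq, m_fwd, m_rev, m_len, min_ident, span_frac, out):
    nreads = offs.shape[0] - 1
    npost = pcodes.shape[0]
    mask = (np.int64(1) << (2 * k)) - 1
    cm = np.empty(_MAXC, np.int64)
    co = np.empty(_MAXC, np.int64)
    cd = np.empty(_MAXC, np.int64)
    for r in range(nreads):
        s = offs[r]
        lr = offs[r + 1] - s
        out[r] = -1
        if lr < k:
            continue
        ncand = 0
        code = np.int64(0)
        valid_run = 0
        for i in range(lr):
            b = buf[s + i]
            if b > 3:
                valid_run = 0
                code = np.int64(0)
                continue
            code = ((code << 2) | np.int64(b)) & mask
            valid_run += 1
            if valid_run < k:
                continue
            p = i - k + 1
            lo = np.searchsorted(pcodes, code)
            while lo < npost and pcodes[lo] == code:
                m = pmember[lo]
                o = porient[lo]
                d = poffset[lo] - p
                seen = False
                for c in range(ncand):
                    if cm[c] == m and co[c] == o and cd[c] == d:
                        seen = True
                        break
                if not seen and ncand < _MAXC:
                    cm[ncand] = m
                    co[ncand] = o
                    cd[ncand] = d
                    ncand += 1
                lo += 1
        if ncand == 0:
            continue
        best = np.int64(-(10**9))
        best_m = np.int64(-1)
        ambig = False
        for c in range(ncand):
            m = cm[c]
            d = cd[c]
            base = m_fwd[m] if co[c] == 0 else m_rev[m]
            lm = m_len[m]
            r0 = -d if d < 0 else 0
            r1 = lr if lm - d > lr else lm - d
            span = r1 - r0
            minlen = lr if lr < lm else lm
            if span + 1e-9 < span_frac * minlen:
                continue
            matches = 0
            for t in range(r0, r1):
                rb = buf[s + t]
                if rb <= 3 and rb == mseq[base + t + d]:
                    matches += 1
            if matches + 1e-9 < min_ident * span:
                continue
            score = 2 * matches - span
            if score > best:
                best = score
                best_m = m
                ambig = False
            elif score == best and best_m != m:
                ambig = True
        if best_m < 0:
            out[r] = -1
        elif ambig:
            out[r] = -2
        else:
            out[r] = best_m


# --------------------------------------------------------------------------
# hit counting
# --------------------------------------------------------------------------


@dataclass
class HitTable:
    """Per-member hit counts and read dispositions for one sample.

    Conservation invariant: hits_recessive + hits_dominant +
    reads_ambiguous + reads_unmapped == reads_processed.
    """

    counts: dict[tuple[str, Member], int]
    hits_recessive: int
    hits_dominant: int
    reads_processed: int
    reads_ambiguous: int
    reads_unmapped: int

    @property
    def total_hits(self) -> int:
        return self.hits_recessive + self.hits_dominant

    def validate(self) -> None:
        assert all(v >= 0 for v in self.counts.values())
        assert (
            self.hits_recessive + self.hits_dominant
            + self.reads_ambiguous + self.reads_unmapped
            == self.reads_processed
        ), "read dispositions do not sum to reads_processed"
        assert sum(v for (_, m), v in self.counts.items() if m is Member.RECESSIVE) \
            == self.hits_recessive
        assert sum(v for (_, m), v in self.counts.items() if m is Member.DOMINANT) \
            == self.hits_dominant


def _chunks(it: Iterator[ReadRecord], size: int) -> Iterator[list[ReadRecord]]:
    while True:
        chunk = list(itertools.islice(it, size))
        if not chunk:
            return
        yield chunk


def count_hits(
    reads: Iterable[ReadRecord],
    index: MarkerIndex,
    max_reads: int | None = None,
    params: PipelineParams | None = None,
    *,
    engine: str = "batch",
    batch_size: int = 65_536,
) -> HitTable:
    """Map the first ``max_reads`` reads and accumulate a HitTable.

    ``engine="batch"`` (default) runs the numba kernel over encoded read
    batches; ``engine="python"`` applies :func:`map_read` per read.  The
    two produce identical tables.
    """
    if params is None:
        params = PipelineParams()
    stream: Iterator[ReadRecord] = iter(reads)
    if max_reads is not None:
        stream = itertools.islice(stream, max_reads)
    per_member = np.zeros(index.n_members, np.int64)
    processed = ambiguous = unmapped = 0
    if engine == "python":
        for read in stream:
            processed += 1
            res = map_read(read, index, params)
            if res.status is AssignmentStatus.UNMAPPED:
                unmapped += 1
            elif res.status is AssignmentStatus.AMBIGUOUS:
                ambiguous += 1
            else:
                number = 2 * next(
                    i for i, mp in enumerate(index.markers) if mp.pair_id == res.pair_id
                ) + (0 if res.member is Member.RECESSIVE else 1)
                per_member[number] += 1
    elif engine == "batch":
        from .synteny import _LUT  # byte -> 2-bit lookup shared with the aligner

        for chunk in _chunks(stream, batch_size):
            joined = "".join(r.sequence for r in chunk).encode("latin-1")
            buf = _LUT[np.frombuffer(joined, dtype=np.uint8)]
            lens = np.fromiter((len(r.sequence) for r in chunk), np.int64, len(chunk))
            offs = np.zeros(len(chunk) + 1, np.int64)
            np.cumsum(lens, out=offs[1:])
            out = np.empty(len(chunk), np.int32)
            _map_batch(
                buf, offs, index.k,
                index._pcodes, index._pmember, index._porient, index._poffset,
                index._mseq, index._m_fwd, index._m_rev, index._m_len,
                params.map_identity_min, SPAN_FRACTION, out,
            )
            processed += len(chunk)
            unmapped += int(np.count_nonzero(out == -1))
            ambiguous += int(np.count_nonzero(out == -2))
            hits = out[out >= 0]
            if len(hits):
                np.add.at(per_member, hits, 1)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    counts = {
        index.member_info(n): int(per_member[n]) for n in range(index.n_members)
    }
    table = HitTable(
        counts=counts,
        hits_recessive=int(per_member[0::2].sum()),
        hits_dominant=int(per_member[1::2].sum()),
        reads_processed=processed,
        reads_ambiguous=ambiguous,
        reads_unmapped=unmapped,
    )
    table.validate()
    return table
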