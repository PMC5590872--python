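"""Synthetic genomes and reads with known ground truth.

The generator emulates the genomic structure the marker pipeline relies
on: a pair of sex chromosomes sharing a handful of syntenic gametolog
segments at controlled substitution divergence — with every identical run
inside a segment kept shorter than a read, as in real recombination-
suppressed gametolog pairs the method targets — embedded in mutually
non-homologous flanking sequence, plus optional autosomes that may carry
verbatim copies of chosen segments (paralog decoys for the uniqueness
screen).  Reads are drawn from a chosen karyotype (XX/XY or ZZ/ZW) with
uniform (WGS-like) or interval-restricted (exome/transcriptome-like)
coverage, strand-symmetric, with i.i.d. substitution errors and constant
Q30 qualities.

Everything is reproducible from the seed, and :class:`SimTruth` records
segment intervals and realized mutation positions so tests can compare
pipeline output against planted truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .seqio import BedInterval, ReadRecord, SeqRecord
from .synteny import encode_dna, kmer_codes, revcomp

logger = logging.getLogger("sexmark.simdata")

__all__ = [
    "SimGenomeSpec",
    "SimSegment",
    "SimTruth",
    "SimGenome",
    "simulate_genome",
    "simulate_reads",
    "KARYOTYPES",
]

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
KARYOTYPES = ("XX", "XY", "ZZ", "ZW")
HETEROGAMETIC_KARYOTYPES = ("XY", "ZW")

_QUAL30 = "?"  # Phred+33 for Q30; scoring ignores qualities, so constant


@dataclass(frozen=True)
class SimGenomeSpec:
    """Study conditions for one synthetic genome.

    Defaults describe the benchmark condition used throughout: a 10 Mb
    chromosome pair with 12 gametolog segments of 200-400 bp at 5-15%
    substitution divergence, identical runs capped below the 35 bp rule.
    """

    chrom_len: int = 10_000_000
    n_gametolog_segments: int = 12
    segment_len_range: tuple[int, int] = (200, 400)
    divergence_range: tuple[float, float] = (0.05, 0.15)
    max_identical_run: int = 34
    n_autosomes: int = 0
    autosome_len: int = 1_000_000
    planted_paralog_ids: tuple[int, ...] = ()
    indel_rate: float = 0.0  # per-base single-base indel rate inside segments
    seed: int = 42
    min_flank_gap: int = 2_000
    kmer_check_k: int = 15
    max_redraw_rounds: int = 25

    def __post_init__(self):
        lo, hi = self.segment_len_range
        dlo, dhi = self.divergence_range
        if not (0 < lo <= hi):
            raise ValueError("segment_len_range must be positive and ordered")
        if not (0.0 < dlo <= dhi < 1.0):
            raise ValueError("divergence_range must lie in (0, 1) and be ordered")
        if lo < 151:
            raise ValueError("segments must be at least one marker length (151 bp)")
        if dlo * lo < 5:
            raise ValueError("divergence * segment length must allow >= 5 mismatches")
        if self.max_identical_run < 1:
            raise ValueError("max_identical_run must be positive")
        need = (
            self.n_gametolog_segments * hi
            + (self.n_gametolog_segments + 1) * self.min_flank_gap
        )
        if self.chrom_len < need:
            raise ValueError(
                f"chrom_len {self.chrom_len} too small for "
                f"{self.n_gametolog_segments} segments plus flank gaps ({need})"
            )
        if self.planted_paralog_ids:
            if self.n_autosomes < 1:
                raise ValueError("planted paralogs need at least one autosome")
            if any(not 0 <= i < self.n_gametolog_segments for i in self.planted_paralog_ids):
                raise ValueError("planted_paralog_ids out of range")


@dataclass
class SimSegment:
    """Planted gametolog segment: intervals (1-based inclusive) and truth."""

    index: int
    x_start: int
    x_end: int
    y_start: int
    y_end: int
    divergence: float
    mutations: list[int]  # 0-based offsets within the segment (X coordinates)
    n_indels: int = 0


@dataclass
class SimSample:
    sample_id: str
    karyotype: str
    n_reads: int
    read_len: int
    error_rate: float
    mode: str
    seed: int


@dataclass
class SimTruth:
    """Ground truth: planted segments plus the samples drawn from them."""

    segments: list[SimSegment]
    samples: list[SimSample] = field(default_factory=list)

    def x_intervals(self) -> list[tuple[int, int]]:
        return [(s.x_start, s.x_end) for s in self.segments]

    def y_intervals(self) -> list[tuple[int, int]]:
        return [(s.y_start, s.y_end) for s in self.segments]

    def target_intervals(self) -> dict[str, list[tuple[int, int]]]:
        """Per-chromosome target intervals for TARGETED read simulation."""
        return {"X": self.x_intervals(), "Y": self.y_intervals()}

    def segments_bed(self, x_chrom: str, y_chrom: str) -> list[BedInterval]:
        out = []
        for s in self.segments:
            out.append(BedInterval(x_chrom, s.x_start, s.x_end, f"segment{s.index:02d}"))
            out.append(BedInterval(y_chrom, s.y_start, s.y_end, f"segment{s.index:02d}"))
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "segments": [asdict(s) for s in self.segments],
                "samples": [asdict(s) for s in self.samples],
            },
            indent=1,
        )


@dataclass
class SimGenome:
    seq_x: SeqRecord
    seq_y: SeqRecord
    autosomes: list[SeqRecord]
    truth: SimTruth


def _array_to_seq(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def _layout(rng, total_len, seg_lens, min_gap) -> list[int]:
    """Segment start offsets: random gaps >= min_gap around each segment."""
    n = len(seg_lens)
    free = total_len - int(seg_lens.sum()) - (n + 1) * min_gap
    extra = rng.multinomial(free, [1.0 / (n + 1)] * (n + 1))
    starts = []
    pos = 0
    for i in range(n):
        pos += min_gap + int(extra[i])
        starts.append(pos)
        pos += int(seg_lens[i])
    return starts


def _place_mutations(rng, length, divergence, max_run, min_mut=5) -> np.ndarray:
    """Mutation offsets: binomial count at the drawn divergence, then extra
    mutations inserted mid-run until no identical run (ends included)
    exceeds ``max_run``."""
    n_mut = max(min_mut, int(rng.binomial(length, divergence)))
    n_mut = min(n_mut, length)
    pos = set(int(p) for p in rng.choice(length, size=n_mut, replace=False))
    while True:
        bounds = [-1] + sorted(pos) + [length]
        gaps = [
            (bounds[i + 1] - bounds[i] - 1, bounds[i])
            for i in range(len(bounds) - 1)
        ]
        bad = [(g, left) for g, left in gaps if g > max_run]
        if not bad:
            break
        for g, left in bad:
            pos.add(left + 1 + g // 2)
    return np.array(sorted(pos), dtype=np.int64)


def _mutate(rng, seg: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    out = seg.copy()
    shift = rng.integers(1, 4, size=len(offsets))
    out[offsets] = (out[offsets] + shift) % 4
    return out


def _apply_indels(rng, seg: np.ndarray, n_indels: int) -> np.ndarray:
    """Scatter single-base insertions/deletions through a mutated segment."""
    out = seg
    for _ in range(n_indels):
        p = int(rng.integers(0, len(out)))
        if rng.integers(0, 2) == 0 and len(out) > 1:
            out = np.delete(out, p)
        else:
            out = np.insert(out, p, rng.integers(0, 4))
    return out


def _shared_kmer_windows(
    y: np.ndarray, x_codes_sorted: np.ndarray, k: int
) -> np.ndarray:
    """Start offsets of Y windows whose k-mer (either strand) occurs in X."""
    if len(x_codes_sorted) == 0:
        return np.empty(0, np.int64)
    hits = []
    cy, vy = kmer_codes(y, k)
    idx = np.flatnonzero(vy)
    if len(idx):
        found = np.searchsorted(x_codes_sorted, cy[idx])
        found = np.minimum(found, len(x_codes_sorted) - 1)
        hits.append(idx[x_codes_sorted[found] == cy[idx]])
    yr = (3 - y) % 4
    yr[y >= 4] = 4
    yr = yr[::-1]
    cr, vr = kmer_codes(yr, k)
    idx = np.flatnonzero(vr)
    if len(idx):
        found = np.searchsorted(x_codes_sorted, cr[idx])
        found = np.minimum(found, len(x_codes_sorted) - 1)
        rc_hits = idx[x_codes_sorted[found] == cr[idx]]
        # convert reverse-complement window starts to forward coordinates
        hits.append(len(y) - k - rc_hits)
    if not hits:
        return np.empty(0, np.int64)
    return np.unique(np.concatenate(hits))


def _windows_share_kmer(
    y: np.ndarray, starts: np.ndarray, x_codes_sorted: np.ndarray, k: int
) -> np.ndarray:
    """Per-window: does its k-mer (either strand) occur in X?  Gather-based,
    for rechecking a sparse set of windows."""
    if len(starts) == 0 or len(x_codes_sorted) == 0:
        return np.zeros(len(starts), bool)
    w = y[starts[:, None] + np.arange(k)[None, :]].astype(np.int64)
    powers = np.int64(4) ** np.arange(k - 1, -1, -1)
    cf = w @ powers
    cr = (3 - w)[:, ::-1] @ powers
    valid = (w < 4).all(axis=1)

    def _in_x(codes: np.ndarray) -> np.ndarray:
        pos = np.minimum(
            np.searchsorted(x_codes_sorted, codes), len(x_codes_sorted) - 1
        )
        return x_codes_sorted[pos] == codes

    return valid & (_in_x(cf) | _in_x(cr))


def simulate_genome(spec: SimGenomeSpec) -> SimGenome:
    """Build the chromosome pair, autosomes, and ground truth from a spec.

    The Y/W chromosome carries substitution-mutated copies of the X/Z
    segments at independently drawn positions (same order, preserving
    synteny); all non-segment Y/W sequence is independent random DNA,
    iteratively re-drawn until it shares no ``kmer_check_k``-mer with the
    X/Z chromosome on either strand (bounded by ``max_redraw_rounds``; a
    warning is logged if any chance collisions survive the cap).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_gametolog_segments
    x = rng.integers(0, 4, spec.chrom_len, dtype=np.uint8)
    seg_lens = rng.integers(
        spec.segment_len_range[0], spec.segment_len_range[1] + 1, n
    )
    x_starts = _layout(rng, spec.chrom_len, seg_lens, spec.min_flank_gap)
    y_gap_extra = rng.multinomial(
        spec.chrom_len - int(seg_lens.sum()) - (n + 1) * spec.min_flank_gap,
        [1.0 / (n + 1)] * (n + 1),
    )
    # assemble Y part by part so indels cannot desynchronize coordinates
    parts: list[np.ndarray] = []
    segments: list[SimSegment] = []
    y_pos = 0
    for i in range(n):
        gap = spec.min_flank_gap + int(y_gap_extra[i])
        parts.append(rng.integers(0, 4, gap, dtype=np.uint8))
        y_pos += gap
        ln = int(seg_lens[i])
        d = float(rng.uniform(*spec.divergence_range))
        offsets = _place_mutations(rng, ln, d, spec.max_identical_run)
        xs = x_starts[i]
        seg = _mutate(rng, x[xs : xs + ln], offsets)
        n_ind = 0
        if spec.indel_rate > 0:
            n_ind = int(rng.binomial(ln, spec.indel_rate))
            seg = _apply_indels(rng, seg, n_ind)
        parts.append(seg)
        segments.append(
            SimSegment(
                index=i,
                x_start=xs + 1,
                x_end=xs + ln,
                y_start=y_pos + 1,
                y_end=y_pos + len(seg),
                divergence=d,
                mutations=[int(o) for o in offsets],
                n_indels=n_ind,
            )
        )
        y_pos += len(seg)
    tail = spec.min_flank_gap + int(y_gap_extra[n])
    parts.append(rng.integers(0, 4, tail, dtype=np.uint8))
    y = np.concatenate(parts)

    # enforce the unrelated-flank property: no shared k-mer outside segments
    k = spec.kmer_check_k
    cx, vx = kmer_codes(x, k)
    x_codes_sorted = np.sort(cx[np.flatnonzero(vx)])
    in_segment = np.zeros(len(y) + 1, np.int64)
    for s in segments:
        in_segment[s.y_start - 1] += 1
        in_segment[s.y_end] -= 1
    in_segment = np.cumsum(in_segment[:-1])
    seg_cum = np.concatenate(([0], np.cumsum(in_segment > 0)))

    def _outside(starts: np.ndarray) -> np.ndarray:
        return starts[(seg_cum[starts + k] - seg_cum[starts]) == 0]

    # full scan once, then recheck only the neighbourhoods of redrawn
    # windows (each re-draw can only create/destroy k-mers within k-1
    # bases of itself)
    shared = _outside(_shared_kmer_windows(y, x_codes_sorted, k))
    rounds = 0
    while len(shared) and rounds < spec.max_redraw_rounds:
        for p in shared:
            y[p : p + k] = rng.integers(0, 4, k, dtype=np.uint8)
        rounds += 1
        cand = (shared[:, None] + np.arange(-k + 1, k)[None, :]).ravel()
        cand = np.unique(np.clip(cand, 0, len(y) - k))
        shared = _outside(cand[_windows_share_kmer(y, cand, x_codes_sorted, k)])
    if len(shared):
        logger.warning(
            "flank re-draw cap reached with %d shared %d-mer window(s) left",
            len(shared), k,
        )

    autosomes = []
    for a in range(spec.n_autosomes):
        autosomes.append(rng.integers(0, 4, spec.autosome_len, dtype=np.uint8))
    for pid in spec.planted_paralog_ids:
        s = segments[pid]
        target = autosomes[pid % spec.n_autosomes]
        copy = x[s.x_start - 1 : s.x_end]
        at = int(rng.integers(0, len(target) - len(copy)))
        target[at : at + len(copy)] = copy

    truth = SimTruth(segments=segments)
    logger.info(
        "simulated genome: %d bp per chromosome, %d segments, %d autosome(s)",
        spec.chrom_len, n, spec.n_autosomes,
    )
    return SimGenome(
        seq_x=SeqRecord("simX", "synthetic X/Z chromosome", _array_to_seq(x)),
        seq_y=SeqRecord("simY", "synthetic Y/W chromosome", _array_to_seq(y)),
        autosomes=[
            SeqRecord(f"simA{i + 1}", "synthetic autosome", _array_to_seq(a))
            for i, a in enumerate(autosomes)
        ],
        truth=truth,
    )


# --------------------------------------------------------------------------
# reads
# --------------------------------------------------------------------------

_ERR_SHIFT = "ACGT"


def _interval_sampler(intervals: Sequence[tuple[int, int]], read_len: int, chrom_len: int):
    """Start-position ranges (0-based) and weights for targeted sampling."""
    ranges = []
    weights = []
    for s, e in intervals:
        lo = s - 1
        hi = min(e - read_len, chrom_len - read_len)
        if hi < lo:
            lo = hi = max(0, min(lo, chrom_len - read_len))
        ranges.append((lo, hi))
        weights.append(hi - lo + 1)
    w = np.asarray(weights, float)
    return ranges, w / w.sum()


def simulate_reads(
    seq_x: SeqRecord,
    seq_y: SeqRecord,
    karyotype: str,
    n_reads: int,
    read_len: int = 100,
    error_rate: float = 0.01,
    mode: str = "WGS",
    target_intervals: dict[str, Sequence[tuple[int, int]]] | None = None,
    seed: int = 0,
    sample_id: str = "sample",
    _batch: int = 100_000,
) -> Iterator[ReadRecord]:
    """Stream reads from one diploid sample of the given karyotype.

    Heterogametic karyotypes (XY, ZW) draw each read 50/50 from the X/Z or
    Y/W copy; homogametic ones (XX, ZZ) use two X/Z copies.  WGS mode uses
    uniform start positions; TARGETED mode restricts starts to
    ``target_intervals`` (keys "X" and "Y", 1-based inclusive), emulating
    exome/transcriptome enrichment.  Substitution errors are i.i.d. at
    ``error_rate``; qualities are constant Q30; strands are symmetric.
    """
    if karyotype not in KARYOTYPES:
        raise ValueError(f"karyotype must be one of {KARYOTYPES}")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    hetero = karyotype in HETEROGAMETIC_KARYOTYPES
    copies = (seq_x.sequence, seq_y.sequence if hetero else seq_x.sequence)
    if read_len > min(len(c) for c in copies):
        raise ValueError("read_len exceeds chromosome length")
    rcs = (revcomp(copies[0]), revcomp(copies[1]))
    lens = (len(copies[0]), len(copies[1]))
    mode = mode.upper()
    if mode not in ("WGS", "TARGETED"):
        raise ValueError("mode must be WGS or TARGETED")
    samplers = None
    if mode == "TARGETED":
        if not target_intervals:
            raise ValueError("TARGETED mode needs non-empty target_intervals")
        iv_x = list(target_intervals.get("X", ()))
        iv_y = list(target_intervals.get("Y", ())) if hetero else iv_x
        if not iv_x or (hetero and not iv_y):
            raise ValueError("TARGETED mode needs intervals for every chromosome copy")
        samplers = (
            _interval_sampler(iv_x, read_len, lens[0]),
            _interval_sampler(iv_y if hetero else iv_x, read_len, lens[1]),
        )
    rng = np.random.default_rng(seed)
    emitted = 0
    qual = _QUAL30 * read_len
    while emitted < n_reads:
        b = min(_batch, n_reads - emitted)
        which = rng.integers(0, 2, b)
        strands = rng.integers(0, 2, b)
        if mode == "WGS":
            u = rng.random(b)
            starts = np.empty(b, np.int64)
            for c in (0, 1):
                m = which == c
                starts[m] = (u[m] * (lens[c] - read_len + 1)).astype(np.int64)
        else:
            starts = np.empty(b, np.int64)
            for c in (0, 1):
                m = which == c
                ranges, probs = samplers[c]
                iv = rng.choice(len(ranges), size=int(m.sum()), p=probs)
                u = rng.random(int(m.sum()))
                lo = np.array([ranges[i][0] for i in iv])
                hi = np.array([ranges[i][1] for i in iv])
                starts[m] = lo + (u * (hi - lo + 1)).astype(np.int64)
        n_err = (
            rng.binomial(read_len, error_rate, b)
            if error_rate > 0
            else np.zeros(b, np.int64)
        )
        for j in range(b):
            c = int(which[j])
            start = int(starts[j])
            if strands[j] == 0:
                s = copies[c][start : start + read_len]
            else:
                rstart = lens[c] - start - read_len
                s = rcs[c][rstart : rstart + read_len]
            ne = int(n_err[j])
            if ne:
                chars = list(s)
                for p in rng.choice(read_len, size=ne, replace=False):
                    old = chars[p]
                    chars[p] = _ERR_SHIFT[
                        (_ERR_SHIFT.find(old) + int(rng.integers(1, 4))) % 4
                    ]
                s = "".join(chars)
            emitted += 1
            yield ReadRecord(f"{sample_id}:{emitted}", s, qual)
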