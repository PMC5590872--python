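"""Syntenic alignment of the two sex chromosomes.

This is the stage a practitioner would delegate to a whole-genome aligner:
gametolog regions shared by the X/Z and Y/W chromosome are located by exact
k-mer seeds, seeds are merged into maximal exact anchors, anchors are
chained collinearly, the short stretches between chained anchors are closed
with an affine-gap global alignment, and block ends are extended through
mismatches with an ungapped X-drop walk (the same recipe BLAST/LASTZ use).
The result is a list of :class:`AlignmentBlock` objects whose per-column
strings (M match / S substitution / I insertion-in-Y / D deletion-in-Y)
feed marker extraction.

Scoring is match +1, mismatch -1, gap -2 per base with an extra -2 to open
(a decision, not a published constant); ties in the dynamic program are
broken M/S > D > I so outputs are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - type-only import, avoids a cycle
    from .markers import PipelineParams
    from .seqio import SeqRecord

logger = logging.getLogger("sexmark.synteny")

__all__ = [
    "Strand",
    "Anchor",
    "AlignmentBlock",
    "encode_dna",
    "revcomp",
    "kmer_codes",
    "find_anchors",
    "chain_anchors",
    "align_gap",
    "align_chromosomes",
]

# ungapped end-extension: BLAST-style X-drop with unit match/mismatch scores
X_DROP = 12
MAX_END_EXTENSION = 300
# k-mers occurring more often than this in the first sequence never seed
# (guards against low-complexity blow-ups; megabase-scale repeat masking is
# out of scope)
MAX_KMER_OCCURRENCES = 64


class Strand(str, Enum):
    FWD = "+"
    REV = "-"


# --------------------------------------------------------------------------
# DNA encoding helpers (shared with the read mapper)
# --------------------------------------------------------------------------

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i

_RC = bytes.maketrans(b"ACGTNacgtn", b"TGCANTGCAN")


def encode_dna(seq: str) -> np.ndarray:
    """2-bit encode a DNA string; anything that is not ACGT becomes 4."""
    return _LUT[np.frombuffer(seq.encode("latin-1"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mer codes of an encoded sequence plus a validity mask.

    ``codes[i]`` packs ``arr[i:i+k]`` two bits per base; ``valid[i]`` is
    False when the window contains a non-ACGT base (those windows never
    seed).
    """
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, bool)
    a = arr.astype(np.int64)
    codes = np.zeros(n, np.int64)
    for j in range(k):
        codes += a[j : j + n] << (2 * (k - 1 - j))
    bad = (arr >= 4).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (cum[k:] - cum[:-k]) == 0
    return codes, valid


# --------------------------------------------------------------------------
# anchors
# --------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Anchor:
    """A maximal exact match between the two sequences.

    ``y_pos`` is always a forward-strand offset on Y; for REV anchors the
    matched Y span is the reverse complement of the X span.
    """

    x_pos: int
    y_pos: int
    length: int
    strand: Strand


def _merge_diagonal_runs(xm: np.ndarray, ym: np.ndarray, k: int) -> list[tuple[int, int, int]]:
    """Collapse per-position k-mer matches into maximal runs per diagonal."""
    diag = xm - ym
    order = np.lexsort((xm, diag))
    d, xs, ys = diag[order], xm[order], ym[order]
    new = np.ones(len(d), bool)
    if len(d) > 1:
        new[1:] = (d[1:] != d[:-1]) | (xs[1:] != xs[:-1] + 1)
    starts = np.flatnonzero(new)
    ends = np.append(starts[1:], len(d))
    return [(int(xs[s]), int(ys[s]), k + int(e - s) - 1) for s, e in zip(starts, ends)]


def _match_oriented(
    sx: str,
    sy_oriented: str,
    scodes: np.ndarray,
    spos: np.ndarray,
    k: int,
) -> list[tuple[int, int, int]]:
    """Maximal exact anchors of sx vs an (already oriented) y string."""
    cy, vy = kmer_codes(encode_dna(sy_oriented), k)
    ypos = np.flatnonzero(vy)
    if len(ypos) == 0 or len(spos) == 0:
        return []
    cyv = cy[ypos]
    lo = np.searchsorted(scodes, cyv, side="left")
    hit = np.flatnonzero(scodes[np.minimum(lo, len(scodes) - 1)] == cyv)
    if len(hit) == 0:
        return []
    lo = lo[hit]
    hi = np.searchsorted(scodes, cyv[hit], side="right")
    cnt = np.minimum(hi - lo, MAX_KMER_OCCURRENCES)
    total = int(cnt.sum())
    yrep = np.repeat(ypos[hit], cnt)
    base = np.repeat(lo, cnt)
    offs = np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
    xm = spos[base + offs]
    runs = _merge_diagonal_runs(xm.astype(np.int64), yrep.astype(np.int64), k)
    # maximal extension left/right (N never matches)
    out = []
    nx, ny = len(sx), len(sy_oriented)
    for x0, y0, ln in runs:
        while x0 > 0 and y0 > 0 and sx[x0 - 1] == sy_oriented[y0 - 1] != "N":
            x0 -= 1
            y0 -= 1
            ln += 1
        while (
            x0 + ln < nx
            and y0 + ln < ny
            and sx[x0 + ln] == sy_oriented[y0 + ln] != "N"
        ):
            ln += 1
        out.append((x0, y0, ln))
    return sorted(set(out))


def find_anchors(seq_x: str, seq_y: str, k: int = 15) -> list[Anchor]:
    """Every maximal shared exact match seeded by a k-mer, both strands.

    Anchors are sorted by (x_pos, y_pos); k-mers containing N never seed.
    """
    if k < 8:
        raise ValueError("seed length k must be >= 8")
    if not seq_x or not seq_y:
        raise ValueError("sequences must be non-empty")
    cx, vx = kmer_codes(encode_dna(seq_x), k)
    xpos = np.flatnonzero(vx)
    anchors: list[Anchor] = []
    if len(xpos):
        cxv = cx[xpos]
        order = np.argsort(cxv, kind="stable")
        scodes, spos = cxv[order], xpos[order]
        for x0, y0, ln in _match_oriented(seq_x, seq_y, scodes, spos, k):
            anchors.append(Anchor(x0, y0, ln, Strand.FWD))
        ry = revcomp(seq_y)
        ny = len(seq_y)
        for x0, y0r, ln in _match_oriented(seq_x, ry, scodes, spos, k):
            anchors.append(Anchor(x0, ny - (y0r + ln), ln, Strand.REV))
    anchors.sort(key=lambda a: (a.x_pos, a.y_pos, a.strand.value))
    return anchors


# --------------------------------------------------------------------------
# chaining
# --------------------------------------------------------------------------


def _gaps(prev: Anchor, nxt: Anchor) -> tuple[int, int]:
    gx = nxt.x_pos - (prev.x_pos + prev.length)
    if prev.strand is Strand.FWD:
        gy = nxt.y_pos - (prev.y_pos + prev.length)
    else:  # forward-y decreasing along the chain
        gy = prev.y_pos - (nxt.y_pos + nxt.length)
    return gx, gy


def chain_anchors(anchors: Sequence[Anchor], max_gap: int = 500) -> list[list[Anchor]]:
    """Partition anchors into disjoint collinear chains.

    Sparse DP with score = sum of anchor lengths; a predecessor must be on
    the same strand, strictly before the successor on both sequences, and
    within ``max_gap`` on each (which also bounds diagonal drift).  Chains
    are extracted best-score-first, so no two chains share an anchor.
    """
    chains: list[list[Anchor]] = []
    for strand in (Strand.FWD, Strand.REV):
        sub = sorted(
            (a for a in anchors if a.strand is strand),
            key=lambda a: (a.x_pos, a.y_pos),
        )
        n = len(sub)
        if n == 0:
            continue
        maxlen = max(a.length for a in sub)
        score = [a.length for a in sub]
        parent = [-1] * n
        for i in range(n):
            ai = sub[i]
            lim = ai.x_pos - max_gap - maxlen
            j = i - 1
            while j >= 0 and sub[j].x_pos >= lim:
                gx, gy = _gaps(sub[j], ai)
                if 0 <= gx <= max_gap and 0 <= gy <= max_gap:
                    cand = score[j] + ai.length
                    if cand > score[i]:
                        score[i] = cand
                        parent[i] = j
                j -= 1
        used = [False] * n
        order = sorted(range(n), key=lambda i: (-score[i], sub[i].x_pos, i))
        for i in order:
            if used[i]:
                continue
            path = []
            cur = i
            while cur != -1 and not used[cur]:
                path.append(cur)
                used[cur] = True
                cur = parent[cur]
            chains.append([sub[c] for c in reversed(path)])
    chains.sort(key=lambda ch: (ch[0].x_pos, ch[0].y_pos))
    return chains


# --------------------------------------------------------------------------
# gap alignment (global, affine)
# --------------------------------------------------------------------------

_NEG = -(10**9)


def align_gap(seq_x_segment: str, seq_y_segment: str) -> str:
    """Globally align two short inter-anchor segments; return a column string.

    Needleman-Wunsch with affine gaps (match +1, mismatch -1, -2 per gap
    base and -2 extra to open); ties broken M/S over D over I.  ``D``
    consumes X only, ``I`` consumes Y only; ``N`` never matches.
    """
    sx, sy = seq_x_segment, seq_y_segment
    n, m = len(sx), len(sy)
    if n == 0:
        return "I" * m
    if m == 0:
        return "D" * n
    # state 0=M (diagonal), 1=D (consume x), 2=I (consume y); backpointers
    # record the predecessor state, chosen in the order M > D > I at ties.
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    D = [[_NEG] * (m + 1) for _ in range(n + 1)]
    I = [[_NEG] * (m + 1) for _ in range(n + 1)]
    BM = [[0] * (m + 1) for _ in range(n + 1)]
    BD = [[0] * (m + 1) for _ in range(n + 1)]
    BI = [[0] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for i in range(1, n + 1):
        D[i][0] = -4 - 2 * (i - 1)
        BD[i][0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        I[0][j] = -4 - 2 * (j - 1)
        BI[0][j] = 0 if j == 1 else 2

    def _pick(vm: int, vd: int, vi: int) -> tuple[int, int]:
        best, state = vm, 0
        if vd > best:
            best, state = vd, 1
        if vi > best:
            best, state = vi, 2
        return best, state

    for i in range(1, n + 1):
        ci = sx[i - 1]
        Mp, Dp, Ip = M[i - 1], D[i - 1], I[i - 1]
        Mi, Di, Ii = M[i], D[i], I[i]
        for j in range(1, m + 1):
            sub = 1 if (ci == sy[j - 1] and ci != "N") else -1
            best, state = _pick(Mp[j - 1], Dp[j - 1], Ip[j - 1])
            Mi[j] = best + sub
            BM[i][j] = state
            best, state = _pick(Mp[j] - 4, Dp[j] - 2, Ip[j] - 4)
            Di[j] = best
            BD[i][j] = state
            best, state = _pick(Mi[j - 1] - 4, Di[j - 1] - 4, Ii[j - 1] - 2)
            Ii[j] = best
            BI[i][j] = state
    _, state = _pick(M[n][m], D[n][m], I[n][m])
    i, j = n, m
    cols: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            cols.append("M" if (sx[i - 1] == sy[j - 1] and sx[i - 1] != "N") else "S")
            state = BM[i][j]
            i, j = i - 1, j - 1
        elif state == 1:
            cols.append("D")
            state = BD[i][j]
            i -= 1
        else:
            cols.append("I")
            state = BI[i][j]
            j -= 1
    return "".join(reversed(cols))


def gap_alignment_score(columns: str, seq_x_segment: str, seq_y_segment: str) -> int:
    """Score a column string under the module's affine scheme (for checks)."""
    score = 0
    i = j = 0
    prev = ""
    for c in columns:
        if c in "MS":
            score += 1 if (seq_x_segment[i] == seq_y_segment[j] != "N") else -1
            i += 1
            j += 1
        elif c == "D":
            score += -2 if prev == "D" else -4
            i += 1
        else:
            score += -2 if prev == "I" else -4
            j += 1
        prev = c
    return score


# --------------------------------------------------------------------------
# blocks
# --------------------------------------------------------------------------


@dataclass
class AlignmentBlock:
    """One gapped syntenic alignment between the two sex chromosomes.

    Coordinates are 1-based inclusive on the forward strand of each
    chromosome.  ``columns`` reads along X and along Y *in block
    orientation* (for REV blocks: along the reverse complement of Y), as do
    the stored ``x_seq``/``y_seq`` segment copies used downstream.
    """

    x_chrom: str
    y_chrom: str
    x_start: int
    x_end: int
    y_start: int
    y_end: int
    strand: Strand
    columns: str
    x_seq: str = field(repr=False, default="")
    y_seq: str = field(repr=False, default="")

    @property
    def identity(self) -> float:
        return self.columns.count("M") / len(self.columns) if self.columns else 0.0

    def validate(self) -> None:
        nm = self.columns.count("M")
        ns = self.columns.count("S")
        nd = self.columns.count("D")
        ni = self.columns.count("I")
        assert nm + ns + nd == self.x_end - self.x_start + 1, "x span mismatch"
        assert nm + ns + ni == self.y_end - self.y_start + 1, "y span mismatch"
        assert 0.0 <= self.identity <= 1.0


def _xdrop_extend(sx: str, sy: str, x: int, y: int, step: int) -> int:
    """Ungapped X-drop walk from (x, y) (exclusive) in direction ``step``.

    Returns the number of columns kept, i.e. the prefix of the walk ending
    at the running score maximum before the score drops by X_DROP.
    """
    best = 0
    score = 0
    kept = 0
    n = 0
    while n < MAX_END_EXTENSION:
        x += step
        y += step
        if not (0 <= x < len(sx) and 0 <= y < len(sy)):
            break
        score += 1 if (sx[x] == sy[y] != "N") else -1
        n += 1
        if score > best:
            best = score
            kept = n
        elif best - score >= X_DROP:
            break
    return kept


def _columns_for_span(sx: str, sy: str, x0: int, y0: int, length: int) -> str:
    return "".join(
        "M" if (sx[x0 + t] == sy[y0 + t] != "N") else "S" for t in range(length)
    )


def align_chromosomes(
    seq_x: "SeqRecord",
    seq_y: "SeqRecord",
    params: "PipelineParams",
    min_block_len: int | None = None,
) -> list[AlignmentBlock]:
    """Full syntenic alignment: seed, chain, close gaps, extend, filter.

    Each chain yields one block (two or more when an inter-anchor gap
    exceeds the DP band limit, which splits the chain); blocks shorter than
    ``min_block_len`` columns (default: params.min_marker_len) are dropped.
    """
    sx, sy = seq_x.sequence, seq_y.sequence
    min_block = params.min_marker_len if min_block_len is None else min_block_len
    if len(sx) < params.seed_k or len(sy) < params.seed_k:
        return []
    anchors = find_anchors(sx, sy, params.seed_k)
    chains = chain_anchors(anchors, params.max_gap)
    ry = revcomp(sy)
    ny = len(sy)
    blocks: list[AlignmentBlock] = []
    for chain in chains:
        strand = chain[0].strand
        y_or = sy if strand is Strand.FWD else ry
        # anchors in oriented-y coordinates (ascending along the chain)
        oriented = [
            (a.x_pos, a.y_pos if strand is Strand.FWD else ny - (a.y_pos + a.length), a.length)
            for a in chain
        ]
        span_x = oriented[-1][0] + oriented[-1][2] - oriented[0][0]
        span_y = oriented[-1][1] + oriented[-1][2] - oriented[0][1]
        if max(span_x, span_y) + 2 * MAX_END_EXTENSION < min_block:
            continue
        # split the chain wherever a gap exceeds the band limit
        pieces: list[list[tuple[int, int, int]]] = [[oriented[0]]]
        for prev, nxt in zip(oriented, oriented[1:]):
            gx = nxt[0] - (prev[0] + prev[2])
            gy = nxt[1] - (prev[1] + prev[2])
            if gx > params.band_limit or gy > params.band_limit:
                pieces.append([nxt])
            else:
                pieces[-1].append(nxt)
        for piece in pieces:
            cols: list[str] = ["M" * piece[0][2]]
            for prev, nxt in zip(piece, piece[1:]):
                gx0, gy0 = prev[0] + prev[2], prev[1] + prev[2]
                cols.append(align_gap(sx[gx0 : nxt[0]], y_or[gy0 : nxt[1]]))
                cols.append("M" * nxt[2])
            x0, y0 = piece[0][0], piece[0][1]
            x1 = piece[-1][0] + piece[-1][2] - 1  # inclusive, oriented
            y1 = piece[-1][1] + piece[-1][2] - 1
            left = _xdrop_extend(sx, y_or, x0, y0, -1)
            right = _xdrop_extend(sx, y_or, x1, y1, +1)
            if left:
                cols.insert(0, _columns_for_span(sx, y_or, x0 - left, y0 - left, left))
                x0 -= left
                y0 -= left
            if right:
                cols.append(_columns_for_span(sx, y_or, x1 + 1, y1 + 1, right))
                x1 += right
                y1 += right
            columns = "".join(cols)
            if len(columns) < min_block:
                continue
            if strand is Strand.FWD:
                yf0, yf1 = y0, y1
            else:
                yf0, yf1 = ny - 1 - y1, ny - 1 - y0
            block = AlignmentBlock(
                x_chrom=seq_x.id,
                y_chrom=seq_y.id,
                x_start=x0 + 1,
                x_end=x1 + 1,
                y_start=yf0 + 1,
                y_end=yf1 + 1,
                strand=strand,
                columns=columns,
                x_seq=sx[x0 : x1 + 1],
                y_seq=y_or[y0 : y1 + 1],
            )
            block.validate()
            blocks.append(block)
    blocks.sort(key=lambda b: (b.x_start, b.y_start))
    logger.log(
        logging.INFO if len(sx) > 10_000 else logging.DEBUG,
        "aligned %s vs %s: %d anchors, %d chains, %d blocks >= %d cols",
        seq_x.id, seq_y.id, len(anchors), len(chains), len(blocks), min_block,
    )
    return blocks
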