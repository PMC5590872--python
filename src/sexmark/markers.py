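"""Marker-pair extraction from syntenic alignment blocks.

A marker pair is a pair of homologous windows, one per sex chromosome,
chosen so that no run of identical alignment columns inside the window is
as long as a read (the 35 bp rule): any read whose footprint covers at
least that much of the window therefore spans a diagnostic site, so the
chromosome copy it came from is decidable.  The extraction pipeline is:

1. align the two sex chromosomes (:mod:`sexmark.synteny`);
2. cut every alignment block at identical runs >= ``max_exact_block``
   columns, keeping up to ``max_exact_block - 1`` flanking identical
   columns per side (:func:`segment_polymorphic`);
3. keep windows of >= ``min_marker_len`` columns with >=
   ``min_mismatches`` non-identical columns (:func:`filter_candidates`);
4. drop pairs with a near-identical autosomal copy or a near-identical
   retained marker (:func:`screen_autosomes`);
5. optionally restrict to genic windows (:func:`restrict_to_genes`).

Every non-M column (substitution or gap) counts as one mismatch, which
keeps the two member sequences maximally distinguishable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import synteny
from .seqio import BedInterval, Member, MarkerHeader, SeqRecord, read_marker_fasta
from .synteny import AlignmentBlock, Strand, revcomp

logger = logging.getLogger("sexmark.markers")

__all__ = [
    "PipelineParams",
    "MarkerPair",
    "segment_polymorphic",
    "filter_candidates",
    "screen_autosomes",
    "restrict_to_genes",
    "extract_markers",
    "load_marker_pairs",
    "load_published_markers",
    "marker_summary",
]


@dataclass(frozen=True)
class PipelineParams:
    """Every tunable constant of the method, with published defaults.

    max_exact_block
        Longest tolerated run of identical alignment columns inside a
        marker, in bases (an exact run this long could be covered by a
        whole read, making the read uninformative).
    min_marker_len / min_mismatches
        Minimum window size in alignment columns and minimum number of
        diagnostic (non-identical) columns per window.
    autosome_identity_cutoff
        Local-alignment identity above which a marker matching an autosome
        is discarded as non-unique.
    het_fraction_threshold
        Fraction of dominant-chromosome (Y/W) hits at or above which a
        sample is called heterogametic; below it, homogametic.
    min_total_hits
        Marker hits required before any call is made at all.
    default_reads_wes_rna / default_reads_wgs
        Recommended read budgets per sequencing type.
    seed_k / map_identity_min
        Seed length for both the aligner and the read mapper, and the
        minimum alignment identity for a read hit.
    max_gap / band_limit
        Anchor-chaining gap bound and the largest inter-anchor gap closed
        by dynamic programming (larger gaps split a block).
    """

    max_exact_block: int = 35
    min_marker_len: int = 151
    min_mismatches: int = 5
    autosome_identity_cutoff: float = 0.90
    het_fraction_threshold: float = 0.2
    min_total_hits: int = 100
    default_reads_wes_rna: int = 5_000_000
    default_reads_wgs: int = 100_000_000
    seed_k: int = 15
    map_identity_min: float = 0.90
    min_marker_pairs_warn: int = 10
    max_gap: int = 500
    band_limit: int = 2000

    def __post_init__(self):
        for name in (
            "max_exact_block", "min_marker_len", "min_mismatches",
            "min_total_hits", "default_reads_wes_rna", "default_reads_wgs",
            "seed_k", "min_marker_pairs_warn", "max_gap", "band_limit",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("autosome_identity_cutoff", "het_fraction_threshold",
                     "map_identity_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.max_exact_block >= self.min_marker_len:
            raise ValueError("max_exact_block must be < min_marker_len")


@dataclass
class MarkerPair:
    """One homologous window pair: X/Z member and Y/W member.

    Sequences are stored on the forward strand of their chromosome;
    ``columns`` (when available) is the window's slice of the parent
    block's column string, ``mismatches`` its count of non-M columns.
    """

    pair_id: str
    header_x: MarkerHeader
    header_y: MarkerHeader
    seq_x: str
    seq_y: str
    columns: str | None = None
    mismatches: int = 0
    length: int = 0
    genes: tuple[str, str] | None = None

    def check(self, params: PipelineParams) -> None:
        """Assert the type invariants under ``params`` (used by tests)."""
        assert self.length >= params.min_marker_len
        assert self.mismatches >= params.min_mismatches
        if self.columns is not None:
            assert len(self.columns) == self.length
            non_m = sum(1 for c in self.columns if c != "M")
            assert non_m == self.mismatches, "mismatches != non-M columns"
            run = 0
            for c in self.columns:
                run = run + 1 if c == "M" else 0
                assert run < params.max_exact_block, "identical run too long"


# --------------------------------------------------------------------------
# step 2: polymorphic-window segmentation
# --------------------------------------------------------------------------


def segment_polymorphic(
    block: AlignmentBlock, params: PipelineParams
) -> list[tuple[int, int]]:
    """Cut a block into candidate windows at long identical runs.

    Returns ordered, disjoint half-open column ranges in which every run of
    consecutive M columns is shorter than ``max_exact_block``.  A run of
    >= ``max_exact_block`` M columns is a separator; each adjacent window
    keeps at most ``max_exact_block - 1`` of the separator's columns (an
    interior separator is shared between its two neighbours, split
    floor/ceil so the windows stay disjoint).  Windows without a single
    polymorphic column are not reported.
    """
    cols = block.columns
    maxb = params.max_exact_block
    e = maxb - 1
    n = len(cols)
    # locate separator runs (maximal M-runs of length >= maxb)
    separators: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if cols[i] == "M":
            j = i
            while j < n and cols[j] == "M":
                j += 1
            if j - i >= maxb:
                separators.append((i, j))
            i = j
        else:
            i += 1
    # core regions between separators
    bounds = [0] + [b for s in separators for b in s] + [n]
    windows: list[tuple[int, int]] = []
    for idx in range(0, len(bounds), 2):
        a, b = bounds[idx], bounds[idx + 1]
        if a >= b or all(c == "M" for c in cols[a:b]):
            continue  # empty or polymorphism-free edge region
        left_sep = separators[idx // 2 - 1] if idx > 0 else None
        right_sep = separators[idx // 2] if idx // 2 < len(separators) else None
        take_left = 0
        if left_sep is not None:
            r = left_sep[1] - left_sep[0]
            # shared with the region before it unless the separator starts the block
            take_left = min(e, r) if left_sep[0] == 0 else min(e, r - r // 2)
        take_right = 0
        if right_sep is not None:
            r = right_sep[1] - right_sep[0]
            take_right = min(e, r) if right_sep[1] == n else min(e, r // 2)
        windows.append((a - take_left, b + take_right))
    return windows


# --------------------------------------------------------------------------
# step 3: length / mismatch filter -> MarkerPair
# --------------------------------------------------------------------------


def _window_to_pair(
    window: tuple[int, int], block: AlignmentBlock
) -> MarkerPair:
    a, b = window
    cols = block.columns[a:b]
    x_off = sum(1 for c in block.columns[:a] if c != "I")
    x_len = sum(1 for c in cols if c != "I")
    y_off = sum(1 for c in block.columns[:a] if c != "D")
    y_len = sum(1 for c in cols if c != "D")
    seq_x = block.x_seq[x_off : x_off + x_len]
    y_oriented = block.y_seq[y_off : y_off + y_len]
    x_start = block.x_start + x_off
    x_end = x_start + x_len - 1
    if block.strand is Strand.FWD:
        y_start = block.y_start + y_off
        y_end = y_start + y_len - 1
        seq_y = y_oriented
    else:
        y_end = block.y_end - y_off
        y_start = y_end - y_len + 1
        seq_y = revcomp(y_oriented)
    mism = sum(1 for c in cols if c != "M")
    hx = MarkerHeader("", Member.RECESSIVE, block.x_chrom, x_start, x_end,
                      "", len(cols), mism)
    hy = MarkerHeader("", Member.DOMINANT, block.y_chrom, y_start, y_end,
                      "", len(cols), mism)
    return MarkerPair("", hx, hy, seq_x, seq_y, cols, mism, len(cols))


def filter_candidates(
    windows: Sequence[tuple[int, int]],
    block: AlignmentBlock,
    params: PipelineParams,
) -> list[MarkerPair]:
    """Keep windows long and polymorphic enough; build MarkerPairs.

    Boundaries are inclusive: exactly ``min_marker_len`` columns with
    exactly ``min_mismatches`` diagnostic columns passes.
    """
    out = []
    for a, b in windows:
        cols = block.columns[a:b]
        if len(cols) < params.min_marker_len:
            continue
        if sum(1 for c in cols if c != "M") < params.min_mismatches:
            continue
        pair = _window_to_pair((a, b), block)
        if pair.seq_x and pair.seq_y:
            out.append(pair)
    return out


def _renumber(pairs: list[MarkerPair]) -> list[MarkerPair]:
    out = []
    for i, p in enumerate(pairs, 1):
        pid = f"pair{i:04d}"
        out.append(
            replace(
                p,
                pair_id=pid,
                header_x=replace(p.header_x, pair_id=pid),
                header_y=replace(p.header_y, pair_id=pid),
            )
        )
    return out


# --------------------------------------------------------------------------
# step 4: uniqueness screens
# --------------------------------------------------------------------------


def _has_similar_local_hit(
    query: str, subject: SeqRecord, params: PipelineParams
) -> bool:
    """Local (seed-and-extend) hit covering >= 50% of the query at >= the
    identity cutoff, either strand."""
    min_cov_bases = math.ceil(0.5 * len(query))
    qrec = SeqRecord("query", "", query)
    blocks = synteny.align_chromosomes(qrec, subject, params, min_block_len=min_cov_bases)
    for b in blocks:
        coverage = (b.x_end - b.x_start + 1) / len(query)
        if coverage >= 0.5 and b.identity >= params.autosome_identity_cutoff:
            return True
    return False


def screen_autosomes(
    pairs: Sequence[MarkerPair],
    autosomes: Sequence[SeqRecord],
    params: PipelineParams,
) -> list[MarkerPair]:
    """Drop non-unique pairs; re-number survivors pair0001, pair0002, ...

    A pair is removed when EITHER member has a local alignment to any
    autosome covering >= 50% of the marker at identity >= the cutoff.
    Afterwards, a retained marker >= 90% identical (same criterion) to an
    earlier retained marker of the same member class is removed too, so the
    final set is mutually distinctive; first-seen (lowest X coordinate)
    wins.
    """
    if not autosomes:
        logger.warning("no autosome sequences given: uniqueness screen skipped")
        survivors = list(pairs)
    else:
        survivors = []
        for p in pairs:
            hit = any(
                _has_similar_local_hit(seq, auto, params)
                for auto in autosomes
                for seq in (p.seq_x, p.seq_y)
            )
            if hit:
                logger.info("marker at %s:%d-%d removed: autosomal copy",
                            p.header_x.chrom, p.header_x.start, p.header_x.end)
            else:
                survivors.append(p)
    deduped: list[MarkerPair] = []
    for p in survivors:
        redundant = False
        for q in deduped:
            for s_new, s_old in ((p.seq_x, q.seq_x), (p.seq_y, q.seq_y)):
                old = SeqRecord("kept", "", s_old)
                if _has_similar_local_hit(s_new, old, params):
                    redundant = True
                    break
            if redundant:
                break
        if not redundant:
            deduped.append(p)
    return _renumber(deduped)


def restrict_to_genes(
    pairs: Sequence[MarkerPair], annotation: Sequence[BedInterval]
) -> list[MarkerPair]:
    """Keep pairs whose X/Z member overlaps an annotated interval >= 1 bp.

    Gene names from the BED name field are attached to whichever members
    they overlap; intervals naming a chromosome that is not one of the
    marker chromosomes are ignored with a warning.
    """
    known = {p.header_x.chrom for p in pairs} | {p.header_y.chrom for p in pairs}
    by_chrom: dict[str, list[BedInterval]] = {}
    unknown = set()
    for iv in annotation:
        if iv.chrom in known:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        else:
            unknown.add(iv.chrom)
    for chrom in sorted(unknown):
        logger.warning("annotation chromosome %r matches no marker chromosome; ignored", chrom)

    def overlapping(h: MarkerHeader) -> list[BedInterval]:
        return [
            iv for iv in by_chrom.get(h.chrom, ())
            if iv.start <= h.end and h.start <= iv.end
        ]

    out = []
    for p in pairs:
        hits_x = overlapping(p.header_x)
        if not hits_x:
            continue
        gene_x = next((iv.name for iv in hits_x if iv.name), "")
        hits_y = overlapping(p.header_y)
        gene_y = next((iv.name for iv in hits_y if iv.name), "")
        out.append(
            replace(
                p,
                header_x=replace(p.header_x, gene=gene_x),
                header_y=replace(p.header_y, gene=gene_y),
                genes=(gene_x, gene_y),
            )
        )
    return out


# --------------------------------------------------------------------------
# composition
# --------------------------------------------------------------------------


def extract_markers(
    seq_x: SeqRecord,
    seq_y: SeqRecord,
    autosomes: Sequence[SeqRecord],
    params: PipelineParams,
    *,
    annotation: Sequence[BedInterval] | None = None,
    genic_only: bool = False,
) -> list[MarkerPair]:
    """Full marker discovery: align, segment, filter, screen, (restrict)."""
    blocks = synteny.align_chromosomes(seq_x, seq_y, params)
    if not blocks:
        logger.warning(
            "no syntenic blocks found between %s and %s; no markers extracted",
            seq_x.id, seq_y.id,
        )
        return []
    candidates: list[MarkerPair] = []
    for block in blocks:
        windows = segment_polymorphic(block, params)
        candidates.extend(filter_candidates(windows, block, params))
    candidates.sort(key=lambda p: (p.header_x.start, p.header_x.end))
    pairs = screen_autosomes(candidates, autosomes, params)
    if genic_only and annotation is not None:
        pairs = restrict_to_genes(pairs, annotation)
    if len(pairs) < params.min_marker_pairs_warn:
        logger.warning(
            "only %d marker pair(s) found (< %d); two parameters can be "
            "adjusted: max_exact_block (currently %d) and min_marker_len "
            "(currently %d)",
            len(pairs), params.min_marker_pairs_warn,
            params.max_exact_block, params.min_marker_len,
        )
    return pairs


def load_marker_pairs(path) -> list[MarkerPair]:
    """Load a marker FASTA written by :func:`sexmark.seqio.write_marker_fasta`."""
    by_pair: dict[str, dict[Member, tuple[MarkerHeader, str]]] = {}
    order: list[str] = []
    for header, seq in read_marker_fasta(path):
        if header.pair_id not in by_pair:
            order.append(header.pair_id)
        by_pair.setdefault(header.pair_id, {})[header.member] = (header, seq)
    pairs = []
    for pid in order:
        members = by_pair[pid]
        if set(members) != {Member.RECESSIVE, Member.DOMINANT}:
            raise ValueError(f"marker pair {pid!r} is missing a member sequence")
        hx, sx = members[Member.RECESSIVE]
        hy, sy = members[Member.DOMINANT]
        pairs.append(
            MarkerPair(pid, hx, hy, sx, sy, None, hx.mismatches, hx.length,
                       (hx.gene, hy.gene) if (hx.gene or hy.gene) else None)
        )
    return pairs


def marker_summary(pairs: Sequence[MarkerPair]) -> dict:
    """Count/mean/min/max summary; means floored to whole integers,
    following the convention of the published marker tables."""
    if not pairs:
        return {"n_pairs": 0}
    lengths = [p.length for p in pairs]
    mism = [p.mismatches for p in pairs]
    return {
        "n_pairs": len(pairs),
        "mean_length": int(np.mean(lengths)),
        "mean_mismatches": int(np.mean(mism)),
        "min_length": min(lengths),
        "max_length": max(lengths),
        "min_mismatches": min(mism),
        "max_mismatches": max(mism),
    }


# --------------------------------------------------------------------------
# published marker catalogs (printed coordinate tables)
# --------------------------------------------------------------------------

_PUBLISHED = {
    "human": "human_xy_markers_hg38.tsv",
    "chicken": "chicken_zw_markers_galgal.tsv",
}


def load_published_markers(species: str) -> pd.DataFrame:
    """Published sex-marker coordinate catalogs (human hg38 X/Y, chicken Z/W).

    Columns: chrom_x, start_x, end_x, gene_x, chrom_y, start_y, end_y,
    gene_y, length, mismatches.  Coordinates are 1-based inclusive and
    satisfy ``length == end - start + 1`` on both chromosomes.
    """
    try:
        fname = _PUBLISHED[species]
    except KeyError:
        raise ValueError(f"unknown species {species!r}; one of {sorted(_PUBLISHED)}")
    with resources.files("sexmark").joinpath("data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, sep="\t")
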