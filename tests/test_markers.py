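import random

import pytest
from hypothesis import given, settings, strategies as st

import sexmark as sm
from oracles import polymorphic_windows
from sexmark.markers import (
    MarkerPair,
    PipelineParams,
    extract_markers,
    filter_candidates,
    restrict_to_genes,
    screen_autosomes,
    segment_polymorphic,
)
from sexmark.seqio import BedInterval, SeqRecord
from sexmark.synteny import AlignmentBlock, Strand, revcomp

PARAMS = PipelineParams()


def rand_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(alphabet) for _ in range(n))


def block_from_columns(cols, seed=0, x_start=1, y_start=1):
    """A consistent AlignmentBlock realizing the given column string."""
    rng = random.Random(seed)
    xs, ys = [], []
    other = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for c in cols:
        if c == "M":
            b = rng.choice("ACGT")
            xs.append(b)
            ys.append(b)
        elif c == "S":
            b = rng.choice("ACGT")
            xs.append(b)
            ys.append(other[b])
        elif c == "D":
            xs.append(rng.choice("ACGT"))
        else:
            ys.append(rng.choice("ACGT"))
    x_seq, y_seq = "".join(xs), "".join(ys)
    return AlignmentBlock(
        "chrX", "chrY", x_start, x_start + len(x_seq) - 1,
        y_start, y_start + len(y_seq) - 1, Strand.FWD, cols, x_seq, y_seq,
    )


class TestSegmentPolymorphic:
    def test_all_identical_block_yields_nothing(self):
        assert segment_polymorphic(block_from_columns("M" * 500), PARAMS) == []

    def test_long_runs_trimmed_to_34_each_side(self):
        windows = segment_polymorphic(block_from_columns("M" * 40 + "S" + "M" * 40), PARAMS)
        assert windows == [(6, 75)]  # 34 M + S + 34 M

    def test_frequent_polymorphisms_keep_whole_block(self):
        cols = ("M" * 29 + "S") * 10
        assert segment_polymorphic(block_from_columns(cols), PARAMS) == [(0, 300)]

    @given(st.lists(st.sampled_from(["M", "S", "I", "D", "MMMMM", "M" * 20, "M" * 40]),
                    min_size=0, max_size=40))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_matches_run_list_oracle_and_window_properties(self, parts):
        cols = "".join(parts)[:1000]
        block = block_from_columns(cols)
        windows = segment_polymorphic(block, PARAMS)
        assert windows == polymorphic_windows(cols, PARAMS.max_exact_block)
        prev_end = 0
        for a, b in windows:
            assert 0 <= a < b <= len(cols)
            assert a >= prev_end  # disjoint and ordered
            prev_end = b
            w = cols[a:b]
            assert any(c != "M" for c in w)
            run = 0
            for c in w:
                run = run + 1 if c == "M" else 0
                assert run < PARAMS.max_exact_block
        # every polymorphic column belongs to some window
        covered = set()
        for a, b in windows:
            covered.update(range(a, b))
        for i, c in enumerate(cols):
            if c != "M":
                assert i in covered


class TestFilterCandidates:
    def _win(self, n_cols, n_sub):
        # substitutions spread so no run reaches the cut length
        step = max(1, n_cols // (n_sub + 1))
        positions = set()
        p = step
        while len(positions) < n_sub:
            positions.add(min(p, n_cols - 1))
            p += step
            if p >= n_cols:
                p = max(0, n_cols - len(positions) - 1)
        cols = "".join("S" if i in positions else "M" for i in range(n_cols))
        return block_from_columns(cols)

    def test_150_columns_dropped(self):
        block = self._win(150, 10)
        assert filter_candidates([(0, 150)], block, PARAMS) == []

    def test_151_columns_4_mismatches_dropped(self):
        block = self._win(151, 4)
        assert filter_candidates([(0, 151)], block, PARAMS) == []

    def test_151_columns_5_mismatches_kept(self):
        block = self._win(151, 5)
        pairs = filter_candidates([(0, 151)], block, PARAMS)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.length == 151 and p.mismatches == 5
        # substitution-only: coordinate span equals column count on both sides
        assert p.header_x.end - p.header_x.start + 1 == 151
        assert p.header_y.end - p.header_y.start + 1 == 151

    def test_gap_columns_shift_coordinates(self):
        cols = "M" * 30 + "S" + "D" + "M" * 30 + "I" + "S" + "M" * 30 + "S" + "M" * 60 + "S" + "M" * 30
        block = block_from_columns(cols, x_start=101, y_start=501)
        pairs = filter_candidates([(0, len(cols))], block, PARAMS)
        assert len(pairs) == 1
        p = pairs[0]
        n_x = sum(1 for c in cols if c != "I")
        n_y = sum(1 for c in cols if c != "D")
        assert p.header_x.end - p.header_x.start + 1 == n_x == len(p.seq_x)
        assert p.header_y.end - p.header_y.start + 1 == n_y == len(p.seq_y)
        assert p.mismatches == sum(1 for c in cols if c != "M")


def _marker_pair(seq_x, seq_y, pid="pair0001"):
    from sexmark.seqio import MarkerHeader, Member

    hx = MarkerHeader(pid, Member.RECESSIVE, "chrX", 1, len(seq_x), "", len(seq_x), 9)
    hy = MarkerHeader(pid, Member.DOMINANT, "chrY", 1, len(seq_y), "", len(seq_y), 9)
    cols = "".join("M" if a == b else "S" for a, b in zip(seq_x, seq_y))
    return MarkerPair(pid, hx, hy, seq_x, seq_y, cols,
                      sum(1 for c in cols if c == "S"), len(cols))


def _paralog(rng, seq, spacing):
    """Copy with paired substitutions every `spacing` bases (keeps exact
    runs long enough to seed)."""
    out = list(seq)
    other = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for p in range(0, len(seq) - 1, spacing):
        out[p] = other[out[p]]
        out[p + 1] = other[out[p + 1]]
    return "".join(out)


class TestScreenAutosomes:
    def _pair(self, rng):
        sx = rand_dna(rng, 200)
        sy = _paralog(rng, sx, 40)  # ~5 substitution clusters -> distinct member
        return _marker_pair(sx, sy)

    def test_verbatim_autosomal_copy_removed(self):
        rng = random.Random(20)
        pair = self._pair(rng)
        auto = SeqRecord("a1", "", rand_dna(rng, 3000, "AC") + pair.seq_x + rand_dna(rng, 3000, "AC"))
        assert screen_autosomes([pair], [auto], PARAMS) == []

    def test_unrelated_autosome_keeps_marker(self):
        rng = random.Random(21)
        pair = self._pair(rng)
        auto = SeqRecord("a1", "", rand_dna(rng, 5000, "AC"))
        kept = screen_autosomes([pair], [auto], PARAMS)
        assert [p.pair_id for p in kept] == ["pair0001"]

    def test_89_percent_paralog_kept_95_percent_removed(self):
        rng = random.Random(22)
        sx = rand_dna(rng, 198)
        pair = _marker_pair(sx, _paralog(rng, sx, 40))
        # 2 mismatches per 18 bases ~ 11% divergence -> identity ~0.89
        par89 = _paralog(rng, sx, 18)
        auto89 = SeqRecord("a", "", rand_dna(rng, 2000, "AC") + par89 + rand_dna(rng, 2000, "AC"))
        assert len(screen_autosomes([pair], [auto89], PARAMS)) == 1
        # 2 mismatches per 40 bases ~ 5% divergence -> identity ~0.95
        par95 = _paralog(rng, sx, 40)
        auto95 = SeqRecord("a", "", rand_dna(rng, 2000, "AC") + par95 + rand_dna(rng, 2000, "AC"))
        assert screen_autosomes([pair], [auto95], PARAMS) == []

    def test_redundant_marker_dropped_and_renumbered(self):
        rng = random.Random(23)
        p1 = self._pair(rng)
        # a later marker nearly identical to p1's X member
        p2 = _marker_pair(_paralog(rng, p1.seq_x, 60), _paralog(rng, p1.seq_y, 60), "pair0002")
        p3 = self._pair(rng)
        p3 = _marker_pair(p3.seq_x, p3.seq_y, "pair0003")
        kept = screen_autosomes([p1, p2, p3], [], PARAMS)
        assert len(kept) == 2
        assert [p.pair_id for p in kept] == ["pair0001", "pair0002"]  # renumbered
        assert kept[1].seq_x == p3.seq_x  # first-seen wins


class TestRestrictToGenes:
    def _pairs(self):
        rng = random.Random(24)
        out = []
        for i, start in enumerate((1000, 5000, 9000), 1):
            sx = rand_dna(rng, 200)
            p = _marker_pair(sx, _paralog(rng, sx, 40), f"pair{i:04d}")
            from dataclasses import replace

            p.header_x = replace(p.header_x, start=start, end=start + 199)
            out.append(p)
        return out

    def test_overlap_keeps_and_annotates(self):
        pairs = self._pairs()
        bed = [BedInterval("chrX", 900, 1100, "GENE1"),
               BedInterval("chrX", 5100, 5150, "")]
        kept = restrict_to_genes(pairs, bed)
        assert [p.header_x.start for p in kept] == [1000, 5000]
        assert kept[0].header_x.gene == "GENE1"

    def test_zero_overlap_dropped(self):
        kept = restrict_to_genes(self._pairs(), [BedInterval("chrX", 20000, 21000, "G")])
        assert kept == []

    def test_unknown_chromosome_warned_and_ignored(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="sexmark.markers"):
            kept = restrict_to_genes(self._pairs(), [BedInterval("chr7", 1, 10000, "G")])
        assert kept == []
        assert any("chr7" in r.message for r in caplog.records)


class TestExtractMarkers:
    def test_identical_chromosomes_give_nothing(self):
        x = rand_dna(random.Random(25), 5000)
        pairs = extract_markers(SeqRecord("x", "", x), SeqRecord("y", "", x), [], PARAMS)
        assert pairs == []

    def test_planted_segments_recovered(self, small_genome, small_markers):
        """>= 90% of planted divergent segments come back as marker pairs
        overlapping the planted interval."""
        segs = small_genome.truth.segments
        planted = {s.index for s in segs}
        recovered = set()
        for s in segs:
            for p in small_markers:
                lo = max(p.header_x.start, s.x_start)
                hi = min(p.header_x.end, s.x_end)
                if hi - lo + 1 >= 0.9 * (s.x_end - s.x_start + 1):
                    recovered.add(s.index)
        # segment 2 is the planted autosomal paralog: it must NOT be there
        assert 2 not in recovered
        assert len(recovered) >= 0.9 * (len(planted) - 1)

    def test_planted_paralog_absent(self, small_genome, small_markers):
        seg = small_genome.truth.segments[2]
        for p in small_markers:
            assert not (p.header_x.start <= seg.x_end and seg.x_start <= p.header_x.end)

    def test_every_pair_satisfies_invariants(self, small_markers, params):
        for p in small_markers:
            p.check(params)
            assert p.header_x.end - p.header_x.start + 1 == len(p.seq_x)
            assert p.header_y.end - p.header_y.start + 1 == len(p.seq_y)

    def test_deterministic_marker_fasta(self, small_genome, params, tmp_path):
        a, b = tmp_path / "a.fa", tmp_path / "b.fa"
        for out in (a, b):
            pairs = extract_markers(
                small_genome.seq_x, small_genome.seq_y, small_genome.autosomes, params
            )
            sm.write_marker_fasta(pairs, out)
        assert a.read_bytes() == b.read_bytes()

    def test_summary_matches_direct_recomputation(self, small_markers):
        import numpy as np

        s = sm.marker_summary(small_markers)
        lengths = [p.length for p in small_markers]
        mism = [p.mismatches for p in small_markers]
        assert s["mean_length"] == int(np.floor(np.mean(lengths)))
        assert s["mean_mismatches"] == int(np.floor(np.mean(mism)))
        assert s["min_length"] == min(lengths) and s["max_length"] == max(lengths)


class TestPipelineParams:
    def test_defaults_are_the_published_constants(self):
        p = PipelineParams()
        assert (p.max_exact_block, p.min_marker_len, p.min_mismatches) == (35, 151, 5)
        assert (p.autosome_identity_cutoff, p.het_fraction_threshold) == (0.90, 0.2)
        assert (p.min_total_hits, p.default_reads_wes_rna, p.default_reads_wgs) == (
            100, 5_000_000, 100_000_000,
        )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"max_exact_block": 200},  # >= min_marker_len
            {"min_marker_len": 0},
            {"het_fraction_threshold": 1.5},
            {"map_identity_min": 0.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PipelineParams(**kwargs)
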