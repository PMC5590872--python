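import random

import pytest
from hypothesis import given, settings, strategies as st

from oracles import affine_dp_score, best_collinear_subset
from sexmark.markers import PipelineParams
from sexmark.seqio import SeqRecord
from sexmark.synteny import (
    Anchor,
    Strand,
    align_chromosomes,
    align_gap,
    chain_anchors,
    find_anchors,
    gap_alignment_score,
    revcomp,
)

PARAMS = PipelineParams()

dna = st.text(alphabet="ACGT", min_size=0, max_size=25)


def rand_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(alphabet) for _ in range(n))


class TestFindAnchors:
    def test_identical_sequences_one_full_anchor(self):
        x = rand_dna(random.Random(0), 100)
        assert find_anchors(x, x, 15) == [Anchor(0, 0, 100, Strand.FWD)]

    def test_disjoint_kmer_vocabularies_no_anchors(self):
        # x uses only A/C, y only G/T: no 15-mer can be shared
        rng = random.Random(1)
        x = rand_dna(rng, 200, "AC")
        y = rand_dna(rng, 200, "GT")
        assert find_anchors(x, y, 15) == []

    def test_reverse_complement_gives_one_rev_anchor(self):
        x = rand_dna(random.Random(2), 120)
        anchors = find_anchors(x, revcomp(x), 15)
        assert anchors == [Anchor(0, 0, 120, Strand.REV)]
        # the REV invariant: x span equals revcomp of the forward-y span
        a = anchors[0]
        y = revcomp(x)
        assert x[a.x_pos : a.x_pos + a.length] == revcomp(
            y[a.y_pos : a.y_pos + a.length]
        )

    def test_matches_brute_force_on_small_inputs(self):
        rng = random.Random(3)
        for _ in range(30):
            n = rng.randint(20, 50)
            x = rand_dna(rng, n)
            y = list(rand_dna(rng, n))
            if rng.random() < 0.8:  # embed a shared chunk
                p = rng.randint(0, n - 10)
                y[p : p + 10] = x[p : p + 10]
            y = "".join(y)
            got = {(a.x_pos, a.y_pos, a.length, a.strand) for a in find_anchors(x, y, 8)}
            want = set()
            for sy, strand in ((y, Strand.FWD), (revcomp(y), Strand.REV)):
                for i in range(n - 7):
                    for j in range(len(sy) - 7):
                        if x[i : i + 8] == sy[j : j + 8]:
                            a, b, L = i, j, 8
                            while a > 0 and b > 0 and x[a - 1] == sy[b - 1]:
                                a, b, L = a - 1, b - 1, L + 1
                            while a + L < n and b + L < len(sy) and x[a + L] == sy[b + L]:
                                L += 1
                            yf = b if strand is Strand.FWD else len(y) - (b + L)
                            want.add((a, yf, L, strand))
            assert got == want

    def test_n_containing_kmers_never_seed(self):
        x = "ACGTACGTACGTACGTACGT"
        y = x[:10] + "N" + x[11:]
        anchors = find_anchors(x, y, 8)
        for a in anchors:
            assert "N" not in y[a.y_pos : a.y_pos + a.length]


class TestChainAnchors:
    def test_two_collinear_anchors_one_chain(self):
        a = Anchor(0, 0, 20, Strand.FWD)
        b = Anchor(30, 30, 20, Strand.FWD)
        chains = chain_anchors([a, b], max_gap=500)
        assert chains == [[a, b]]

    def test_crossing_anchors_stay_separate(self):
        a = Anchor(0, 100, 20, Strand.FWD)
        b = Anchor(30, 0, 20, Strand.FWD)
        chains = chain_anchors([a, b], max_gap=500)
        assert sorted(len(c) for c in chains) == [1, 1]

    def test_outlier_excluded_matches_exhaustive_best_subset(self):
        rng = random.Random(4)
        for _ in range(20):
            anchors = []
            x = y = 0
            for _ in range(4):  # collinear backbone
                ln = rng.randint(10, 25)
                anchors.append(Anchor(x, y, ln, Strand.FWD))
                x += ln + rng.randint(1, 100)
                y = anchors[-1].y_pos + ln + rng.randint(1, 100)
            anchors.append(Anchor(rng.randint(0, 50), rng.randint(2000, 3000),
                                  rng.randint(10, 25), Strand.FWD))  # off-diagonal
            anchors.sort(key=lambda a: (a.x_pos, a.y_pos))
            best_score, best_set = best_collinear_subset(anchors, 500)
            chains = chain_anchors(anchors, 500)
            top = max(chains, key=lambda c: sum(a.length for a in c))
            assert sum(a.length for a in top) == best_score
            assert tuple(top) == best_set

    def test_chains_never_share_anchors(self):
        rng = random.Random(5)
        anchors = [
            Anchor(rng.randint(0, 2000), rng.randint(0, 2000), rng.randint(10, 30),
                   Strand.FWD)
            for _ in range(40)
        ]
        anchors = sorted(set(anchors), key=lambda a: (a.x_pos, a.y_pos))
        chains = chain_anchors(anchors, 500)
        flat = [a for c in chains for a in c]
        assert len(flat) == len(set(flat)) == len(anchors)


class TestAlignGap:
    @pytest.mark.parametrize(
        "sx,sy,expected",
        [
            ("ACGT", "ACGT", "MMMM"),
            ("ACGT", "ACTT", "MMSM"),
            ("", "ACG", "III"),
            ("AC", "", "DD"),
        ],
    )
    def test_examples(self, sx, sy, expected):
        assert align_gap(sx, sy) == expected

    def test_single_deletion(self):
        cols = align_gap("ACGT", "AGT")
        assert sorted(cols) == ["D", "M", "M", "M"]
        assert gap_alignment_score(cols, "ACGT", "AGT") == affine_dp_score("ACGT", "AGT")

    @given(sx=dna, sy=dna)
    @settings(deadline=None, max_examples=150, derandomize=True)
    def test_score_equals_full_dp_oracle(self, sx, sy):
        cols = align_gap(sx, sy)
        assert sum(c in "MSD" for c in cols) == len(sx)
        assert sum(c in "MSI" for c in cols) == len(sy)
        assert gap_alignment_score(cols, sx, sy) == affine_dp_score(sx, sy)

    def test_oracle_equivalence_at_200bp(self):
        rng = random.Random(6)
        x = rand_dna(rng, 200)
        y = list(x)
        for _ in range(20):
            p = rng.randrange(200)
            y[p] = rng.choice("ACGT")
        for _ in range(3):
            del y[rng.randrange(len(y))]
        y = "".join(y)
        cols = align_gap(x, y)
        assert gap_alignment_score(cols, x, y) == affine_dp_score(x, y)


def _mutate(rng, s, positions):
    out = list(s)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestAlignChromosomes:
    def test_identical_sequences_single_perfect_block(self):
        x = rand_dna(random.Random(7), 2000)
        blocks = align_chromosomes(SeqRecord("x", "", x), SeqRecord("y", "", x), PARAMS)
        assert len(blocks) == 1
        assert blocks[0].identity == 1.0
        assert (blocks[0].x_start, blocks[0].x_end) == (1, 2000)

    def test_scattered_substitutions_recovered_as_s_columns(self):
        rng = random.Random(8)
        x = rand_dna(rng, 2000)
        positions = sorted(rng.sample(range(30, 1970), 20))
        # keep mutations spaced > 15 so every inter-mutation run can seed
        positions = [p for i, p in enumerate(positions) if i == 0 or p - positions[i - 1] > 20][:20]
        y = _mutate(rng, x, positions)
        blocks = align_chromosomes(SeqRecord("x", "", x), SeqRecord("y", "", y), PARAMS)
        assert len(blocks) == 1
        b = blocks[0]
        assert b.columns.count("S") == len(positions)
        s_offsets = [i for i, c in enumerate(b.columns) if c == "S"]
        assert [b.x_start - 1 + o for o in s_offsets] == positions

    def test_two_planted_regions_give_two_blocks(self):
        rng = random.Random(9)
        region1, region2 = rand_dna(rng, 520), rand_dna(rng, 520)
        mut1 = _mutate(rng, region1, range(10, 510, 25))
        mut2 = _mutate(rng, region2, range(10, 510, 25))
        x = rand_dna(rng, 10000) + region1 + rand_dna(rng, 10000) + region2 + rand_dna(rng, 10000)
        y = rand_dna(rng, 10000) + mut1 + rand_dna(rng, 10000) + mut2 + rand_dna(rng, 10000)
        blocks = align_chromosomes(SeqRecord("x", "", x), SeqRecord("y", "", y), PARAMS)
        assert len(blocks) == 2

    def test_block_sequences_match_chromosome_slices(self):
        rng = random.Random(10)
        x = rand_dna(rng, 1500)
        y = _mutate(rng, x, range(5, 1495, 20))
        for sy, strand in ((y, Strand.FWD), (revcomp(y), Strand.REV)):
            blocks = align_chromosomes(SeqRecord("x", "", x), SeqRecord("y", "", sy), PARAMS)
            assert len(blocks) == 1
            b = blocks[0]
            assert b.strand is strand
            assert b.x_seq == x[b.x_start - 1 : b.x_end]
            fwd_slice = sy[b.y_start - 1 : b.y_end]
            assert b.y_seq == (fwd_slice if strand is Strand.FWD else revcomp(fwd_slice))
            # column string is consistent with the stored sequences
            i = j = 0
            for c in b.columns:
                if c in "MS":
                    assert (b.x_seq[i] == b.y_seq[j]) == (c == "M")
                    i += 1
                    j += 1
                elif c == "D":
                    i += 1
                else:
                    j += 1
            b.validate()

    def test_identity_is_m_fraction(self, small_genome, params):
        blocks = align_chromosomes(small_genome.seq_x, small_genome.seq_y, params)
        assert blocks
        for b in blocks:
            assert b.identity == b.columns.count("M") / len(b.columns)
            b.validate()

    def test_planted_segments_covered_by_blocks(self, small_genome, params):
        """Planted-region recovery: every segment overlaps a block over
        >= 90% of its length at <= 15% divergence."""
        blocks = align_chromosomes(small_genome.seq_x, small_genome.seq_y, params)
        for seg in small_genome.truth.segments:
            cover = max(
                (min(b.x_end, seg.x_end) - max(b.x_start, seg.x_start) + 1)
                for b in blocks
            )
            assert cover >= 0.9 * (seg.x_end - seg.x_start + 1)
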