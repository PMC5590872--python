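# Methods

## The model

Sex chromosomes that stopped recombining accumulate substitutions between
the gametolog copies of genes they still share (AMELX/AMELY-type pairs).
`sexmark` turns that divergence into a classifier with one observable per
sample: among sequencing reads that map to a curated set of gametolog
window pairs, the fraction `f` that land on the sex-limited (Y/W,
"dominant") member. Under a heterogametic karyotype both chromosome
copies contribute reads, so `f` concentrates near 0.5; under a
homogametic karyotype only the shared (X/Z, "recessive") chromosome
exists and `f` concentrates near 0. The decision rule is

    total hits < min_total_hits          -> indeterminate (no call)
    f >= het_fraction_threshold (0.2)    -> heterogametic
    f <  het_fraction_threshold          -> homogametic

with phenotype labels assigned by the declared system (XY: heterogametic
= male; ZW: heterogametic = female). The boundary value 0.2 itself counts
as heterogametic: only fractions strictly below the threshold are
homogametic. The threshold's job is to absorb stray dominant hits from
mis-mapped reads in homogametic samples while staying far below the
binomial spread of `f` around 0.5; it can be re-fit to labeled data with
`train_threshold` (below).

Assumptions worth stating: the two reference sex chromosomes are
assembled well enough to contain diverged syntenic windows; marker
windows behave as single-copy sequence (enforced by the autosome screen);
and read depth is roughly balanced between the two chromosome copies of a
diploid genome. Aneuploidies (XXY, X0), tumor contamination, and
probabilistic calls are out of scope.

## Marker discovery

1. **Syntenic alignment** (`synteny`). Exact k-mer seeds (k = 15, both
   strands, N-free, k-mers occurring > 64 times never seed) are merged
   into maximal exact anchors, chained collinearly by sparse dynamic
   programming (score = summed anchor length; gaps on either sequence
   bounded by `max_gap` = 500 bp), and the inter-anchor gaps are closed
   with a global affine-gap alignment (match +1, mismatch −1, gap −2 per
   base, −2 extra to open; inter-anchor gaps above `band_limit` = 2000
   split the chain instead). Block ends are then extended through
   mismatches by an ungapped X-drop walk (±1 scoring, drop-off 12,
   ≤ 300 columns per side, trimmed back to the running score maximum).
   Without this extension, the outermost exact seed of a 10–15% diverged
   window sits tens of bases inside the homologous region and the window
   edges would be lost. Alignment ties are broken M/S > D > I so output
   is bit-reproducible. Blocks shorter than `min_marker_len` columns are
   dropped.
2. **Polymorphic-window segmentation** (`markers.segment_polymorphic`).
   Each block is cut at every run of ≥ `max_exact_block` (35) identical
   columns; a window keeps at most 34 columns of a flanking identical
   run (an interior run is split floor/ceil between its two neighbouring
   windows so windows stay disjoint). The invariant this buys: any read
   footprint of ≥ 35 aligned bases inside a marker covers at least one
   diagnostic site.
3. **Length/mismatch filter**: windows need ≥ 151 columns and ≥ 5
   non-identical columns; both bounds are inclusive. Every non-M column
   (substitution or gap) counts as a mismatch.
4. **Uniqueness screen** (`markers.screen_autosomes`): a pair is removed
   when either member has a local (seed-and-extend, either strand)
   autosomal alignment covering ≥ 50% of the marker at ≥ 90% identity;
   afterwards a retained marker ≥ 90% identical to an earlier one (same
   criterion, member-wise) is also removed, first-seen wins. Survivors
   are renumbered `pair0001…`.
5. **Optional genic restriction** to BED intervals (≥ 1 bp overlap of
   the X/Z member), for transcriptome work.

Coordinates are 1-based inclusive on the forward strand everywhere
user-visible; reverse-strand blocks report the Y/W member
reverse-complemented into forward orientation. With substitution-only
divergence, `length == end − start + 1` holds on both members — the
convention of the bundled published marker catalogs
(`sexmark.load_published_markers`: 38 human hg38 X/Y rows averaging
216 bp/28 mismatches, 15 chicken Z/W rows averaging 196 bp/31; means
floored to integers).

## Read mapping and counting

The marker set is tiny, so the mapper indexes every k-mer of both strands
of both members. A read's candidates are (member, strand, diagonal)
triples reached by any shared k-mer; each is scored by gapless alignment
over the overlap span (match +1, mismatch −1). A hit requires identity
≥ `map_identity_min` (0.90) over the span and span ≥ 0.8 × min(read,
marker) length. The best-scoring candidate wins; an exact score tie
across members or pairs makes the read *ambiguous*, and ambiguous reads
are discarded rather than assigned — arbitrary tie-breaking would leak
spurious dominant hits into homogametic samples, exactly what the 0.2
threshold exists to absorb (the threshold is kept regardless). Each read
contributes at most one hit. Reads shorter than k, or whose best
candidate fails the gates, are unmapped. Indels in a read show up as two
seed diagonals scored independently; the better gapless diagonal wins or
the read stays unmapped — adequate for substitution-dominated markers,
and the published catalogs are substitution-only by the span convention
above.

`count_hits` runs a numba batch kernel over 2-bit-encoded read chunks;
`map_read` is the pure-Python reference with identical semantics, and a
test asserts the two agree read-for-read. The float thresholds are
applied with a 1e-9 slack so that, e.g., exactly 90% identity passes on
both paths despite binary rounding of `0.9 * span`.

## Threshold training and test mode

`train_threshold` does an exhaustive 0-1-loss sweep over the midpoints of
adjacent distinct sorted training fractions for the rule "heterogametic
iff f ≥ t"; among loss minimizers the maximum-margin midpoint wins, and
exact margin ties go to the smaller threshold. On inseparable data it
returns the minimum-error midpoint; if all fractions coincide it returns
that value with a warning. This is deliberately the smallest learner that
fits the one-dimensional, monotone problem.

`estimate_min_reads` streams the sample once, recording cumulative marker
hits at each point of a read-count schedule (default ladder 10⁵ … 10⁸,
mirroring the spread between enriched and whole-genome inputs), and
recommends the smallest schedule value whose cumulative count exceeds
`min_total_hits`; if the crossing lies beyond the schedule the crossing
read count itself is returned, and a stream that never crosses reports
"insufficient". Mean hits per marker pair is reported per step for
plotting. Recommended budgets of 5×10⁶ reads (exome/RNA) and 1×10⁸
(WGS) are exposed as configuration defaults, not enforced.

## The simulator and what passing tests mean

`simdata.simulate_genome` plants `n` gametolog segments (default 12, of
200–400 bp) at random, well-separated positions on a random X/Z
chromosome (default 10 Mb); the Y/W chromosome carries copies of those
segments with binomially drawn substitutions at a per-segment divergence
(default uniform in 5–15%), with extra substitutions inserted mid-run
until no identical run — segment ends included — exceeds 34 bp, mirroring
the marker definition. All non-segment Y/W sequence is independent random
DNA iteratively re-drawn until it shares no 15-mer with the X/Z
chromosome on either strand, making "non-homologous flank" an enforced
property; the re-draw loop is capped (25 rounds) and warns if chance
collisions survive, though it converges at every scale exercised,
including 10 Mb. Optional autosomes can carry verbatim copies of chosen
segments as uniqueness-screen decoys. A single-base `indel_rate` option
exists for the segments but defaults to 0: substitution-only divergence
matches the span convention of the published catalogs.

`simulate_reads` draws each read from one chromosome copy (50/50 for
heterogametic karyotypes), uniformly (WGS) or restricted to given
intervals (TARGETED, emulating exome/RNA enrichment), on either strand,
with i.i.d. substitution errors (default 1%) and constant Q30 qualities.
Not emulated: empirical quality/error profiles, GC and strand bias,
paired-end inserts, splicing, duplicates. Passing the benchmark therefore
demonstrates the pipeline's logic end to end — marker recovery from
divergence, hit counting, threshold behaviour — under idealized coverage;
it does not certify performance on degraded or biased real libraries,
where the 100-hit floor and the test mode are the practical safeguards.

## Benchmark sizes and numerical choices

The bundled benchmark (tests and `scripts/acceptance.py`) uses a 10 Mb
chromosome pair, 12 segments, and 40 samples of 500,000 × 100 bp reads at
1% error — enough that a WGS-like sample yields ~150 marker hits,
comfortably above the 100-hit floor, while the whole experiment stays in
the minutes range on one CPU. Unit tests use 80–300 kb genomes with 3–6
segments. Determinism: every stochastic stage takes an explicit seed
(numpy `default_rng`), alignment tie-breaks are fixed, and identical
inputs produce byte-identical marker FASTA; acceptance sample seeds are
derived as `base_seed * 1000 + sample_number`.

Degenerate inputs: empty gap sides align as pure insertion/deletion
columns; blocks made entirely of identical columns segment to nothing;
identical chromosomes yield zero markers with a parameter-adjustment
warning (as does any extraction below 10 pairs); an empty marker set
refuses to build an index; a zero-read stream gives an all-zero,
indeterminate hit table; classification with zero total hits defines
f = 0.

## Known limitations

- The aligner is for chromosome-scale pairs with localized homology, not
  whole-genome repeat landscapes; there is no repeat masking beyond the
  k-mer occurrence cap, and the gap DP is quadratic (bounded by
  `band_limit`).
- Mapping ignores base qualities and does true gapped alignment of
  neither reads nor markers; highly indel-rich markers would undercount.
- The fraction threshold assumes roughly balanced per-copy coverage;
  strong enrichment differences between X/Z and Y/W targets would shift
  f away from 0.5 for heterogametic samples.
- ZW support relabels the same arithmetic (Z≙X, W≙Y); no avian-specific
  dosage modelling is attempted.
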