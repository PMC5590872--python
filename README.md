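# sexmark

Genetic-sex identification from sequencing reads, without a reference
alignment.

Public sequencing archives are full of samples whose sex is missing or
wrong, and a mislabeled sex is one of the cheapest sample-swap signals a
QC pipeline can check. The usual route — align every read to the whole
genome and inspect X-chromosome B-allele frequencies or coverage — costs
hours per sample. `sexmark` takes the shortcut: it derives a few dozen
short **gametolog marker pairs** from the two sex chromosomes once, then
decides each sample's sex by mapping only as many reads as needed against
that tiny reference. It works for both male-heterogametic (XY, mammals)
and female-heterogametic (ZW, birds) systems, and for WGS, exome, and RNA
sequencing.

## Method

A *gametolog pair* is a pair of homologous windows, one on each sex
chromosome (e.g. *AMELX*/*AMELY*), diverged since recombination stopped.
Marker discovery aligns the two chromosomes (k-mer seeding, collinear
chaining, affine-gap closing, X-drop end extension — all built in, no
external aligner) and keeps aligned windows that satisfy:

- every run of identical alignment columns is shorter than **35 bp** (no
  read-length window can be uninformative),
- window length ≥ **151 bp** with ≥ **5** mismatching columns,
- no local autosomal match at ≥ **90%** identity over half the marker
  (uniqueness screen), and optionally only windows inside genic BED
  intervals.

For a sample, reads are mapped to the marker set with a built-in k-mer
mapper (best gapless candidate, identity ≥ 0.9; ties between members are
discarded as ambiguous). With hits `n_X` on the shared-chromosome members
and `n_Y` on the sex-limited members, the dominant-hit fraction is

    f = n_Y / (n_X + n_Y)

A heterogametic genome gives `f ≈ 0.5` (1:1 hits), a homogametic one
`f ≈ 0` (1:0). The call is **heterogametic** when `f ≥ 0.2`, homogametic
when `f < 0.2`, and no call is made below **100** total hits. The 0.2
threshold can also be re-learned from labeled samples
(`sexmark.train_threshold`), and a *test mode* estimates how many input
reads a dataset needs before the 100-hit floor is reached (defaults:
5×10⁶ reads for exome/RNA, 1×10⁸ for WGS).

A simulator (`sexmark.simdata`) generates chromosome pairs with planted
gametolog segments at controlled divergence, optional autosomal paralog
decoys, and reads of chosen karyotype/coverage/error, so the whole
pipeline is testable with known ground truth.

## Worked example

```
sexmark simulate --preset wgs-xy --seed 9 --out-dir demo \
    --chrom-len 150000 --segments 4 --n-reads 40000
sexmark extract --chr-x demo/chrX.fa --chr-y demo/chrY.fa --out demo/run
sexmark call --markers demo/run.markers.fa --reads demo/reads.fastq \
    --system XY --out demo/report.tsv
```

The `extract` step prints a catalog summary:

```
4 marker pairs | length mean 262 range 231-288 | mismatches mean 29 range 24-42
```

i.e. four X/Y window pairs were found, averaging 262 alignment columns and
29 diagnostic sites each. The `call` step prints one line per sample:

```
reads	HETEROGAMETIC	male	fraction=0.4703	hits=107/95	ok
```

107 reads hit X members and 95 hit Y members; the dominant fraction
0.4703 is ≥ 0.2, so this simulated XY sample is called male; with
`--system ZW` the same 1:1 ratio would mean a ZW female. An XX sample
shows `fraction=0.0000` and is called female. For real data, point
`--chr-x/--chr-y` at reference sex chromosomes (add `--autosomes` for the
uniqueness screen) and `--reads` at any FASTQ(.gz).

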