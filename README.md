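# anchorcons

Anchored-consensus assembly and analysis of tandem-repeat (macrosatellite)
loci from noisy long reads.

## The problem and the idea

Macrosatellite arrays — tandem repeats with unit lengths in the kilobase
range, such as the GC-rich D4Z4 repeat whose copy-number contraction causes
facioscapulohumeral muscular dystrophy — defeat ordinary read mapping:
a read that lies entirely inside the array matches every unit almost
equally well, so its placement, and therefore any per-unit consensus, is
arbitrary. Long single-molecule reads span enough sequence to help, but
carry indel-dominated errors of up to ~15%, so no single read is a usable
reference either.

The approach implemented here sidesteps placement entirely:

1. **Anchor selection.** Only reads containing one of the two *unique*
   flanking sequences (NDE-like on the 5' side, pLAM-like on the 3' side)
   are used. Each such read is trimmed to start at its flank hit and
   oriented so the anchor sits at the 5' end with the array running 3' of
   it; 3'-flank reads are stored reverse-complemented so both groups read
   *into* the array from known unique sequence.
2. **Left-anchored star alignment.** Because every read in a group starts
   at the same locus position, a multiple alignment needs no placement
   search: reads are stacked against a backbone draft with banded
   affine-gap alignment, rows pinned at their anchor offsets, and read
   insertions expanded into columns; one refinement pass re-aligns all
   reads against the first-pass plurality consensus.
3. **Threshold consensus.** Each column is called by plurality with the
   column *depth* (reads still extending that far from the anchor) as the
   denominator; a winning base is accepted when its fraction reaches a
   threshold in the low teens (default 0.14), appropriate for raw
   single-molecule error profiles where indels spread support thin. The
   consensus extends until coverage or confidence collapses, giving one
   high-accuracy contig per anchor.

Companion modules provide the surrounding toolchain: a ground-truth
simulator with a realistic indel-dominated error model, repeat-unit
segmentation and pairwise comparison, dot plots, degenerate-motif scans,
in-silico restriction digests, copy-number estimation at half-unit
resolution, and read-set QC (N50, GC distributions, positional quality,
coverage profiles).

## Worked example

`examples/02_anchored_consensus.py` simulates the standard benchmark —
a 6.5-copy array of 500 bp units (70% GC, 2% inter-unit divergence)
between 500 bp unique flanks, sequenced as 60 reads of mean 3 kb at 10%
total error (7% insertion / 2% deletion / 1% substitution, seed 42) — and
runs the full method:

```
anchored reads: 18 at the 5' flank, 18 at the 3' flank
5' stack: 18 rows x 5992 columns
consensus lengths: 3941 (5'), 3517 (3')
identity to truth over the first 3 units: 99.272% (5'), 99.139% (3')
```

Both consensus contigs reconstruct the first three repeat units at over
99% identity from reads that are individually 10% wrong. With zero-error
reads (seed 1) both consensi are exact substrings of the truth, and
segmenting the truth with the unit template returns the full 6.5 copies.

Copy number can also be read from region length alone
(`examples/05_digest_and_copy_number.py`):

```
region 48000 bp with 3450 bp of flanks -> 13.5 copies
EcoRV on AAAGATATCAAA -> [6, 6]
```

The other examples cover simulation (`01`), unit comparison, dot plots and
motif conservation (`03`), and read QC (`04`).

## Command line

The CLI is a thin wrapper over the library; every stage also works on
plain files so stages can be rerun or substituted individually:

```sh
anchorcons simulate --seed 42 --unit-length 500 --n-copies 6.5 --outdir sim/
anchorcons select --reads sim/reads.fastq --flank5 sim/flank5.fasta \
                  --flank3 sim/flank3.fasta --outdir sel/
anchorcons msa --selected sel/selected.flank5.fasta \
               --anchor-fasta sim/flank5.fasta --out aln5.afa
anchorcons consensus --alignment aln5.afa --out cons5.fasta
anchorcons analyze --sequence cons5.fasta --probe sim/probe.fasta --outdir analysis/
anchorcons qc --reads sim/reads.fastq --outdir qc/
anchorcons run --config config.yaml --seed 42 --outdir run/   # all stages
```

`run` writes every stage output plus `summary.json`; re-running with the
same config is byte-identical, and all outputs carry the config hash.

## Library layout

| module | contents |
| --- | --- |
| `anchorcons.seqio` | FASTA/FASTQ/BED I/O (Biopython-backed), records, intervals, revcomp |
| `anchorcons.synthetic_data` | ground-truth array builder, error model, read sampler |
| `anchorcons.align` | banded affine-gap global alignment, seeded local alignment |
| `anchorcons.anchor_select` | flank-anchored read selection, trimming, orientation |
| `anchorcons.anchored_msa` | left-anchored star alignment, column matrix |
| `anchorcons.consensus` | threshold consensus calling, support profiles |
| `anchorcons.repeat_analysis` | unit segmentation, pairwise comparison, dot plots, motifs, digests, copy number |
| `anchorcons.qc` | N50/length stats, GC distributions, positional quality, coverage |
| `anchorcons.pipeline` | config-driven end-to-end runner |

See `docs/methods.md` for the model, algorithms, parameter choices and
limitations.

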