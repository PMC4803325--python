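# Methods

## Locus model

A simulated locus is `[inverted distractor + spacer] + flank5 + unit array
+ flank3`. The unit template is drawn i.i.d. with a configurable GC bias
(default 0.70, macrosatellite-like); each copy derives from the template by
independent substitutions at the inter-unit divergence rate (default 1%,
benchmark 2%). Copy number is specified in half-unit steps; a fractional
copy is the distal-most unit truncated at its 3' side, matching how
truncated terminal units are described for real arrays. The optional
distractor is a reverse-complemented mutated unit copy upstream of the 5'
flank (a DUX4c-like mapping decoy). Flanks are unbiased random sequence
and must be ≥ 100 bp to be usable as anchors.

## Read model

Reads are sampled uniformly from both strands: the start is uniform *on
the sampled strand* and the length log-normal (σ = 0.55, configurable
mean), truncated at the configured maximum and at that strand's molecule
end, so both edges of the locus are reached symmetrically. An earlier
forward-strand-only formulation starved 5'-flank coverage and biased the
anchor groups; the symmetric form fixed this. σ = 0.55 gives a long right
tail (the maximum of tens of thousands of draws reaches ~6–7× the mean),
the shape of filtered single-molecule subread length distributions.

Errors are independent per position: deletion (default 2%), substitution
to a random different base (1%), and insertion of a random base after the
position (7%) — insertion-dominated, as in raw single-molecule reads. The
summed rate is capped at 15% (configurable), the worst-case error level of
the emulated technology. Read ids carry the true interval and strand so
every downstream stage can be tested against ground truth. The realized
edit-distance rate is measured, not assumed: the acceptance suite checks
it stays within ±20% relative of the configured total.

## Anchored selection

Each flank is located in each read by seeded local alignment: exact
13-mer seeds, diagonal clustering (tolerance 40), banded Smith–Waterman
extension. A read joins a group when the best hit reaches 85% identity
over ≥ 60% of the flank. Reads are searched in both orientations with a
lexicographic orientation order so the outcome is invariant under
reverse-complementing the input (verified by test). The 5' group is
stored in locus-forward orientation; the 3' group is stored
reverse-complemented, so both groups begin with unique sequence and read
into the array. A read hitting both flanks joins both groups. Trimming
keeps the read from the flank-hit start; the position *within* the flank
where the read begins is kept as its anchor offset.

## Alignment engine

Pairwise alignment is a hand-written banded Gotoh (affine gaps; defaults
match +2 / mismatch −4 / gap open −4 / gap extend −2; a gap of length k
costs open + k·extend), row-vectorized with numpy; the gap-in-a state is
computed per row in closed form with a running prefix maximum. The band
starts near |len(a) − len(b)| and doubles whenever the optimal path
touches a band edge, so reported optima are exact (validated against an
external edit-distance oracle under unit costs). Variants: free trailing
gaps (`free_end`) and a free alignment start anywhere in the second
sequence (`free_start_b`, band centred on an expected offset) — the
combination used to pin reads at their anchor offsets. Local alignment
reports identity as matches / alignment columns.

## Left-anchored star alignment

The longest read serves as backbone; when other rows start earlier inside
the flank, the anchor sequence scaffolds the columns to the backbone's
left. Every read is aligned to the draft with free trailing gaps and a
free, offset-centred start; insertions are expanded into dedicated columns
(one slot block before each draft position, sized by the largest insertion
observed there). A single refinement pass re-aligns all reads against the
first-pass plurality consensus, with anchor offsets remapped through the
emitted-column index. Rows are contiguous blocks pinned at their anchor
offsets; cells beyond a read's span are an explicit *missing* state,
distinct from alignment gaps, so column depth means "molecules extending
this far". Placement correctness relies on each read starting with unique
anchor sequence; a pure-repeat read has co-optimal placements at every
period and is exactly what anchored selection excludes.

## Threshold consensus

Per column, the plurality character wins; a gap loses ties to any base and
base ties break alphabetically (a fixed, documented convention). A
winning base is emitted if its fraction of the column depth reaches the
threshold (default 0.14; thresholds in the low teens suit ~10–15% raw
error where indels thin out per-column support), otherwise the column
emits N; a winning gap emits nothing. Calling starts at the first column
reaching the minimum depth (default 3) and stops at the first
50-column window that is entirely below minimum depth or majority-N, then
trims back to the last confident base. The depth denominator — rather
than total read count — keeps one threshold meaningful as coverage decays
with distance from the anchor.

## Repeat analysis and QC

Unit segmentation tiles a sequence with non-overlapping probe hits
(greedy by score, ≥ 80% identity, ≥ 30% probe coverage; < 85% coverage
flags a partial unit; reverse-strand hits are reported as inverted
distractors, not units). Copy number is full units + 0.5 per partial.
Pairwise unit comparison uses optimal global alignment with gap columns
counted as differences (stated in the output, since conventions differ
between tools); the comparison is made symmetric by canonicalizing the
argument order before aligning, so co-optimal alignments cannot make
identity(a,b) ≠ identity(b,a). Copy-number-from-length rounds
(region − flanks) / unit to the nearest half unit; the flank total is
model-dependent and surfaced as an explicit argument. Digests cut at
every recognition-site occurrence on both strands (midpoint cut by
default; fragment lengths provably sum to the input length). N50 is the
largest L such that reads ≥ L hold at least half of all bases, computed
by descending cumulative sums and checked against brute force.

## Numerical and engineering choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; pipeline outputs are byte-identical across reruns and embed a
  hash of the canonicalized config.
- Alignment matrices are uint8 column stacks; scores use large-magnitude
  integer sentinels rather than floating-point infinities.
- The external alignment library used in testing is an oracle only; the
  implementation shipped here is self-contained.
- Coverage profiling extends only the two strongest seed clusters per
  read with a band of length/8 — enough to recover the best placement and
  a runner-up score for the ambiguity flag at a fraction of the cost of
  exhaustive extension.

## Limitations

- The error model is i.i.d. per position; real single-molecule errors are
  burstier and context-dependent (e.g. homopolymer length errors), so
  consensus accuracy here is an optimistic bound at equal total rate.
- Inter-unit divergence is substitution-only; real arrays also differ by
  small indels and rearrangements between copies.
- Consensus length is limited by read length: each anchor contig covers
  only the units reachable from its flank at the minimum depth, so large
  arrays are recovered at their edges, not bridged (as with the real
  protocol, interior units of a long array remain unresolved unless reads
  span them).
- The star alignment refines once against a draft consensus; it is not an
  iterative EM/POA scheme and can retain backbone-biased gap placement in
  low-depth columns.
- Half-unit copy calling assumes the truncated unit is the distal one and
  covers 30–85% of the probe; other truncation geometries would be
  misclassified.
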