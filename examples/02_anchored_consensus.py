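"""Anchored consensus: select flank-anchored reads, stack them in a
left-anchored star alignment, and call a threshold consensus.

Reads inside a near-identical tandem array cannot be placed uniquely, but
reads containing a unique flank can.  Each flank defines a read group; all
group members are trimmed at the flank hit, oriented so the anchor sits at
the 5' end, and stacked with every row pinned at its anchor offset.
"""

from anchorcons import (
    ArraySpec, ErrorModel, build_array, build_msa, call_consensus,
    revcomp, sample_reads, select_anchored_reads,
)
from anchorcons.align import region_identity

spec = ArraySpec(unit_length=500, n_copies=6.5, inter_unit_divergence=0.02,
                 flank5_length=500, flank3_length=500, seed=42)
model = ErrorModel(insertion_rate=0.07, deletion_rate=0.02,
                   substitution_rate=0.01, read_length_mean=3000, seed=42)
truth = build_array(spec)
reads = sample_reads(truth, model, 60)
flank5 = truth.full_sequence[truth.flank5.start : truth.flank5.end]
flank3 = truth.full_sequence[truth.flank3.start : truth.flank3.end]

group5, group3, report = select_anchored_reads(reads, flank5, flank3)
print(f"anchored reads: {len(group5)} at the 5' flank, {len(group3)} at the 3' flank")

# the 3' group is stored reverse-complemented, so its anchor is revcomp(flank3)
matrix5 = build_msa(group5, anchor=flank5)
matrix3 = build_msa(group3, anchor=revcomp(flank3))
print(f"5' stack: {matrix5.n_rows} rows x {matrix5.n_cols} columns")

consensus5 = call_consensus(matrix5, threshold=0.14).sequence
consensus3 = call_consensus(matrix3, threshold=0.14).sequence
print(f"consensus lengths: {len(consensus5)} (5'), {len(consensus3)} (3')")

# score each consensus against the truth over the first 3 units it covers
region5 = (truth.flank5.end, truth.flank5.end + 3 * spec.unit_length)
id5 = region_identity(consensus5, truth.full_sequence, region5)
rc = revcomp(truth.full_sequence)
off = len(truth.full_sequence) - truth.flank3.end + len(flank3)
id3 = region_identity(consensus3, rc, (off, off + 3 * spec.unit_length))
print(f"identity to truth over the first 3 units: {id5:.3%} (5'), {id3:.3%} (3')")
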