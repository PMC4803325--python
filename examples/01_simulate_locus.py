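"""Simulate a macrosatellite-like locus and a noisy long-read dataset.

The locus is a tandem array of GC-rich units with small inter-unit
divergence, bracketed by unique flanks; reads come from both strands with
log-normal lengths and an indel-dominated error model.
"""

from anchorcons import ArraySpec, ErrorModel, build_array, read_stats, sample_reads

spec = ArraySpec(
    unit_length=500,
    n_copies=6.5,              # 6 full units + one 3'-truncated half unit
    unit_gc=0.70,
    inter_unit_divergence=0.02,
    flank5_length=500,
    flank3_length=500,
    seed=42,
)
truth = build_array(spec)
print(f"locus length: {len(truth.full_sequence)} bp")
print(f"true copy number: {truth.n_copies}")
for _, interval, _ in truth.units:
    print(f"  {interval.name}: [{interval.start}, {interval.end})")

model = ErrorModel(
    insertion_rate=0.07, deletion_rate=0.02, substitution_rate=0.01,
    read_length_mean=3000, seed=42,
)
reads = sample_reads(truth, model, 60)
stats = read_stats(reads)
print(f"\n{stats.n_reads} reads, {stats.n_bases} bases, "
      f"N50 {stats.n50_length}, longest {stats.max_length}")
print("read ids carry the ground truth, e.g.:", reads[0].id)
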