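"""Read-set QC: length statistics, GC split by locus region, coverage.

GC content separates repeat-derived reads (GC-rich units) from flank reads;
the coverage profile against a consensus shows depth decaying with distance
from the anchor and flags ambiguous repeat placements.
"""

from anchorcons import (
    ArraySpec, ErrorModel, build_array, coverage_profile, gc_distribution,
    read_stats, sample_reads, select_anchored_reads, build_msa, call_consensus,
)
from anchorcons.synthetic_data import parse_read_id

spec = ArraySpec(unit_length=500, n_copies=6.5, unit_gc=0.70,
                 flank5_length=500, flank3_length=500, seed=11)
model = ErrorModel(read_length_mean=2500, seed=11)
truth = build_array(spec)
reads = sample_reads(truth, model, 50)

stats = read_stats(reads)
print(f"{stats.n_reads} reads, mean {stats.mean_length:.0f} bp, "
      f"N50 {stats.n50_length} bp")

# label reads by their true origin (possible here because ids carry truth)
labels = {}
for r in reads:
    meta = parse_read_id(r.id)
    mid = meta["start"] + meta["len"] // 2
    labels[r.id] = "repeat" if truth.flank5.end <= mid < truth.flank3.start else "flank"
gc = gc_distribution(reads, region_labels=labels)
for label, d in sorted(gc.items()):
    print(f"GC of {label:>6} reads: mean {d['mean']:.3f} sd {d['sd']:.3f} (n={d['n']})")

flank5 = truth.full_sequence[truth.flank5.start : truth.flank5.end]
flank3 = truth.full_sequence[truth.flank3.start : truth.flank3.end]
g5, _, _ = select_anchored_reads(reads, flank5, flank3)
consensus = call_consensus(build_msa(g5, anchor=flank5)).sequence
cov = coverage_profile(reads, consensus)
print(f"coverage vs 5' consensus: {cov.n_mapped} mapped, "
      f"{cov.n_unmapped} unmapped, {cov.n_multi_hit} ambiguous, "
      f"mean depth {cov.depth.mean():.1f}")
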