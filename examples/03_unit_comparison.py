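"""Decompose a locus into repeat units and compare them pairwise.

Unit boundaries come from non-overlapping probe hits; pairwise identities
use optimal global alignment with gap columns counted as differences.
A dot plot of the array against itself shows the tandem periodicity, and a
degenerate-motif scan reports positions conserved across every unit.
"""

from anchorcons import (
    ArraySpec, build_array, compare_all_units, count_copies, dotplot,
    scan_motifs, segment_units,
)

truth = build_array(ArraySpec(unit_length=500, n_copies=4.5,
                              inter_unit_divergence=0.02, seed=7))
seg = segment_units(truth.full_sequence, truth.unit_template)
print(f"{len(seg.intervals)} unit intervals, copy number {count_copies(seg)}")

units = {
    iv.name: truth.full_sequence[iv.start : iv.end]
    for i, iv in enumerate(seg.intervals)
    if not seg.partial_flags[i]
}
table = compare_all_units(units)
print("\npairwise unit identities (gaps count as differences):")
print(table.to_string(index=False))

array = truth.full_sequence[truth.flank5.end : truth.flank3.start]
points = dotplot(array[:1000], array[:1000], window=20)
diagonals = {j - i for i, j in points}
print(f"\ndot plot of the first 1 kb against itself: {len(points)} points; "
      f"off-diagonals near the unit length: "
      f"{sorted(d for d in diagonals if 450 <= d <= 550)[:5]}")

hits, conserved = scan_motifs(units, [("GC-box", "GGGCGG"), ("E-box", "CANNTG")])
print(f"\nmotif hits: {len(hits)}; positions conserved in every unit: "
      f"{len(conserved)}")
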