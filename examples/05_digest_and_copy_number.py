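"""Copy number two ways: in-silico restriction digest and region length.

The classical assay sizes the repeat region on a gel after cutting with
enzymes that flank the array; the region length then implies the copy
number at half-unit resolution once the flank contribution is subtracted.
"""

from anchorcons import (
    ArraySpec, build_array, estimate_copies_from_length, in_silico_digest,
)

truth = build_array(ArraySpec(unit_length=3300, n_copies=13.5,
                              flank5_length=2000, flank3_length=1450, seed=3))
print(f"locus: {len(truth.full_sequence)} bp, true copies {truth.n_copies}")

fragments = in_silico_digest(truth.full_sequence, [("BamHI", "GGATCC")])
print(f"BamHI digest: {len(fragments)} fragments, largest {max(fragments)} bp, "
      f"sum {sum(fragments)} bp (= locus length)")

# worked mid-site example: EcoRV cuts GAT^ATC bluntly in the middle
print("EcoRV on AAAGATATCAAA ->", in_silico_digest("AAAGATATCAAA",
                                                   [("EcoRV", "GATATC")]))

region = truth.flank3.end - truth.flank5.start
copies = estimate_copies_from_length(region, 3300, 2000 + 1450)
print(f"region {region} bp with 3450 bp of flanks -> {copies} copies")
print("published-style reading:",
      estimate_copies_from_length(48_000, 3_300, 3_450), "copies from a 48 kb region")
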