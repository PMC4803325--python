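import re

import numpy as np
import pytest

from anchorcons import (
    ArraySpec,
    Scoring,
    build_array,
    compare_all_units,
    compare_units,
    count_copies,
    dotplot,
    estimate_copies_from_length,
    in_silico_digest,
    revcomp,
    scan_motifs,
    segment_units,
)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# --- segmentation ----------------------------------------------------------

def test_segmentation_recovers_truth_units():
    truth = build_array(ArraySpec(unit_length=500, n_copies=4.5,
                                  inter_unit_divergence=0.02, seed=21))
    seg = segment_units(truth.full_sequence, truth.unit_template)
    assert count_copies(seg) == 4.5
    assert sum(seg.partial_flags) == 1
    starts = [iv.start for iv in seg.intervals]
    true_starts = [iv.start for _, iv, _ in truth.units]
    assert all(abs(a - b) < 30 for a, b in zip(starts, true_starts))


def test_segmentation_reports_inverted_distractor():
    truth = build_array(ArraySpec(unit_length=500, n_copies=3,
                                  include_inverted_distractor=True, seed=22))
    seg = segment_units(truth.full_sequence, truth.unit_template)
    assert count_copies(seg) == 3.0
    assert len(seg.distractors) == 1
    d = seg.distractors[0]
    assert abs(d.start - truth.distractor.start) < 30
    assert d.strand == "-"


def test_segmentation_rejects_short_probe():
    with pytest.raises(ValueError):
        segment_units("ACGT" * 100, "ACGT" * 10)


# --- pairwise unit comparison ---------------------------------------------

def test_compare_units_self_identity():
    rng = np.random.default_rng(0)
    s = _random_seq(rng, 120)
    c = compare_units(s, s)
    assert c.percent_identity == 100.0
    assert c.differences == 0
    assert c.alignment_columns == 120


def test_compare_units_counts_gaps_as_differences():
    c = compare_units("AAAATTTT", "AAAACCTTTT")
    # best alignment: 8 matches plus a 2-base gap = 10 columns, 2 differences
    assert c.alignment_columns == 10
    assert c.differences == 2
    assert c.percent_identity == 80.0


def test_compare_units_symmetry():
    rng = np.random.default_rng(1)
    for _ in range(30):
        a = _random_seq(rng, int(rng.integers(10, 60)))
        b = _random_seq(rng, int(rng.integers(10, 60)))
        ab, ba = compare_units(a, b), compare_units(b, a)
        assert ab.percent_identity == ba.percent_identity
        assert ab.differences == ba.differences


def test_compare_all_units_table_shape():
    units = {"u1": "ACGTACGTAC", "u2": "ACGTACCTAC", "u3": "ACGTACGTAC"}
    table = compare_all_units(units)
    assert len(table) == 3  # all unordered pairs
    row = table[(table.unit_a == "u1") & (table.unit_b == "u3")].iloc[0]
    assert row.percent_identity == 100.0


# --- dot plot --------------------------------------------------------------

def _dotplot_oracle(a, b, window, min_matches):
    out = set()
    for i in range(len(a) - window + 1):
        for j in range(len(b) - window + 1):
            m = sum(1 for k in range(window) if a[i + k] == b[j + k])
            if m >= min_matches:
                out.add((i, j))
    return out


def test_dotplot_matches_brute_force():
    rng = np.random.default_rng(2)
    for _ in range(10):
        a = _random_seq(rng, 60)
        b = _random_seq(rng, 50)
        w = int(rng.integers(4, 9))
        mm = int(rng.integers(w - 2, w + 1))
        assert dotplot(a, b, window=w, min_matches=mm) == _dotplot_oracle(a, b, w, mm)


def test_dotplot_tandem_structure():
    unit = _random_seq(np.random.default_rng(3), 50)
    arr = unit * 3
    pts = dotplot(arr, arr, window=20)
    # the main diagonal plus off-diagonals at multiples of the unit length
    assert (0, 0) in pts and (0, 50) in pts and (0, 100) in pts and (50, 0) in pts


def test_dotplot_rejects_tiny_window():
    with pytest.raises(ValueError):
        dotplot("ACGTACGT", "ACGTACGT", window=3)


# --- motif scanning --------------------------------------------------------

def test_scan_motifs_degenerate_and_overlapping():
    units = {"u1": "ACACACG", "u2": "TTACACG"}
    hits, cons = scan_motifs(units, [("dinuc", "ACAC"), ("iupac", "RCR")])
    u1_dinuc = hits[(hits.unit == "u1") & (hits.motif == "dinuc")].position.tolist()
    assert u1_dinuc == [0, 2]  # overlapping matches both found
    # RCR = [AG]C[AG]: in u1 at 0, 2, 4; in u2 at 2, 4
    assert set(cons[cons.motif == "dinuc"].offset) == {2}
    assert set(cons[cons.motif == "iupac"].offset) == {2, 4}


def test_scan_motifs_rejects_bad_symbol():
    with pytest.raises(ValueError):
        scan_motifs(["ACGT"], [("bad", "ACQT")])


# --- in silico digest ------------------------------------------------------

def test_digest_worked_example_midsite():
    assert in_silico_digest("AAAGATATCAAA", [("EcoRV", "GATATC")]) == [6, 6]


def test_digest_no_site_returns_whole_sequence():
    assert in_silico_digest("AAAA", [("EcoRV", "GATATC")]) == [4]


def test_digest_cuts_reverse_complement_occurrence():
    # GGATCC is palindromic; a non-palindromic site must cut its revcomp too
    seq = "T" * 10 + revcomp("GAATTG") + "T" * 10
    frags = in_silico_digest(seq, [("X", "GAATTG")])
    assert len(frags) == 2
    assert sum(frags) == len(seq)


def test_digest_conserves_length_on_random_input():
    rng = np.random.default_rng(4)
    for _ in range(50):
        seq = _random_seq(rng, int(rng.integers(20, 400)))
        site = _random_seq(rng, 6)
        frags = in_silico_digest(seq, [("E", site)])
        assert sum(frags) == len(seq)
        assert all(f > 0 for f in frags)


def test_digest_rejects_degenerate_site():
    with pytest.raises(ValueError):
        in_silico_digest("ACGT", [("E", "GANTC")])


# --- copy number from length ----------------------------------------------

def test_estimate_copies_half_unit_resolution():
    assert estimate_copies_from_length(48_000, 3_300, 3_450) == 13.5
    assert estimate_copies_from_length(4_250, 500, 1_000) == 6.5
    with pytest.raises(ValueError):
        estimate_copies_from_length(3_000, 3_300, 3_450)
    with pytest.raises(ValueError):
        estimate_copies_from_length(-1, 3_300, 0)
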