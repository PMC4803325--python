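import numpy as np
import pytest

from anchorcons import (
    ArraySpec,
    ErrorModel,
    build_array,
    corrupt,
    revcomp,
    sample_reads,
)
from anchorcons.synthetic_data import parse_read_id


def test_array_structure_and_lengths():
    spec = ArraySpec(unit_length=400, n_copies=3.5, flank5_length=200,
                     flank3_length=300, seed=7)
    truth = build_array(spec)
    expected = 200 + 3 * 400 + 200 + 300  # 3 full units + one half unit
    assert len(truth.full_sequence) == expected
    assert truth.n_copies == 3.5
    names = [iv.name for _, iv, _ in truth.units]
    assert names[-1].endswith("partial")
    assert all(n.endswith("full") for n in names[:-1])
    # intervals tile the declared coordinates and carry the true sequences
    for _, iv, seq in truth.units:
        assert truth.full_sequence[iv.start : iv.end] == seq


def test_integer_copies_have_no_partial_unit():
    truth = build_array(ArraySpec(unit_length=400, n_copies=3, flank5_length=200,
                                  flank3_length=200, seed=7))
    assert truth.n_copies == 3.0
    assert all(iv.name.endswith("full") for _, iv, _ in truth.units)


def test_unit_gc_is_respected():
    truth = build_array(ArraySpec(unit_length=5000, n_copies=1, unit_gc=0.70, seed=3))
    gc = (truth.unit_template.count("G") + truth.unit_template.count("C")) / 5000
    assert abs(gc - 0.70) < 0.02


def test_inter_unit_divergence_calibration():
    spec = ArraySpec(unit_length=2000, n_copies=4, inter_unit_divergence=0.02, seed=5)
    truth = build_array(spec)
    for _, _, seq in truth.units:
        diff = sum(1 for x, y in zip(seq, truth.unit_template) if x != y)
        assert 0.01 < diff / 2000 < 0.035  # ~2% substitutions, binomial spread


def test_inverted_distractor_is_reverse_oriented_copy():
    spec = ArraySpec(unit_length=500, n_copies=2, include_inverted_distractor=True,
                     distractor_offset=300, seed=11)
    truth = build_array(spec)
    assert truth.distractor is not None
    d = truth.full_sequence[truth.distractor.start : truth.distractor.end]
    fwd = revcomp(d)
    diff = sum(1 for x, y in zip(fwd, truth.unit_template) if x != y)
    assert diff / len(fwd) < 0.05  # a mutated copy of the template, inverted
    assert truth.flank5.start == truth.distractor.end + 300


def test_build_array_is_deterministic():
    a = build_array(ArraySpec(seed=9, unit_length=300, n_copies=2))
    b = build_array(ArraySpec(seed=9, unit_length=300, n_copies=2))
    assert a.full_sequence == b.full_sequence


def test_spec_validation():
    with pytest.raises(ValueError):
        ArraySpec(n_copies=3.3)
    with pytest.raises(ValueError):
        ArraySpec(inter_unit_divergence=0.5)
    with pytest.raises(ValueError):
        ArraySpec(flank5_length=50)


def test_error_model_rejects_rates_over_ceiling():
    with pytest.raises(ValueError):
        ErrorModel(insertion_rate=0.10, deletion_rate=0.05, substitution_rate=0.05)
    ErrorModel(insertion_rate=0.10, deletion_rate=0.05, substitution_rate=0.05,
               max_total_rate=0.25)


def test_corrupt_zero_rates_is_identity():
    model = ErrorModel(insertion_rate=0, deletion_rate=0, substitution_rate=0, seed=1)
    s = "ACGT" * 100
    assert corrupt(s, model) == s


def test_corrupt_changes_length_as_expected():
    rng = np.random.default_rng(0)
    model = ErrorModel(insertion_rate=0.07, deletion_rate=0.02,
                       substitution_rate=0.01, seed=0)
    s = "".join(rng.choice(list("ACGT"), size=20000))
    out = corrupt(s, model, np.random.default_rng(0))
    # expected net growth = (ins - del) * len = 5% of 20 kb = 1000
    assert 700 < len(out) - len(s) < 1300


def test_sample_reads_ids_encode_true_coordinates():
    truth = build_array(ArraySpec(unit_length=500, n_copies=3, seed=2))
    model = ErrorModel(insertion_rate=0, deletion_rate=0, substitution_rate=0,
                       read_length_mean=800, seed=2)
    reads = sample_reads(truth, model, 30)
    for r in reads:
        meta = parse_read_id(r.id)
        frag = truth.full_sequence[meta["start"] : meta["start"] + meta["len"]]
        if meta["strand"] == "-":
            frag = revcomp(frag)
        assert r.sequence == frag  # zero-error reads equal the true fragment


def test_sample_reads_uses_both_strands_and_is_deterministic():
    truth = build_array(ArraySpec(unit_length=500, n_copies=3, seed=2))
    model = ErrorModel(read_length_mean=800, seed=3)
    reads = sample_reads(truth, model, 60)
    strands = {parse_read_id(r.id)["strand"] for r in reads}
    assert strands == {"+", "-"}
    again = sample_reads(truth, model, 60)
    assert [r.sequence for r in reads] == [r.sequence for r in again]


def test_read_lengths_are_capped():
    truth = build_array(ArraySpec(unit_length=3300, n_copies=10, seed=4))
    model = ErrorModel(read_length_mean=4500, read_length_max=6000, seed=4)
    reads = sample_reads(truth, model, 100)
    # realized length <= cap * (1 + total error head-room)
    assert max(len(r) for r in reads) <= 6000 * 1.2
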