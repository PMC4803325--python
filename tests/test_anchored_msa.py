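import numpy as np
import pytest

from anchorcons import AnchoredRead, FLANK5, build_msa, read_afa, write_afa
from anchorcons.anchored_msa import GAP, MISSING, ColumnMatrix


def _mk(read_id, seq, offset=0):
    return AnchoredRead(read_id=read_id, anchor=FLANK5, trimmed_sequence=seq,
                        original_strand="+", anchor_identity=1.0,
                        anchor_offset=offset)


def test_rows_reconstruct_their_reads(perfect_run):
    """Removing gaps and missing cells from any row yields the input read."""
    for matrix, group in (
        (perfect_run.matrix5, perfect_run.group5),
        (perfect_run.matrix3, perfect_run.group3),
    ):
        by_id = {ar.read_id: ar.trimmed_sequence for ar in group}
        for i, rid in enumerate(matrix.row_ids):
            assert matrix.ungapped_row(i) == by_id[rid]


def test_rows_are_contiguous_blocks(perfect_run):
    for matrix in (perfect_run.matrix5, perfect_run.matrix3):
        for i in range(matrix.n_rows):
            row = matrix.data[i]
            nz = np.nonzero(row != MISSING)[0]
            assert len(nz) > 0
            # no missing cell inside the covered span
            assert np.all(row[nz[0] : nz[-1] + 1] != MISSING)


def test_identical_reads_stack_without_gaps():
    seq = "ACGTTGCA" * 25
    group = [_mk(f"r{i}", seq) for i in range(5)]
    matrix = build_msa(group)
    assert matrix.n_cols == len(seq)
    assert not np.any(matrix.data == GAP)
    for i in range(5):
        assert matrix.ungapped_row(i) == seq


def test_offset_rows_pin_at_their_anchor_position():
    anchor = "ACGTACGTGGCCAATT" * 20  # 320 bp
    tail = "TTGACCAGTT" * 10
    full = anchor + tail
    group = [
        _mk("r0", full, offset=0),
        _mk("r1", full[50:], offset=50),
        _mk("r2", full[120:], offset=120),
    ]
    matrix = build_msa(group, anchor=anchor)
    assert matrix.n_cols == len(full)
    depth = matrix.depth()
    assert depth[0] == 1 and depth[50] == 2 and depth[120] == 3
    # all three rows agree wherever they overlap
    for col in range(120, len(full)):
        vals = {matrix.data[i, col] for i in range(3)}
        assert len(vals) == 1


def test_depth_counts_only_covering_reads():
    # non-periodic sequence: anchored reads start with unique flank content,
    # which is what pins a short read at offset 0 among its placements
    rng = np.random.default_rng(0)
    full = "".join(rng.choice(list("ACGT"), size=120))
    group = [_mk("a", full), _mk("b", full[:40])]
    matrix = build_msa(group)
    depth = matrix.depth()
    assert depth[0] == 2
    assert depth[-1] == 1


def test_single_read_group():
    matrix = build_msa([_mk("only", "ACGTACGTAC" * 12)])
    assert matrix.n_rows == 1
    assert matrix.ungapped_row(0) == "ACGTACGTAC" * 12


def test_empty_group_raises():
    with pytest.raises(ValueError):
        build_msa([])


def test_mixed_anchor_group_raises():
    a = _mk("a", "ACGT" * 30)
    b = AnchoredRead("b", "FLANK3", "ACGT" * 30, "+", 1.0)
    with pytest.raises(ValueError):
        build_msa([a, b])


def test_afa_round_trip(tmp_path, perfect_run):
    p = tmp_path / "aln.afa"
    write_afa(perfect_run.matrix5, p)
    back = read_afa(p)
    assert back.row_ids == perfect_run.matrix5.row_ids
    assert np.array_equal(back.data, perfect_run.matrix5.data)


def test_msa_is_deterministic(perfect_run):
    again = build_msa(perfect_run.group5, anchor=perfect_run.flank5)
    assert np.array_equal(again.data, perfect_run.matrix5.data)
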