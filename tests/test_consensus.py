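import numpy as np
import pytest

from anchorcons import call_consensus
from anchorcons.anchored_msa import ColumnMatrix


def _matrix(rows):
    """Build a ColumnMatrix from strings over A,C,G,T,-,. ('.' = missing)."""
    data = np.zeros((len(rows), len(rows[0])), dtype=np.uint8)
    for i, row in enumerate(rows):
        for j, ch in enumerate(row):
            data[i, j] = 0 if ch == "." else ord(ch)
    return ColumnMatrix(row_ids=[f"r{i}" for i in range(len(rows))], data=data)


def test_unanimous_columns():
    m = _matrix(["ACGT", "ACGT", "ACGT"])
    assert call_consensus(m, min_depth=1).sequence == "ACGT"


def test_low_fraction_winner_emits_n():
    # column 0: A wins with 2/6 = 0.33 -> called at threshold 0.14, N at 0.5
    m = _matrix(["A", "A", "C", "G", "T", "T"])
    assert call_consensus(m, threshold=0.14, min_depth=1).sequence == "A"
    assert call_consensus(m, threshold=0.5, min_depth=1).sequence == "N"


def test_gap_plurality_emits_nothing():
    m = _matrix(["A-C", "A-C", "AAC", "A-C"])
    assert call_consensus(m, min_depth=1).sequence == "AC"


def test_gap_loses_ties_to_bases():
    m = _matrix(["A-", "AC", "A-", "AC"])  # column 1: 2 gaps vs 2 C
    assert call_consensus(m, min_depth=1).sequence == "AC"


def test_base_ties_break_alphabetically():
    m = _matrix(["AG", "AT", "AG", "AT"])  # column 1: G and T tie at 2
    assert call_consensus(m, min_depth=1).sequence == "AG"


def test_depth_is_the_denominator_not_row_count():
    # column 2 is covered by only 2 of 6 rows; the winner has 2/2 = 1.0
    rows = ["ACG", "ACG", "AC.", "AC.", "AC.", "AC."]
    m = _matrix(rows)
    res = call_consensus(m, threshold=0.5, min_depth=1)
    assert res.sequence == "ACG"
    assert res.per_column[2].depth == 2
    assert res.per_column[2].winner_fraction == 1.0


def test_calling_starts_at_first_sufficiently_deep_column():
    rows = [
        "ACGTACGT",
        "..GTACGT",
        "..GTACGT",
    ]
    m = _matrix(rows)
    res = call_consensus(m, min_depth=3)
    assert res.sequence == "GTACGT"
    assert res.per_column[0].column == 2


def test_stop_on_sustained_low_depth_trims_to_last_confident_base():
    deep = "ACGTACGTAC"
    rows = [
        deep + "G" * 40,
        deep + "." * 40,
        deep + "." * 40,
    ]
    m = _matrix(rows)
    res = call_consensus(m, min_depth=3, stop_window=20)
    assert res.sequence == deep
    assert res.stopped_at_column is not None


def test_invalid_threshold_rejected():
    m = _matrix(["ACGT"])
    for t in (0.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            call_consensus(m, threshold=t)


def test_empty_matrix_rejected():
    with pytest.raises(ValueError):
        call_consensus(ColumnMatrix(row_ids=[], data=np.zeros((0, 0), dtype=np.uint8)))


def test_threshold_monotonicity_on_random_matrices():
    rng = np.random.default_rng(0)
    letters = "ACGT-"
    for _ in range(30):
        rows = []
        n_cols = int(rng.integers(10, 40))
        for _ in range(int(rng.integers(2, 10))):
            span = int(rng.integers(5, n_cols + 1))
            row = "".join(rng.choice(list(letters), size=span)) + "." * (n_cols - span)
            rows.append(row)
        m = _matrix(rows)
        called = []
        for t in (0.05, 0.13, 0.14, 0.30, 0.51, 0.9):
            seq = call_consensus(m, threshold=t, min_depth=1,
                                 stop_window=10_000).sequence
            called.append(len(seq) - seq.count("N"))
        assert called == sorted(called, reverse=True)
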