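import numpy as np
import pytest

from anchorcons import Scoring, global_align, local_hits, revcomp
from anchorcons.align import BandOverflowError, best_local_hit, cigar_identity

try:
    import edlib
except ImportError:  # pragma: no cover - oracle library expected in test env
    edlib = None


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _cigar_consistent(aln, a, b):
    """The cigar must consume exactly a[0:a_end] and b[b_start:b_end]."""
    ia = sum(ln for op, ln in aln.cigar if op in "MI")
    ib = sum(ln for op, ln in aln.cigar if op in "MD")
    assert ia == aln.a_end
    assert ib == aln.b_end - aln.b_start


def _score_of(aln, a, b, sc):
    """Recompute the affine score of an alignment from its cigar."""
    score = 0
    i, j = 0, aln.b_start
    for op, ln in aln.cigar:
        if op == "M":
            for k in range(ln):
                score += sc.match if a[i + k] == b[j + k] else sc.mismatch
            i += ln
            j += ln
        else:
            score += sc.gap_open + sc.gap_extend * ln
            if op == "I":
                i += ln
            else:
                j += ln
    return score


@pytest.mark.skipif(edlib is None, reason="edlib oracle not installed")
def test_global_alignment_matches_edlib_distance():
    """With unit costs the optimal score equals -edit distance."""
    rng = np.random.default_rng(0)
    sc = Scoring(match=0, mismatch=-1, gap_open=0, gap_extend=-1)
    for _ in range(200):
        a = _random_seq(rng, int(rng.integers(1, 120)))
        b = _random_seq(rng, int(rng.integers(1, 120)))
        aln = global_align(a, b, scoring=sc)
        dist = edlib.align(a, b, mode="NW")["editDistance"]
        assert aln.score == -dist
        _cigar_consistent(aln, a, b)


def test_cigar_score_agrees_with_reported_score():
    rng = np.random.default_rng(1)
    sc = Scoring()
    for _ in range(50):
        a = _random_seq(rng, int(rng.integers(5, 150)))
        b = _random_seq(rng, int(rng.integers(5, 150)))
        aln = global_align(a, b, scoring=sc)
        assert _score_of(aln, a, b, sc) == aln.score


def test_identical_sequences_align_perfectly():
    s = _random_seq(np.random.default_rng(2), 300)
    aln = global_align(s, s)
    assert aln.cigar == [("M", 300)]
    matches, cols = cigar_identity(aln.cigar, s, s)
    assert matches == cols == 300


def test_free_end_alignment_of_prefix():
    rng = np.random.default_rng(3)
    b = _random_seq(rng, 400)
    a = b[:150]
    aln = global_align(a, b, free_end=True)
    assert aln.cigar == [("M", 150)]
    assert aln.a_end == 150 and aln.b_end == 150


def test_free_start_b_alignment_of_internal_fragment():
    rng = np.random.default_rng(4)
    b = _random_seq(rng, 600)
    a = b[200:380]
    aln = global_align(a, b, free_end=True, free_start_b=True, b_offset=200)
    assert aln.b_start == 200 and aln.b_end == 380
    assert aln.cigar == [("M", 180)]


def test_band_doubling_reaches_optimum_for_shifted_pair():
    # a large indel forces the path far off the diagonal; the adaptive band
    # must widen until the optimum no longer touches the band edge
    rng = np.random.default_rng(5)
    core = _random_seq(rng, 300)
    a = core
    b = _random_seq(rng, 250) + core
    sc = Scoring(match=0, mismatch=-1, gap_open=0, gap_extend=-1)
    aln = global_align(a, b, scoring=sc, band=8)
    if edlib is not None:
        assert aln.score == -edlib.align(a, b, mode="NW")["editDistance"]
    assert aln.score >= -250


def test_band_overflow_raises_when_doubling_disabled():
    rng = np.random.default_rng(6)
    a = _random_seq(rng, 200)
    b = _random_seq(rng, 50) + a
    with pytest.raises(BandOverflowError):
        global_align(a, b, band=4, max_doublings=0)


def test_local_hit_finds_exact_embedded_query():
    rng = np.random.default_rng(7)
    target = _random_seq(rng, 2000)
    query = target[700:1000]
    hits = local_hits(query, target)
    assert hits
    h = hits[0]
    assert (h.target_start, h.target_end) == (700, 1000)
    assert (h.query_start, h.query_end) == (0, 300)
    assert h.identity == 1.0 and h.strand == "+"


def test_local_hit_finds_reverse_strand_query():
    rng = np.random.default_rng(8)
    target = _random_seq(rng, 2000)
    query = revcomp(target[400:700])
    h = best_local_hit(query, target)
    assert h is not None
    assert h.strand == "-"
    assert (h.target_start, h.target_end) == (400, 700)
    assert h.identity == 1.0


def test_local_hit_tolerates_10pct_corruption():
    from anchorcons import ErrorModel, corrupt

    rng = np.random.default_rng(9)
    target = _random_seq(rng, 3000)
    model = ErrorModel(insertion_rate=0.07, deletion_rate=0.02,
                       substitution_rate=0.01, seed=9)
    query = corrupt(target[1000:1500], model, rng)
    h = best_local_hit(query, target, min_identity=0.8)
    assert h is not None
    assert h.identity >= 0.85
    assert abs(h.target_start - 1000) < 30 and abs(h.target_end - 1500) < 30


def test_no_hit_for_unrelated_sequence():
    rng = np.random.default_rng(10)
    assert best_local_hit(_random_seq(rng, 100), _random_seq(rng, 1000)) is None
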