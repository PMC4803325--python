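"""Pairwise alignment engines shared across the package.

Two engines, both affine-gap (Gotoh) and both banded:

* :func:`global_align` — global alignment of two sequences, optionally with
  free trailing gaps (used for stacking left-anchored reads, where both
  sequences start together and end wherever the molecule ended).  The band is
  centred on the straight line from (0, 0) to (m, n), so a systematic length
  difference between the sequences (typical of insertion-dominated long-read
  errors) does not consume the band; if the optimal path touches the band
  edge the band is doubled automatically up to a cap.
* :func:`local_hits` — seeded local (Smith–Waterman) search of a query in a
  long target on both strands: exact k-mer seeds are clustered by diagonal,
  and each cluster is extended by a banded local alignment.

Gap cost convention: a gap of length k costs ``gap_open + k * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Scoring",
    "PairwiseAlignment",
    "LocalHit",
    "BandOverflowError",
    "global_align",
    "local_hits",
    "best_local_hit",
    "cigar_identity",
]

NEG = -(2**40)

_M, _X, _Y, _START = 0, 1, 2, 3


class BandOverflowError(RuntimeError):
    """The optimal alignment path left the band even after doubling."""


@dataclass(frozen=True)
class Scoring:
    """Alignment scoring; defaults are blastn-like and indel-tolerant."""

    match: int = 2
    mismatch: int = -4
    gap_open: int = -4
    gap_extend: int = -2


@dataclass
class PairwiseAlignment:
    """Result of a (semi-)global alignment of a (query) against b (target).

    ``cigar`` ops: ``M`` consumes both (match or mismatch), ``I`` consumes a
    only, ``D`` consumes b only.  With free trailing gaps the alignment may
    stop before either end; ``a_end``/``b_end`` give the consumed prefixes.
    With a free leading gap in b the alignment starts at ``b_start``.
    """

    score: int
    cigar: list[tuple[str, int]]
    a_end: int
    b_end: int
    b_start: int = 0


@dataclass(frozen=True)
class LocalHit:
    """One local alignment of a query inside a target."""

    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str
    identity: float
    score: int
    matches: int
    columns: int


def encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _shift(arr: np.ndarray, off: int) -> np.ndarray:
    """out[k] = arr[k + off], NEG-filled outside."""
    W = arr.shape[0]
    out = np.full(W, NEG, dtype=np.int64)
    if off >= 0:
        if off < W:
            out[: W - off] = arr[off:]
    else:
        if -off < W:
            out[-off:] = arr[: W + off]
    return out


def _compress_cigar(ops: list[str]) -> list[tuple[str, int]]:
    cigar: list[tuple[str, int]] = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return cigar


def _global_banded(
    ac: np.ndarray,
    bc: np.ndarray,
    sc: Scoring,
    band: int,
    free_end: bool,
    free_start_b: bool = False,
    b_offset: int = 0,
) -> tuple[PairwiseAlignment, bool]:
    """One banded pass. Returns (alignment, touched_band_edge)."""
    m, n = len(ac), len(bc)
    go, ge = sc.gap_open, sc.gap_extend

    # band centre: for a fully-global alignment, the (0,0)->(m,n) line; with
    # free trailing gaps the path hugs the unit diagonal until one sequence
    # ends, so a slope above 1 would walk the band away from it.  b_offset
    # shifts the centre when a is known to start ~b_offset into b.
    if free_end:
        slope = min(1.0, max(0, n - b_offset) / m)
    else:
        slope = n / m
    centers = b_offset + np.rint(np.arange(m + 1) * slope).astype(np.int64)
    lo = centers - band
    W = 2 * band + 1
    kidx = np.arange(W, dtype=np.int64)

    ptrM = np.full((m + 1, W), -1, dtype=np.int8)
    ptrX = np.full((m + 1, W), -1, dtype=np.int8)
    ptrY = np.full((m + 1, W), -1, dtype=np.int8)

    # row 0
    js = lo[0] + kidx
    valid = (js >= 0) & (js <= n)
    Mrow = np.full(W, NEG, dtype=np.int64)
    Xrow = np.full(W, NEG, dtype=np.int64)
    Yrow = np.full(W, NEG, dtype=np.int64)
    if free_start_b:
        Mrow[valid] = 0  # alignment may start at (0, j) for any j, free
    else:
        Mrow[js == 0] = 0
        top = valid & (js >= 1)
        Yrow[top] = go + ge * js[top]
        ptrY[0, top] = _Y
        ptrY[0, js == 1] = _M

    # endpoint candidates: (score, i, j, state)
    best_free: tuple[int, int, int, int] | None = None

    def consider(score: int, i: int, j: int, state: int) -> None:
        nonlocal best_free
        if score <= NEG // 2:
            return
        key = (score, i, j)
        if best_free is None or key > (best_free[0], best_free[1], best_free[2]):
            best_free = (score, i, j, state)

    if free_end and n >= lo[0] and n <= lo[0] + W - 1:
        kn = n - lo[0]
        for st, row in ((_M, Mrow), (_X, Xrow), (_Y, Yrow)):
            consider(int(row[kn]), 0, n, st)

    for i in range(1, m + 1):
        sh = int(lo[i] - lo[i - 1])
        Mp = _shift(Mrow, sh)
        Xp = _shift(Xrow, sh)
        Yp = _shift(Yrow, sh)
        Mpd = _shift(Mrow, sh - 1)
        Xpd = _shift(Xrow, sh - 1)
        Ypd = _shift(Yrow, sh - 1)

        js = lo[i] + kidx
        valid = (js >= 0) & (js <= n)

        # substitution scores for j >= 1
        sub = np.full(W, NEG, dtype=np.int64)
        okj = valid & (js >= 1)
        bidx = js[okj] - 1
        sub[okj] = np.where(bc[bidx] == ac[i - 1], sc.match, sc.mismatch)

        stack = np.stack((Mpd, Xpd, Ypd))
        arg = stack.argmax(axis=0)
        Mnew = sub + stack.max(axis=0)
        Mnew[~okj] = NEG
        ptrM[i] = arg.astype(np.int8)

        stack = np.stack((Mp + go + ge, Xp + ge, Yp + go + ge))
        arg = stack.argmax(axis=0)
        Xnew = stack.max(axis=0)
        Xnew[~valid] = NEG
        ptrX[i] = arg.astype(np.int8)

        # Y via prefix-max closed form: Y[k] = go + ge*k' + max_{l<k}(G[l] - ge*l)
        G = np.maximum(Mnew, Xnew)
        H = np.maximum.accumulate(G - ge * kidx)
        Ynew = np.full(W, NEG, dtype=np.int64)
        Ynew[1:] = go + ge * kidx[1:] + H[:-1]
        Ynew[~okj] = NEG
        Ynew = np.maximum(Ynew, NEG)
        # pointers for Y from immediate predecessor at k-1
        openM = np.full(W, NEG, dtype=np.int64)
        openX = np.full(W, NEG, dtype=np.int64)
        ext = np.full(W, NEG, dtype=np.int64)
        openM[1:] = Mnew[:-1] + go + ge
        openX[1:] = Xnew[:-1] + go + ge
        ext[1:] = Ynew[:-1] + ge
        ptrY[i] = np.stack((openM, openX, ext)).argmax(axis=0).astype(np.int8)

        Mrow, Xrow, Yrow = Mnew, Xnew, Ynew

        if free_end and lo[i] <= n <= lo[i] + W - 1:
            kn = n - lo[i]
            for st, row in ((_M, Mrow), (_X, Xrow), (_Y, Yrow)):
                consider(int(row[kn]), i, n, st)

    # choose endpoint
    if free_end:
        js = lo[m] + kidx
        valid = (js >= 0) & (js <= n)
        for k in np.nonzero(valid)[0]:
            j = int(js[k])
            for st, row in ((_M, Mrow), (_X, Xrow), (_Y, Yrow)):
                consider(int(row[k]), m, j, st)
        if best_free is None:
            raise BandOverflowError("no endpoint inside band")
        score, ei, ej, state = best_free
    else:
        kn = n - lo[m]
        if not (0 <= kn < W):
            raise BandOverflowError("global endpoint outside band")
        cands = [(int(row[kn]), st) for st, row in ((_M, Mrow), (_X, Xrow), (_Y, Yrow))]
        score, state = max(cands)
        ei, ej = m, n
        if score <= NEG // 2:
            raise BandOverflowError("no path to endpoint inside band")

    # traceback
    touched = False
    ops: list[str] = []
    i, j, st = ei, ej, state
    while not (i == 0 and (j == 0 or free_start_b)):
        if (j == lo[i] and j > 0) or (j == lo[i] + W - 1 and j < n):
            touched = True
        k = j - lo[i]
        if st == _M:
            prev = int(ptrM[i, k])
            ops.append("M")
            i -= 1
            j -= 1
        elif st == _X:
            prev = int(ptrX[i, k])
            ops.append("I")
            i -= 1
        elif st == _Y:
            prev = int(ptrY[i, k])
            ops.append("D")
            j -= 1
        else:  # pragma: no cover - defensive
            raise BandOverflowError("traceback escaped the band")
        if prev < 0:
            raise BandOverflowError("traceback hit an unreachable cell")
        st = prev
    ops.reverse()
    return (
        PairwiseAlignment(int(score), _compress_cigar(ops), ei, ej, b_start=j),
        touched,
    )


def global_align(
    a: str,
    b: str,
    scoring: Scoring | None = None,
    band: int | None = None,
    free_end: bool = False,
    free_start_b: bool = False,
    b_offset: int = 0,
    max_doublings: int = 8,
) -> PairwiseAlignment:
    """Optimal global alignment of a and b (affine gaps, optional band).

    ``band=None`` starts from a small adaptive band and doubles until the
    optimal path no longer touches the band edge, so the result is exact.
    With an explicit ``band`` the same doubling applies up to
    ``max_doublings``; beyond that :class:`BandOverflowError` is raised.
    ``free_end=True`` makes trailing gaps in either sequence free (both
    sequences are pinned at position 0).  ``free_start_b=True`` additionally
    lets the alignment start anywhere in b (a leading gap in b is free; a is
    still pinned at its own position 0), with ``b_offset`` centring the band
    where a is expected to start in b.
    """
    sc = scoring or Scoring()
    ac, bc = encode(a), encode(b)
    m, n = len(ac), len(bc)
    if m == 0 or n == 0:
        if free_end or (m == 0 and n == 0):
            return PairwiseAlignment(0, [], 0, 0)
        if m == 0:
            return PairwiseAlignment(sc.gap_open + sc.gap_extend * n, [("D", n)], 0, n)
        return PairwiseAlignment(sc.gap_open + sc.gap_extend * m, [("I", m)], m, 0)

    full = max(m, n)
    b0 = band if band is not None else max(32, abs(n - m) + 16)
    b0 = min(b0, full)
    doublings = 0
    while True:
        aln, touched = _global_banded(ac, bc, sc, b0, free_end, free_start_b, b_offset)
        if not touched or b0 >= full:
            return aln
        if doublings >= max_doublings:
            raise BandOverflowError(
                f"band overflow after {doublings} doublings (band={b0})"
            )
        b0 = min(b0 * 2, full)
        doublings += 1


def region_identity(
    a: str,
    b: str,
    region: tuple[int, int],
    scoring: Scoring | None = None,
    band: int = 400,
) -> float:
    """Identity of a against b restricted to b-positions in ``region``.

    a is aligned to b with a free leading and trailing gap in b and a free
    trailing gap in a (a left-anchored sequence that may start anywhere in
    b).  Columns whose b-position falls inside [region) are scored; region
    positions not covered by the alignment count as differences.
    """
    aln = global_align(a, b, scoring=scoring, band=band, free_end=True,
                       free_start_b=True)
    lo, hi = region
    i, j = 0, aln.b_start
    matches = 0
    cols = 0
    for op, ln in aln.cigar:
        for _ in range(ln):
            if op == "M":
                if lo <= j < hi:
                    cols += 1
                    if a[i] == b[j]:
                        matches += 1
                i += 1
                j += 1
            elif op == "I":
                if lo <= j < hi:
                    cols += 1
                i += 1
            else:
                if lo <= j < hi:
                    cols += 1
                j += 1
    covered = max(0, min(hi, aln.b_end) - max(lo, aln.b_start))
    cols += (hi - lo) - covered
    return matches / cols if cols else 0.0


def cigar_identity(cigar: list[tuple[str, int]], a: str, b: str) -> tuple[int, int]:
    """(match_columns, total_columns) of a global cigar over a and b."""
    i = j = matches = cols = 0
    for op, ln in cigar:
        if op == "M":
            for _ in range(ln):
                if a[i] == b[j]:
                    matches += 1
                i += 1
                j += 1
            cols += ln
        elif op == "I":
            i += ln
            cols += ln
        else:
            j += ln
            cols += ln
    return matches, cols


# ---------------------------------------------------------------------------
# seeded local alignment
# ---------------------------------------------------------------------------


def _kmer_seeds(qc: np.ndarray, tc: np.ndarray, k: int) -> list[tuple[int, int]]:
    """Exact k-mer matches as (qpos, tpos) pairs."""
    if len(qc) < k or len(tc) < k:
        return []
    index: dict[bytes, list[int]] = {}
    qb = qc.tobytes()
    for i in range(len(qc) - k + 1):
        index.setdefault(qb[i : i + k], []).append(i)
    out: list[tuple[int, int]] = []
    tb = tc.tobytes()
    for j in range(len(tc) - k + 1):
        hits = index.get(tb[j : j + k])
        if hits:
            for i in hits:
                out.append((i, j))
    return out


def _cluster_seeds(
    seeds: list[tuple[int, int]], qlen: int, diag_tol: int
) -> list[tuple[int, int, int]]:
    """Group seeds into (weight, diagonal, t_anchor) clusters.

    Seeds are grouped when their diagonals agree within ``diag_tol`` and
    their target positions fall within one query length of each other.
    """
    if not seeds:
        return []
    items = sorted(((t - q, t, q) for q, t in seeds))
    clusters: list[tuple[int, int, int]] = []
    group: list[tuple[int, int, int]] = []

    def flush(g: list[tuple[int, int, int]]) -> None:
        if not g:
            return
        g.sort(key=lambda x: x[1])
        sub: list[tuple[int, int, int]] = [g[0]]
        for it in g[1:]:
            if it[1] - sub[-1][1] > qlen:
                _emit(sub)
                sub = [it]
            else:
                sub.append(it)
        _emit(sub)

    def _emit(sub: list[tuple[int, int, int]]) -> None:
        diags = sorted(d for d, _, _ in sub)
        med = diags[len(diags) // 2]
        tpos = {t for _, t, _ in sub}
        clusters.append((len(tpos), med, min(tpos)))

    for it in items:
        if group and it[0] - group[-1][0] > diag_tol:
            flush(group)
            group = [it]
        else:
            group.append(it)
    flush(group)
    clusters.sort(key=lambda c: (-c[0], c[2]))
    return clusters


def _local_banded(
    qc: np.ndarray, tc: np.ndarray, diag: int, band: int, sc: Scoring
) -> tuple[int, int, int, int, int, int, int] | None:
    """Banded Smith-Waterman around a diagonal.

    Returns (score, q0, q1, t0, t1, matches, columns) or None.
    """
    m, n = len(qc), len(tc)
    go, ge = sc.gap_open, sc.gap_extend
    W = 2 * band + 1
    kidx = np.arange(W, dtype=np.int64)

    ptrM = np.full((m + 1, W), _START, dtype=np.int8)
    ptrX = np.full((m + 1, W), -1, dtype=np.int8)
    ptrY = np.full((m + 1, W), -1, dtype=np.int8)

    Mrow = np.full(W, NEG, dtype=np.int64)
    Xrow = np.full(W, NEG, dtype=np.int64)
    Yrow = np.full(W, NEG, dtype=np.int64)
    lo0 = diag - band  # row i window starts at i + diag - band

    best = (0, -1, -1)  # score, i, k
    for i in range(1, m + 1):
        loi = i + lo0
        js = loi + kidx
        okj = (js >= 1) & (js <= n)

        Mpd = _shift(Mrow, 0)  # previous row, shift per row is 1, diagonal = same k
        Xpd = _shift(Xrow, 0)
        Ypd = _shift(Yrow, 0)
        Mp = _shift(Mrow, 1)  # same j = k+1 in previous row's frame
        Xp = _shift(Xrow, 1)
        Yp = _shift(Yrow, 1)

        sub = np.full(W, NEG, dtype=np.int64)
        bidx = js[okj] - 1
        sub[okj] = np.where(tc[bidx] == qc[i - 1], sc.match, sc.mismatch)

        stack = np.stack(
            (Mpd, Xpd, Ypd, np.zeros(W, dtype=np.int64))
        )
        arg = stack.argmax(axis=0)
        Mnew = sub + stack.max(axis=0)
        Mnew[~okj] = NEG
        ptrM[i] = arg.astype(np.int8)

        stack = np.stack((Mp + go + ge, Xp + ge, Yp + go + ge))
        arg = stack.argmax(axis=0)
        Xnew = stack.max(axis=0)
        Xnew[~okj] = NEG
        ptrX[i] = arg.astype(np.int8)

        G = np.maximum(Mnew, Xnew)
        H = np.maximum.accumulate(G - ge * kidx)
        Ynew = np.full(W, NEG, dtype=np.int64)
        Ynew[1:] = go + ge * kidx[1:] + H[:-1]
        Ynew[~okj] = NEG
        openM = np.full(W, NEG, dtype=np.int64)
        openX = np.full(W, NEG, dtype=np.int64)
        ext = np.full(W, NEG, dtype=np.int64)
        openM[1:] = Mnew[:-1] + go + ge
        openX[1:] = Xnew[:-1] + go + ge
        ext[1:] = Ynew[:-1] + ge
        ptrY[i] = np.stack((openM, openX, ext)).argmax(axis=0).astype(np.int8)

        Mrow, Xrow, Yrow = Mnew, Xnew, Ynew

        k = int(Mrow.argmax())
        if int(Mrow[k]) > best[0]:
            best = (int(Mrow[k]), i, k)

    score, ei, ek = best
    if ei < 0 or score <= 0:
        return None
    # traceback (local alignments start and end in M)
    i, k, st = ei, ek, _M
    matches = cols = 0
    q1 = ei
    t1 = ei + lo0 + ek  # j = i + lo0 + k is already end-exclusive
    while True:
        j = i + lo0 + k
        if st == _M:
            prev = int(ptrM[i, k])
            if qc[i - 1] == tc[j - 1]:
                matches += 1
            cols += 1
            i -= 1
            k += 0  # window shifts by 1 per row; same k is diagonal
            if prev == _START:
                break
            st = prev
        elif st == _X:
            prev = int(ptrX[i, k])
            cols += 1
            i -= 1
            k += 1  # same j in previous row frame
            st = prev
        elif st == _Y:
            prev = int(ptrY[i, k])
            cols += 1
            k -= 1
            st = prev
        else:  # pragma: no cover
            return None
        if i == 0:
            break
    q0 = i
    t0 = i + lo0 + k
    return score, q0, q1, t0, t1, matches, cols


def local_hits(
    query: str,
    target: str,
    seed_length: int = 13,
    scoring: Scoring | None = None,
    max_clusters: int | None = None,
    band: int | None = None,
    diag_tol: int = 40,
    strands: str = "+-",
) -> list[LocalHit]:
    """All seeded local alignments of query in target.

    One hit per diagonal seed cluster; hits are returned sorted by
    (score desc, target start asc, '+' before '-').  ``strands`` restricts
    the search ('+' = query as given, '-' = reverse-complemented query).
    """
    from .seqio import revcomp

    sc = scoring or Scoring()
    qlen = len(query)
    if band is None:
        band = max(32, int(0.3 * qlen))
    hits: list[LocalHit] = []
    tc = encode(target)
    for strand, qseq in (("+", query), ("-", revcomp(query))):
        if strand not in strands:
            continue
        qc = encode(qseq)
        clusters = _cluster_seeds(_kmer_seeds(qc, tc, seed_length), qlen, diag_tol)
        if max_clusters is not None:
            clusters = clusters[:max_clusters]
        for _, diag, _ in clusters:
            res = _local_banded(qc, tc, diag, band, sc)
            if res is None:
                continue
            score, q0, q1, t0, t1, matches, cols = res
            if strand == "-":
                q0, q1 = qlen - q1, qlen - q0
            hits.append(
                LocalHit(
                    query_start=q0,
                    query_end=q1,
                    target_start=t0,
                    target_end=t1,
                    strand=strand,
                    identity=matches / cols if cols else 0.0,
                    score=score,
                    matches=matches,
                    columns=cols,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.target_start, h.strand))
    return hits


def best_local_hit(
    query: str,
    target: str,
    seed_length: int = 13,
    min_identity: float = 0.85,
    scoring: Scoring | None = None,
) -> LocalHit | None:
    """Best seeded local hit, or None when nothing reaches min_identity."""
    hits = local_hits(query, target, seed_length=seed_length, scoring=scoring,
                      max_clusters=8)
    for h in hits:
        if h.identity >= min_identity:
            return h
    return None
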