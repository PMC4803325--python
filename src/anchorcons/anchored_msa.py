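"""Left-anchored multiple alignment of one anchored read group.

All reads in a group begin at the same anchor, so the hard placement problem
of repetitive reads disappears: a star alignment against a draft suffices.
The longest read serves as the initial backbone; every read is aligned to it
by banded global alignment with free gaps only at the far (3') end, read
insertions are merged into the column set, and a single refinement pass
re-aligns every read against the draft consensus of the first pass.

The resulting :class:`ColumnMatrix` stacks rows over ``{A, C, G, T, -}``
with an explicit "missing" state beyond each read's end, so per-column depth
reflects how many molecules actually extend that far from the anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import PairwiseAlignment, Scoring, global_align
from .anchor_select import AnchoredRead

__all__ = ["ColumnMatrix", "build_msa", "write_afa", "read_afa"]

MISSING = 0
GAP = ord("-")


@dataclass
class ColumnMatrix:
    """Gapped alignment matrix; code 0 marks positions beyond a read's end."""

    row_ids: list[str]
    data: np.ndarray  # uint8, shape (n_rows, n_cols)
    anchor_column: int = 0

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    def depth(self) -> np.ndarray:
        """Non-missing rows per column."""
        return (self.data != MISSING).sum(axis=0)

    def row_text(self, i: int) -> str:
        """Row as printable characters; missing rendered as '.'."""
        b = self.data[i].copy()
        b[b == MISSING] = ord(".")
        return b.tobytes().decode("ascii")

    def ungapped_row(self, i: int) -> str:
        b = self.data[i]
        b = b[(b != MISSING) & (b != GAP)]
        return b.tobytes().decode("ascii")


def _events(aln: PairwiseAlignment, read: str) -> list[tuple[str, int, int, int]]:
    """Cigar as (op, draft_pos, read_pos, length); read overhang appended."""
    out = []
    i, j = 0, aln.b_start
    for op, ln in aln.cigar:
        out.append((op, j, i, ln))
        if op == "M":
            i += ln
            j += ln
        elif op == "I":
            i += ln
        else:
            j += ln
    if aln.a_end < len(read):
        out.append(("I", j, i, len(read) - aln.a_end))
    return out


def _stack(
    reads: list[str],
    offsets: list[int],
    draft: str,
    scoring: Scoring,
    band: int,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Align every read to the draft and expand insertions into columns.

    Each read starts about ``offsets[i]`` into the draft (its anchor
    offset); leading draft gaps are free so rows pin at their own anchor
    position.  Returns (matrix, match_col, first_col_per_row) where
    match_col maps draft positions to matrix columns.
    """
    n = len(draft)
    aligned = []
    for r, off in zip(reads, offsets):
        # initial band grows with read length: indel-dominated errors drift
        # the path off the unit diagonal roughly in proportion to length
        b = max(band, len(r) // 16 + 32)
        aln = global_align(
            r, draft, scoring=scoring, band=b, free_end=True,
            free_start_b=True, b_offset=off,
        )
        aligned.append(_events(aln, r))

    ins_max = np.zeros(n + 1, dtype=np.int64)
    for ev in aligned:
        for op, j, _, ln in ev:
            if op == "I":
                ins_max[j] = max(ins_max[j], ln)

    # column layout: [ins slots before draft pos j][match col j] ... [trailing]
    match_col = np.zeros(n, dtype=np.int64)
    ins_col = np.zeros(n + 1, dtype=np.int64)
    c = 0
    for j in range(n):
        ins_col[j] = c
        c += ins_max[j]
        match_col[j] = c
        c += 1
    ins_col[n] = c
    c += ins_max[n]
    total = c

    data = np.zeros((len(reads), total), dtype=np.uint8)
    firsts: list[int] = []
    for ri, (read, ev) in enumerate(zip(reads, aligned)):
        row = data[ri]
        rb = np.frombuffer(read.encode("ascii"), dtype=np.uint8)
        last = -1
        first = total
        for op, j, i, ln in ev:
            if op == "M":
                cols = match_col[j : j + ln]
                row[cols] = rb[i : i + ln]
            elif op == "I":
                c0 = ins_col[j]
                cols = np.arange(c0, c0 + ln)
                row[cols] = rb[i : i + ln]
            else:  # D: read has a gap over these draft columns
                cols = match_col[j : j + ln]
                row[cols] = GAP
            if len(cols):
                last = max(last, int(cols[-1]))
                first = min(first, int(cols[0]))
        if last >= 0:
            span = row[first : last + 1]
            span[span == MISSING] = GAP
            firsts.append(first)
        else:
            firsts.append(0)
    return data, match_col, firsts


def _draft_consensus(
    data: np.ndarray, match_col: np.ndarray, draft: str
) -> tuple[str, np.ndarray]:
    """Plurality call per column ('-' loses ties; gap-majority columns drop;
    columns no read reaches keep the scaffold character).

    Returns (consensus, emitted_before): emitted_before[c] is the number of
    consensus characters emitted before matrix column c, used to remap
    anchor offsets onto the new draft.
    """
    letters = np.frombuffer(b"ACGT-", dtype=np.uint8)
    counts = np.stack([(data == c).sum(axis=0) for c in letters])
    base_counts = counts[:4]
    best_base = base_counts.argmax(axis=0)
    best_base_count = base_counts.max(axis=0)
    emit = np.zeros(data.shape[1], dtype=np.uint8)
    covered = (best_base_count >= counts[4]) & (best_base_count > 0)
    emit[covered] = letters[best_base[covered]]
    # scaffold fallback where no read reaches (only match columns can be bare)
    depth = counts.sum(axis=0)
    bare = match_col[depth[match_col] == 0]
    draft_b = np.frombuffer(draft.encode("ascii"), dtype=np.uint8)
    emit[bare] = draft_b[depth[match_col] == 0]
    keep = emit != 0
    emitted_before = np.concatenate(([0], np.cumsum(keep)))[:-1]
    return emit[keep].tobytes().decode("ascii"), emitted_before


def build_msa(
    group: list[AnchoredRead],
    scoring: Scoring | None = None,
    band: int = 200,
    anchor: str | None = None,
) -> ColumnMatrix:
    """Anchored star alignment of one read group with one refinement pass.

    ``anchor`` is the anchor sequence in stored-read orientation (flank5, or
    revcomp(flank3) for the distal group); when given it scaffolds the part
    of the flank between the earliest and the backbone read's anchor
    offsets, otherwise that stretch is approximated from the earliest-
    starting read.

    Placement relies on each read starting with unique (anchor) sequence:
    a read consisting purely of repeat units has co-optimal placements at
    every period and may pin at any of them.  Anchored selection guarantees
    the unique prefix, so this ambiguity does not arise for its output.
    """
    if not group:
        raise ValueError("cannot align an empty read group")
    anchors = {ar.anchor for ar in group}
    if len(anchors) != 1:
        raise ValueError(f"group mixes anchors: {sorted(anchors)}")
    sc = scoring or Scoring()
    reads = [ar.trimmed_sequence for ar in group]
    ids = [ar.read_id for ar in group]

    min_o = min(ar.anchor_offset for ar in group)
    offsets = [ar.anchor_offset - min_o for ar in group]
    bb = max(range(len(reads)), key=lambda i: (len(reads[i]), reads[i]))
    o_b = offsets[bb]
    if o_b > 0:
        if anchor is not None:
            prefix = anchor[min_o : min_o + o_b]
        else:
            first = min(range(len(reads)), key=lambda i: (offsets[i], -len(reads[i])))
            prefix = reads[first][:o_b]
    else:
        prefix = ""
    draft = prefix + reads[bb]

    data, match_col, firsts = _stack(reads, offsets, draft, sc, band)
    draft1, emitted_before = _draft_consensus(data, match_col, draft)
    if draft1:
        offsets1 = [int(emitted_before[f]) for f in firsts]
        data, _, _ = _stack(reads, offsets1, draft1, sc, band)
    return ColumnMatrix(row_ids=ids, data=data)


def write_afa(matrix: ColumnMatrix, path: str | Path, width: int = 80) -> None:
    """Aligned FASTA: '-' for gaps, trailing '.' for missing."""
    with open(path, "w") as fh:
        for i, rid in enumerate(matrix.row_ids):
            fh.write(f">{rid}\n")
            text = matrix.row_text(i)
            for k in range(0, len(text), width):
                fh.write(text[k : k + width] + "\n")


def read_afa(path: str | Path) -> ColumnMatrix:
    ids: list[str] = []
    rows: list[str] = []
    cur: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if ids:
                    rows.append("".join(cur))
                ids.append(line[1:].split()[0])
                cur = []
            else:
                cur.append(line)
    if ids:
        rows.append("".join(cur))
    if not ids:
        raise ValueError(f"no rows in alignment file {path}")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("alignment rows have unequal lengths")
    data = np.zeros((len(rows), width), dtype=np.uint8)
    for i, r in enumerate(rows):
        b = np.frombuffer(r.upper().encode("ascii"), dtype=np.uint8).copy()
        b[b == ord(".")] = MISSING
        data[i] = b
    return ColumnMatrix(row_ids=ids, data=data)
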