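"""Threshold consensus calling from a left-anchored alignment matrix.

Per column the plurality character among the non-missing rows wins ('-'
loses ties to any base; base ties break alphabetically).  A winning base is
emitted when its fraction of the column depth reaches the threshold,
otherwise the column emits N; a winning gap emits nothing (gap-plurality
columns are insertion noise under an indel-dominated error profile).  The
threshold denominator is the column depth — the number of reads still
extending that far from the anchor — not the total read count, so one
threshold stays meaningful as coverage decays toward the 3' end.  Calling
stops when the signal collapses for a sustained window and the consensus is
trimmed back to the last confidently called base.

Thresholds in the low-teens (0.13-0.14) are appropriate for raw
single-molecule reads, where random indels spread column support thin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .anchored_msa import GAP, MISSING, ColumnMatrix

__all__ = ["ConsensusResult", "call_consensus", "consensus_support_profile"]

_LETTERS = np.frombuffer(b"ACGT-", dtype=np.uint8)


@dataclass
class ColumnCall:
    column: int
    depth: int
    winner: str  # one of A,C,G,T,-
    winner_fraction: float
    emitted: str  # base, 'N', or '' when nothing was emitted


@dataclass
class ConsensusResult:
    sequence: str
    per_column: list[ColumnCall]
    threshold: float
    stopped_at_column: int | None = None

    @property
    def called_length(self) -> int:
        return len(self.sequence)


def call_consensus(
    matrix: ColumnMatrix,
    threshold: float = 0.14,
    min_depth: int = 3,
    stop_window: int = 50,
) -> ConsensusResult:
    """Call the threshold consensus of an anchored stack.

    Calling begins at the first column whose depth reaches ``min_depth``
    (rows may pin at different offsets within the anchor, so the leftmost
    columns of a stack can be thinly covered).  Processing stops at the
    first run of ``stop_window`` consecutive columns in which every column
    is below ``min_depth``, or more than half of the columns emitted N; the
    sequence is then trimmed back to the last confident (non-N, depth >=
    min_depth) base.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if matrix.n_rows == 0 or matrix.n_cols == 0:
        raise ValueError("cannot call a consensus from an empty matrix")

    data = matrix.data
    counts = np.stack([(data == c).sum(axis=0) for c in _LETTERS])  # (5, n_cols)
    depth = (data != MISSING).sum(axis=0)

    base_counts = counts[:4]
    best_base = base_counts.argmax(axis=0)  # alphabetical tie-break: first max
    best_base_count = base_counts.max(axis=0)
    gap_count = counts[4]
    gap_wins = gap_count > best_base_count  # '-' loses ties to any base

    per_column: list[ColumnCall] = []
    emitted: list[str] = []
    emit_col: list[int] = []  # matrix column of each emitted char
    confident_upto = 0  # length of `emitted` at the last confident base
    window: list[bool] = []  # True when the column is low-depth
    window_n: list[bool] = []  # True when the column emitted N
    stopped_at = None

    deep = np.nonzero(depth >= min_depth)[0]
    start_col = int(deep[0]) if len(deep) else matrix.n_cols

    for col in range(start_col, matrix.n_cols):
        d = int(depth[col])
        if d == 0:
            winner, frac, out = "-", 1.0, ""
            low = True
            is_n = False
        elif gap_wins[col]:
            winner = "-"
            frac = gap_count[col] / d
            out = ""
            low = d < min_depth
            is_n = False
        else:
            winner = chr(_LETTERS[best_base[col]])
            frac = best_base_count[col] / d
            low = d < min_depth
            if frac >= threshold:
                out = winner
                is_n = False
            else:
                out = "N"
                is_n = True
        per_column.append(ColumnCall(col, d, winner, float(frac), out))
        if out:
            emitted.append(out)
            emit_col.append(col)
            if out != "N" and not low:
                confident_upto = len(emitted)
        window.append(low)
        window_n.append(is_n)
        if len(window) > stop_window:
            window.pop(0)
            window_n.pop(0)
        if len(window) == stop_window and (
            all(window) or sum(window_n) > 0.5 * stop_window
        ):
            stopped_at = col
            break

    if stopped_at is not None:
        emitted = emitted[:confident_upto]
        per_column = [c for c in per_column if c.column <= (emit_col[confident_upto - 1] if confident_upto else -1)]
    return ConsensusResult(
        sequence="".join(emitted),
        per_column=per_column,
        threshold=threshold,
        stopped_at_column=stopped_at,
    )


def consensus_support_profile(result: ConsensusResult) -> pd.DataFrame:
    """Support table with one row per processed column."""
    return pd.DataFrame(
        {
            "column": [c.column for c in result.per_column],
            "depth": [c.depth for c in result.per_column],
            "winner": [c.winner for c in result.per_column],
            "winner_fraction": [c.winner_fraction for c in result.per_column],
            "emitted": [c.emitted for c in result.per_column],
        }
    )


def write_profile(result: ConsensusResult, path: str | Path) -> None:
    consensus_support_profile(result).to_csv(path, sep="\t", index=False)
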