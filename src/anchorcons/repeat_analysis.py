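"""Repeat-unit decomposition, pairwise unit comparison, dot plots, motif
scanning and restriction analyses of a consensus (or ground-truth) sequence.

Copy number is reported at half-unit resolution: a trailing interval
covering 30-85% of the probe counts as half a copy, matching the convention
of describing a truncated distal unit as ".5".  The pairwise comparison
counts each gap column as one difference (stated in output metadata, since
alignment-length conventions differ between tools).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import Scoring, cigar_identity, global_align, local_hits
from .seqio import Interval, revcomp

__all__ = [
    "UnitSegmentation",
    "UnitComparison",
    "segment_units",
    "count_copies",
    "compare_units",
    "compare_all_units",
    "dotplot",
    "scan_motifs",
    "in_silico_digest",
    "estimate_copies_from_length",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass
class UnitSegmentation:
    """Ordered non-overlapping unit intervals plus inverted distractor hits."""

    intervals: list[Interval]
    partial_flags: list[bool]
    probe: str
    distractors: list[Interval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class UnitComparison:
    unit_a: str
    unit_b: str
    percent_identity: float
    differences: int
    alignment_columns: int
    convention: str = "gap columns count as differences"


def segment_units(
    sequence: str,
    probe: str,
    min_identity: float = 0.8,
    seed_length: int = 13,
    scoring: Scoring | None = None,
) -> UnitSegmentation:
    """Tile a sequence with non-overlapping local hits of the repeat probe.

    Hits are gathered on both strands (inverted hits become distractors),
    greedily selected by score then leftmost position, and ordered 5'->3'.
    A hit covering >= 30% but < 85% of the probe is flagged partial.
    """
    if len(probe) < 100:
        raise ValueError("probe must be at least 100 bases")
    probe = probe.upper()
    sequence = sequence.upper()
    hits = [
        h
        for h in local_hits(probe, sequence, seed_length=seed_length, scoring=scoring)
        if h.identity >= min_identity
        and (h.query_end - h.query_start) >= 0.3 * len(probe)
    ]
    hits.sort(key=lambda h: (-h.score, h.target_start, h.strand))
    accepted = []
    for h in hits:
        overlap = False
        for a in accepted:
            ov = min(h.target_end, a.target_end) - max(h.target_start, a.target_start)
            shorter = min(h.target_end - h.target_start, a.target_end - a.target_start)
            if ov > 0.3 * shorter:
                overlap = True
                break
        if not overlap:
            accepted.append(h)
    accepted.sort(key=lambda h: h.target_start)

    intervals, partials, distractors = [], [], []
    idx = 0
    for h in accepted:
        cov = (h.query_end - h.query_start) / len(probe)
        if h.strand == "-":
            distractors.append(
                Interval(h.target_start, h.target_end, "distractor", "-")
            )
            continue
        idx += 1
        partial = cov < 0.85
        name = f"unit_{idx}_{'partial' if partial else 'full'}"
        intervals.append(Interval(h.target_start, h.target_end, name, "+"))
        partials.append(partial)
    return UnitSegmentation(intervals, partials, probe, distractors)


def count_copies(seg: UnitSegmentation) -> float:
    """Full intervals count 1, partial intervals 0.5."""
    return sum(0.5 if p else 1.0 for p in seg.partial_flags)


def compare_units(a: str, b: str, scoring: Scoring | None = None,
                  name_a: str = "a", name_b: str = "b") -> UnitComparison:
    """Optimal global alignment comparison of two repeat units.

    differences = mismatch columns + gap columns;
    percent_identity = 100 * match columns / total columns.

    The comparison is symmetric by construction: the pair is aligned in a
    canonical order, so co-optimal alignments with different column
    compositions cannot make identity(a, b) differ from identity(b, a).
    """
    if not a or not b:
        raise ValueError("units must be non-empty")
    a, b = a.upper(), b.upper()
    x, y = (a, b) if a <= b else (b, a)
    aln = global_align(x, y, scoring=scoring)
    matches, cols = cigar_identity(aln.cigar, x, y)
    return UnitComparison(
        unit_a=name_a,
        unit_b=name_b,
        percent_identity=100.0 * matches / cols,
        differences=cols - matches,
        alignment_columns=cols,
    )


def compare_all_units(units: dict[str, str], scoring: Scoring | None = None) -> pd.DataFrame:
    """Pairwise comparison table over named units (matrix shape)."""
    names = list(units)
    rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            c = compare_units(units[na], units[nb], scoring, na, nb)
            rows.append(
                {
                    "unit_a": na,
                    "unit_b": nb,
                    "percent_identity": c.percent_identity,
                    "differences": c.differences,
                    "alignment_columns": c.alignment_columns,
                }
            )
    return pd.DataFrame(rows)


def dotplot(a: str, b: str, window: int = 20, min_matches: int | None = None) -> set[tuple[int, int]]:
    """(i, j) pairs where a[i:i+window] and b[j:j+window] match at
    >= min_matches positions (default: exact, min_matches = window)."""
    if window < 4:
        raise ValueError("window must be >= 4")
    if min_matches is None:
        min_matches = window
    ac = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    bc = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    na, nb = len(ac), len(bc)
    if na < window or nb < window:
        return set()
    out: set[tuple[int, int]] = set()
    # per-diagonal sliding window sums of the match indicator
    for d in range(-(na - window), nb - window + 1):
        i0 = max(0, -d)
        j0 = i0 + d
        ln = min(na - i0, nb - j0)
        if ln < window:
            continue
        eq = (ac[i0 : i0 + ln] == bc[j0 : j0 + ln]).astype(np.int32)
        cs = np.concatenate(([0], np.cumsum(eq)))
        wins = cs[window:] - cs[:-window]
        for k in np.nonzero(wins >= min_matches)[0]:
            out.add((i0 + int(k), j0 + int(k)))
    return out


def _iupac_regex(pattern: str) -> re.Pattern:
    try:
        return re.compile("".join(IUPAC[c] for c in pattern.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC symbol {exc.args[0]!r} in {pattern!r}") from exc


def scan_motifs(
    units: list[str] | dict[str, str],
    motifs: list[tuple[str, str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Degenerate motif scan on the given strand of each unit.

    Returns (hits, conservation): hits has one row per match
    (unit, motif, position); conservation lists per-motif offsets present in
    every unit (homologous positions conserved across the whole array).
    """
    if isinstance(units, list):
        units = {f"unit_{i + 1}": u for i, u in enumerate(units)}
    rows = []
    per_motif_offsets: dict[str, list[set[int]]] = {name: [] for name, _ in motifs}
    for name, pattern in motifs:
        rx = _iupac_regex(pattern)
        for uname, seq in units.items():
            # overlapping matches via zero-width lookahead
            positions = {m.start() for m in re.finditer(f"(?={rx.pattern})", seq.upper())}
            per_motif_offsets[name].append(positions)
            for p in sorted(positions):
                rows.append({"unit": uname, "motif": name, "position": p})
    cons_rows = []
    for name, _ in motifs:
        sets = per_motif_offsets[name]
        shared = set.intersection(*sets) if sets else set()
        for p in sorted(shared):
            cons_rows.append({"motif": name, "offset": p, "n_units": len(sets)})
    hits = pd.DataFrame(rows, columns=["unit", "motif", "position"])
    conservation = pd.DataFrame(cons_rows, columns=["motif", "offset", "n_units"])
    return hits, conservation


def in_silico_digest(
    sequence: str,
    sites: list[tuple[str, str]] | list[tuple[str, str, int]],
) -> list[int]:
    """Fragment lengths after cutting at every recognition-site occurrence.

    Each site is (enzyme, recognition[, cut_offset]); the default cut offset
    is the midpoint of the recognition sequence (blunt EcoRV-style).  For a
    non-palindromic recognition sequence the reverse-complement occurrence is
    also cut, at the mirrored offset.  Fragment lengths always sum to the
    sequence length.
    """
    seq = sequence.upper()
    cuts: set[int] = set()
    for site in sites:
        enzyme, recog = site[0], site[1].upper()
        if set(recog) - set("ACGT"):
            raise ValueError(f"{enzyme}: degenerate recognition sequences not supported")
        offset = site[2] if len(site) > 2 else len(recog) // 2
        targets = [(recog, offset)]
        rc = revcomp(recog)
        if rc != recog:
            targets.append((rc, len(recog) - offset))
        for pat, off in targets:
            start = 0
            while True:
                p = seq.find(pat, start)
                if p < 0:
                    break
                cut = p + off
                if 0 < cut < len(seq):
                    cuts.add(cut)
                start = p + 1
    positions = [0] + sorted(cuts) + [len(seq)]
    return [positions[i + 1] - positions[i] for i in range(len(positions) - 1)]


def estimate_copies_from_length(
    region_length: float, unit_length: float, flank_total: float
) -> float:
    """Copies implied by a repeat-region length, at half-unit resolution.

    (region_length - flank_total) / unit_length rounded to the nearest 0.5;
    the flank total is model-dependent and must come from the same region
    definition as region_length.
    """
    if region_length <= 0 or unit_length <= 0 or flank_total < 0:
        raise ValueError("lengths must be positive")
    if region_length <= flank_total:
        raise ValueError("region_length must exceed flank_total")
    raw = (region_length - flank_total) / unit_length
    return round(raw * 2) / 2
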