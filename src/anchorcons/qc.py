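"""Read- and contig-level quality-control observables.

Length statistics (count, bases, mean, N50, max), per-read GC histograms
with a fitted normal, per-position quality five-number summaries, and
coverage profiles with depth histograms.  All outputs are numeric tables;
plotting is left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import Scoring, local_hits
from .seqio import SeqRecord, gc_fraction

__all__ = [
    "ReadStats",
    "CoverageProfile",
    "read_stats",
    "gc_distribution",
    "positional_quality",
    "coverage_profile",
]


@dataclass(frozen=True)
class ReadStats:
    n_reads: int
    n_bases: int
    mean_length: float
    n50_length: int
    max_length: int

    def as_row(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "n_bases": self.n_bases,
            "mean_length": self.mean_length,
            "n50_length": self.n50_length,
            "max_length": self.max_length,
        }


@dataclass
class CoverageProfile:
    depth: np.ndarray  # per contig position
    histogram: pd.DataFrame  # columns: depth, n_positions
    n_mapped: int
    n_unmapped: int
    n_multi_hit: int


def read_stats(reads: list[SeqRecord]) -> ReadStats:
    """Length statistics; N50 is the largest L such that reads of length
    >= L contain at least half of all bases."""
    if not reads:
        raise ValueError("read_stats requires at least one read")
    lengths = np.sort(np.array([len(r) for r in reads]))[::-1]
    total = int(lengths.sum())
    cum = np.cumsum(lengths)
    n50 = int(lengths[np.searchsorted(cum, total / 2)])
    return ReadStats(
        n_reads=len(reads),
        n_bases=total,
        mean_length=total / len(reads),
        n50_length=n50,
        max_length=int(lengths[0]),
    )


def gc_distribution(
    reads: list[SeqRecord],
    region_labels: dict[str, str] | None = None,
    n_bins: int = 50,
) -> dict[str, dict]:
    """Per-label GC-fraction histogram plus a fitted normal (mean, sd).

    ``region_labels`` maps read id -> label (e.g. repeat vs flank, assigned
    by probe hit); unlabelled reads fall under 'all'.
    """
    if not reads:
        raise ValueError("gc_distribution requires at least one read")
    groups: dict[str, list[float]] = {}
    for r in reads:
        label = region_labels.get(r.id, "all") if region_labels else "all"
        try:
            groups.setdefault(label, []).append(gc_fraction(r.sequence))
        except ValueError:
            continue  # all-N read carries no GC signal
    out = {}
    for label, vals in groups.items():
        v = np.array(vals)
        counts, edges = np.histogram(v, bins=n_bins, range=(0.0, 1.0))
        sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
        out[label] = {
            "n": len(v),
            "mean": float(v.mean()),
            "sd": sd,
            "hist_counts": counts,
            "hist_edges": edges,
        }
    return out


def positional_quality(reads: list[SeqRecord], n_bins: int = 100) -> pd.DataFrame:
    """Five-number summaries of Phred qualities binned by read position.

    Positions are binned 5'->3' over the longest read; bins that no read
    reaches are omitted.
    """
    with_q = [r for r in reads if r.quality is not None]
    if not with_q:
        raise ValueError("positional_quality requires reads with quality scores")
    max_len = max(len(r) for r in with_q)
    edges = np.linspace(0, max_len, n_bins + 1).astype(int)
    rows = []
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        if hi <= lo:
            continue
        vals: list[int] = []
        for r in with_q:
            if len(r) > lo:
                vals.extend(r.quality[lo : min(hi, len(r))])
        if not vals:
            continue
        v = np.array(vals)
        rows.append(
            {
                "bin": b,
                "pos_start": lo,
                "pos_end": hi,
                "n": len(v),
                "min": int(v.min()),
                "q1": float(np.percentile(v, 25)),
                "median": float(np.median(v)),
                "q3": float(np.percentile(v, 75)),
                "max": int(v.max()),
            }
        )
    return pd.DataFrame(rows)


def coverage_profile(
    reads: list[SeqRecord],
    contig: str,
    seed_length: int = 13,
    min_identity: float = 0.7,
    scoring: Scoring | None = None,
) -> CoverageProfile:
    """Depth per contig position using the single best placement per read.

    Reads whose best hit falls below ``min_identity`` are counted as
    unmapped; reads with a second placement scoring within 10% of the best
    are counted as multi-hit (ambiguous repeat placements) but still placed
    once, at the best hit.
    """
    if not contig:
        raise ValueError("contig must be non-empty")
    depth = np.zeros(len(contig), dtype=np.int64)
    n_mapped = n_unmapped = n_multi = 0
    for r in reads:
        # two strongest seed clusters are enough for a best placement plus a
        # runner-up score; the band only needs to absorb net indel drift,
        # which grows linearly but much slower than read length
        hits = [
            h
            for h in local_hits(
                r.sequence, contig, seed_length=seed_length, scoring=scoring,
                max_clusters=2, band=max(64, len(r.sequence) // 8),
            )
            if h.identity >= min_identity
        ]
        if not hits:
            n_unmapped += 1
            continue
        best = hits[0]
        if len(hits) > 1 and hits[1].score >= 0.9 * best.score:
            n_multi += 1
        depth[best.target_start : best.target_end] += 1
        n_mapped += 1
    hist = np.bincount(depth)
    histogram = pd.DataFrame(
        {"depth": np.arange(len(hist)), "n_positions": hist}
    )
    return CoverageProfile(
        depth=depth,
        histogram=histogram,
        n_mapped=n_mapped,
        n_unmapped=n_unmapped,
        n_multi_hit=n_multi,
    )
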