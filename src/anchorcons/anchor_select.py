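"""Select reads containing a unique flank, trim at the anchor, normalize strand.

Repetitive reads cannot be placed unambiguously on a near-identical tandem
array; reads that contain one of the unique flanking sequences can.  This
module finds flank hits on both strands of every read by seeded local
alignment, orients each selected read so the anchor sits at its 5' end with
the array extending 3' of it, and trims the read to start at the anchor hit.

Orientation convention: the FLANK5 group is stored on the forward strand of
the locus (reads begin with flank5).  The FLANK3 group is stored reverse-
complemented relative to the locus, so those reads begin with
revcomp(flank3) and read into the array from the distal side — the
convention that brings the unique sequence to the 5' end before stacking.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import LocalHit, Scoring, best_local_hit, local_hits
from .seqio import SeqRecord, revcomp

__all__ = ["AnchoredRead", "SelectionReport", "local_align", "select_anchored_reads"]

FLANK5 = "FLANK5"
FLANK3 = "FLANK3"


@dataclass
class AnchoredRead:
    """A read selected, trimmed and orientation-normalized at one anchor.

    ``anchor_offset`` is the position within the anchor where the trimmed
    sequence begins: 0 when the read contains the anchor start, positive
    when the molecule was already inside the flank when the read began.
    """

    read_id: str
    anchor: str  # FLANK5 or FLANK3
    trimmed_sequence: str
    original_strand: str  # strand of the stored orientation in the input read
    anchor_identity: float
    anchor_offset: int = 0


@dataclass
class SelectionReport:
    """Per-group selection statistics (anchored-subread table shape)."""

    n_reads: dict[str, int]
    max_trimmed_length: dict[str, int]
    max_depth: dict[str, int]
    n_both_flanks: int = 0

    def rows(self) -> list[tuple[str, int, int, int]]:
        return [
            (g, self.n_reads[g], self.max_trimmed_length[g], self.max_depth[g])
            for g in (FLANK5, FLANK3)
        ]


def local_align(
    query: str,
    target: str,
    seed_length: int = 13,
    min_identity: float = 0.85,
    scoring: Scoring | None = None,
) -> LocalHit | None:
    """Best local alignment of query in target (both strands), by exact
    k-mer seeding plus banded extension; None when nothing reaches
    min_identity or no seed matches."""
    if seed_length < 8:
        raise ValueError("seed_length must be >= 8")
    return best_local_hit(
        query, target, seed_length=seed_length, min_identity=min_identity, scoring=scoring
    )


def _find_anchor(
    anchor_seq: str,
    read: str,
    seed_length: int,
    min_identity: float,
    min_anchor_cov: float,
    scoring: Scoring | None,
) -> LocalHit | None:
    """Best hit of anchor_seq in the read passing identity and coverage."""
    hits = local_hits(anchor_seq, read, seed_length=seed_length,
                      scoring=scoring, max_clusters=8, strands="+")
    for h in hits:  # sorted best-first
        if h.identity >= min_identity and (
            h.query_end - h.query_start
        ) >= min_anchor_cov * len(anchor_seq):
            return h
    return None


def select_anchored_reads(
    reads: list[SeqRecord],
    flank5: str,
    flank3: str,
    min_identity: float = 0.85,
    min_anchor_cov: float = 0.6,
    seed_length: int = 13,
    scoring: Scoring | None = None,
) -> tuple[list[AnchoredRead], list[AnchoredRead], SelectionReport]:
    """Split reads into FLANK5- and FLANK3-anchored groups.

    A read joins a group when the anchor hit covers at least
    ``min_anchor_cov`` of the flank at identity >= ``min_identity``.  A read
    matching both flanks (it spans the whole array) joins both groups and is
    counted in the report.  Selected reads are trimmed to start at the
    anchor-hit start in anchor orientation.
    """
    flank5 = flank5.upper()
    flank3 = flank3.upper()
    if not flank5 or not flank3:
        raise ValueError("flanks must be non-empty")
    cross = local_align(flank5, flank3, seed_length=min(seed_length, 13),
                        min_identity=min_identity)
    if cross is not None and (cross.query_end - cross.query_start) > 0.5 * len(flank5):
        raise ValueError("flanks are mutually similar; they cannot serve as anchors")

    # anchor sequences in stored-read orientation: FLANK5 forward,
    # FLANK3 reverse-complemented so the array follows the anchor
    anchors = {FLANK5: flank5, FLANK3: revcomp(flank3)}
    groups: dict[str, list[AnchoredRead]] = {FLANK5: [], FLANK3: []}
    n_both = 0

    for rec in reads:
        assigned = []
        fwd = rec.sequence
        rev = revcomp(rec.sequence)
        # search both read orientations with the anchor held forward; pick
        # the better hit with a strand-symmetric tie-break so that
        # reverse-complementing the input cannot change the result
        orientations = sorted([(fwd, "+"), (rev, "-")], key=lambda t: t[0])
        for name, aseq in anchors.items():
            best = None
            for oriented, strand in orientations:
                hit = _find_anchor(aseq, oriented, seed_length, min_identity,
                                   min_anchor_cov, scoring)
                if hit is not None and (best is None or hit.score > best[0].score):
                    best = (hit, oriented, strand)
            if best is None:
                continue
            hit, oriented, strand = best
            # trim at the anchor-hit start: the anchor stays in the read
            trimmed = oriented[hit.target_start :]
            assigned.append(
                AnchoredRead(
                    read_id=rec.id,
                    anchor=name,
                    trimmed_sequence=trimmed,
                    original_strand=strand,
                    anchor_identity=hit.identity,
                    anchor_offset=hit.query_start,
                )
            )
        if len(assigned) == 2:
            n_both += 1
        for ar in assigned:
            groups[ar.anchor].append(ar)

    for g in groups.values():
        g.sort(key=lambda ar: ar.read_id)

    report = SelectionReport(
        n_reads={k: len(v) for k, v in groups.items()},
        max_trimmed_length={
            k: max((len(ar.trimmed_sequence) for ar in v), default=0)
            for k, v in groups.items()
        },
        # left-anchored stack: every read covers column 0, so the maximum
        # coverage depth equals the group size
        max_depth={k: len(v) for k, v in groups.items()},
        n_both_flanks=n_both,
    )
    return groups[FLANK5], groups[FLANK3], report
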