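"""Ground-truth macrosatellite loci and noisy long reads.

The generator emulates the structure of a D4Z4-like locus: a tandem array of
GC-rich ~3.3 kb units with small inter-unit divergence, flanked on both sides
by unique sequence, optionally preceded by an inverted distractor copy
(DUX4c-like).  Reads are sampled uniformly from both strands with a
log-normal length distribution and corrupted by an indel-dominated error
model with a configurable total rate (the technology this emulates has
insertion/deletion-type errors of up to 15%).

Everything is deterministic under a fixed seed; read ids carry the true
start coordinate and strand so downstream stages can be tested against the
ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seqio import Interval, SeqRecord, revcomp

__all__ = ["ArraySpec", "ErrorModel", "ArrayTruth", "build_array", "sample_reads", "corrupt"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ArraySpec:
    """Parameters of a simulated tandem-repeat locus.

    n_copies is in half-unit steps (e.g. 13.5): the fractional copy, if any,
    is the distal-most unit truncated at its 3' side.
    """

    unit_length: int = 3300
    n_copies: float = 13.5
    unit_gc: float = 0.70
    inter_unit_divergence: float = 0.01
    flank5_length: int = 500
    flank3_length: int = 500
    include_inverted_distractor: bool = False
    distractor_offset: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.n_copies * 2 - round(self.n_copies * 2)) > 1e-9 or self.n_copies < 0.5:
            raise ValueError("n_copies must be a multiple of 0.5 and >= 0.5")
        if not 0.0 <= self.unit_gc <= 1.0:
            raise ValueError("unit_gc must be in [0, 1]")
        if not 0.0 <= self.inter_unit_divergence <= 0.2:
            raise ValueError("inter_unit_divergence must be in [0, 0.2]")
        if self.flank5_length < 100 or self.flank3_length < 100:
            raise ValueError("flanks shorter than 100 bases make anchors unusable")
        if self.unit_length < 1:
            raise ValueError("unit_length must be positive")


@dataclass(frozen=True)
class ErrorModel:
    """Per-base error probabilities and read-length distribution.

    Rates are independent per-position event probabilities: deletion of the
    base, substitution to a uniformly random different base, and insertion of
    a uniformly random base after the position.  The default ceiling on the
    summed rates is 0.15, matching the worst-case error level of the
    single-molecule reads this emulates; pass ``max_total_rate`` to relax it.
    """

    insertion_rate: float = 0.07
    deletion_rate: float = 0.02
    substitution_rate: float = 0.01
    read_length_mean: float = 4500.0
    read_length_max: int = 33000
    seed: int = 0
    max_total_rate: float = 0.15

    def __post_init__(self) -> None:
        total = self.insertion_rate + self.deletion_rate + self.substitution_rate
        if min(self.insertion_rate, self.deletion_rate, self.substitution_rate) < 0:
            raise ValueError("rates must be non-negative")
        if total > self.max_total_rate + 1e-12:
            raise ValueError(f"total error rate {total:.3f} exceeds ceiling {self.max_total_rate}")
        if not self.read_length_max >= self.read_length_mean > 0:
            raise ValueError("need read_length_max >= read_length_mean > 0")

    @property
    def total_rate(self) -> float:
        return self.insertion_rate + self.deletion_rate + self.substitution_rate


@dataclass
class ArrayTruth:
    """A simulated locus with full provenance of every interval."""

    full_sequence: str
    flank5: Interval
    flank3: Interval
    units: list[tuple[int, Interval, str]]  # (index, interval, true unit sequence)
    unit_template: str
    distractor: Interval | None = None
    spec: ArraySpec | None = None

    @property
    def n_copies(self) -> float:
        n = 0.0
        for _, iv, _ in self.units:
            n += 1.0 if iv.name.endswith("full") else 0.5
        return n

    def intervals(self) -> list[Interval]:
        out = []
        if self.distractor is not None:
            out.append(self.distractor)
        out.append(self.flank5)
        out.extend(iv for _, iv, _ in self.units)
        out.append(self.flank3)
        return out


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability `rate`."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def build_array(spec: ArraySpec) -> ArrayTruth:
    """Build a ground-truth locus: [distractor +] flank5 + units + flank3.

    Each unit copy derives from one random GC-biased template by independent
    substitutions at the configured inter-unit divergence; a fractional copy
    is the distal-most unit truncated at its 3' side.
    """
    rng = np.random.default_rng(spec.seed)
    template = _random_seq(rng, spec.unit_length, spec.unit_gc)
    flank5 = _random_seq(rng, spec.flank5_length)
    flank3 = _random_seq(rng, spec.flank3_length)

    n_full = int(spec.n_copies)
    has_half = (round(spec.n_copies * 2) % 2) == 1
    copies = []
    for i in range(n_full + (1 if has_half else 0)):
        copies.append(_mutate(rng, template, spec.inter_unit_divergence))
    if has_half:
        copies[-1] = copies[-1][: spec.unit_length // 2]  # 3'-truncated distal unit

    parts: list[str] = []
    pos = 0
    distractor = None
    if spec.include_inverted_distractor:
        inv = revcomp(_mutate(rng, template, spec.inter_unit_divergence))
        spacer = _random_seq(rng, spec.distractor_offset)
        parts.extend([inv, spacer])
        distractor = Interval(0, len(inv), "distractor_inverted_unit", "-")
        pos = len(inv) + len(spacer)

    f5 = Interval(pos, pos + len(flank5), "flank5")
    parts.append(flank5)
    pos = f5.end
    units = []
    for i, c in enumerate(copies):
        is_partial = has_half and i == len(copies) - 1
        name = f"unit_{i + 1}_{'partial' if is_partial else 'full'}"
        iv = Interval(pos, pos + len(c), name)
        units.append((i, iv, c))
        parts.append(c)
        pos = iv.end
    f3 = Interval(pos, pos + len(flank3), "flank3")
    parts.append(flank3)

    return ArrayTruth(
        full_sequence="".join(parts),
        flank5=f5,
        flank3=f3,
        units=units,
        unit_template=template,
        distractor=distractor,
        spec=spec,
    )


def corrupt(sequence: str, model: ErrorModel, rng: np.random.Generator | None = None) -> str:
    """Apply the indel-dominated error model to one sequence.

    Per position, independently: deletion with p_del; otherwise substitution
    to a random different base with p_sub; insertion of a random base after
    the position with p_ins.  Expected edit distance to the input is close to
    (p_del + p_sub + p_ins) x length.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    n = len(arr)
    if n == 0:
        return ""
    u = rng.random(n)
    deleted = u < model.deletion_rate
    substituted = (~deleted) & (u < model.deletion_rate + model.substitution_rate)
    inserted = rng.random(n) < model.insertion_rate

    out = arr.copy()
    for i in np.nonzero(substituted)[0]:
        choices = _BASES[_BASES != arr[i]]
        out[i] = rng.choice(choices)

    n_ins = int(inserted.sum())
    ins_bases = rng.choice(_BASES, size=n_ins) if n_ins else np.empty(0, dtype=np.uint8)

    pieces: list[np.ndarray] = []
    keep = ~deleted
    ins_pos = np.nonzero(inserted)[0]
    # assemble: kept bases with insertions spliced in after their positions
    last = 0
    for idx, pos in enumerate(ins_pos):
        seg = out[last : pos + 1][keep[last : pos + 1]]
        pieces.append(seg)
        pieces.append(ins_bases[idx : idx + 1])
        last = pos + 1
    pieces.append(out[last:][keep[last:]])
    return np.concatenate(pieces).tobytes().decode("ascii")


def _lognormal_params(mean: float, sigma: float = 0.55) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the requested mean.

    sigma 0.55 gives a long right tail (max of a few tens of thousands of
    draws reaches ~6-7x the mean), matching the shape of filtered-subread
    length distributions with mean ~4.5 kb and maxima above 30 kb.
    """
    mu = math.log(mean) - sigma**2 / 2
    return mu, sigma


def sample_reads(truth: ArrayTruth, model: ErrorModel, n_reads: int) -> list[SeqRecord]:
    """Sample noisy reads from the locus.

    Each read: uniform random start on either strand, log-normal length
    truncated at ``read_length_max`` and at the end of that strand of the
    molecule (so both molecule edges are reached symmetrically).  Read ids
    encode the true coordinates, e.g.
    ``read_0007|start=1234|strand=-|len=4021``: start is the forward-strand
    start of the covered interval [start, start+len); for '-' reads the read
    is the reverse complement of that interval.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(model.seed)
    L = len(truth.full_sequence)
    mu, sigma = _lognormal_params(model.read_length_mean)
    reads: list[SeqRecord] = []
    for i in range(n_reads):
        strand = "+" if rng.random() < 0.5 else "-"
        s = int(rng.integers(0, L))  # start on the sampled strand
        length = int(min(np.rint(rng.lognormal(mu, sigma)), model.read_length_max))
        length = max(1, min(length, L - s))
        if strand == "+":
            start = s
            frag = truth.full_sequence[start : start + length]
        else:
            start = L - s - length  # forward-strand coordinates of the interval
            frag = revcomp(truth.full_sequence[start : start + length])
        seq = corrupt(frag, model, rng)
        if not seq:
            seq = "N"
        rid = f"read_{i:04d}|start={start}|strand={strand}|len={length}"
        reads.append(SeqRecord(id=rid, sequence=seq))
    return reads


def parse_read_id(read_id: str) -> dict:
    """Recover the true coordinates encoded in a simulated read id."""
    fields = dict(part.split("=") for part in read_id.split("|")[1:])
    return {"start": int(fields["start"]), "strand": fields["strand"], "len": int(fields["len"])}
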