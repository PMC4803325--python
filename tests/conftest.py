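"""Shared fixtures: two standard synthetic benchmarks, built once per session.

The perfect benchmark (seed 1, zero read error) exercises exact recovery;
the noisy benchmark (seed 42, 10% indel-dominated error) exercises the full
select -> anchored MSA -> threshold consensus path under study conditions.
Both are expensive relative to the rest of the suite, so every test that
needs them shares the session-scoped result.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from anchorcons import (
    ArraySpec,
    ArrayTruth,
    ErrorModel,
    SeqRecord,
    build_array,
    build_msa,
    call_consensus,
    revcomp,
    sample_reads,
    select_anchored_reads,
)
from anchorcons.anchored_msa import ColumnMatrix


@dataclass
class BenchmarkRun:
    truth: ArrayTruth
    reads: list[SeqRecord]
    flank5: str
    flank3: str
    group5: list
    group3: list
    matrix5: ColumnMatrix
    matrix3: ColumnMatrix
    consensus5: str
    consensus3: str


def run_benchmark(spec: ArraySpec, model: ErrorModel, n_reads: int) -> BenchmarkRun:
    truth = build_array(spec)
    reads = sample_reads(truth, model, n_reads)
    flank5 = truth.full_sequence[truth.flank5.start : truth.flank5.end]
    flank3 = truth.full_sequence[truth.flank3.start : truth.flank3.end]
    g5, g3, _ = select_anchored_reads(reads, flank5, flank3)
    m5 = build_msa(g5, anchor=flank5)
    m3 = build_msa(g3, anchor=revcomp(flank3))
    c5 = call_consensus(m5).sequence
    c3 = call_consensus(m3).sequence
    return BenchmarkRun(truth, reads, flank5, flank3, g5, g3, m5, m3, c5, c3)


@pytest.fixture(scope="session")
def perfect_run() -> BenchmarkRun:
    """Zero-error reads over a 6.5-copy array of 500 bp units (seed 1)."""
    spec = ArraySpec(
        unit_length=500, n_copies=6.5, inter_unit_divergence=0.0,
        flank5_length=500, flank3_length=500, seed=1,
    )
    model = ErrorModel(
        insertion_rate=0.0, deletion_rate=0.0, substitution_rate=0.0,
        read_length_mean=3000, seed=1,
    )
    return run_benchmark(spec, model, n_reads=40)


@pytest.fixture(scope="session")
def noisy_run() -> BenchmarkRun:
    """10% total error (7% ins / 2% del / 1% sub), 2% inter-unit divergence,
    60 reads of mean 3 kb over a 6.5-copy array (seed 42)."""
    spec = ArraySpec(
        unit_length=500, n_copies=6.5, inter_unit_divergence=0.02,
        flank5_length=500, flank3_length=500, seed=42,
    )
    model = ErrorModel(
        insertion_rate=0.07, deletion_rate=0.02, substitution_rate=0.01,
        read_length_mean=3000, seed=42,
    )
    return run_benchmark(spec, model, n_reads=60)
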