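"""End-to-end pipeline: simulate (or load) -> select -> msa -> consensus ->
analyze -> qc, with a single config, deterministic seeding and a
machine-readable summary.

Re-running with the same config produces byte-identical outputs; every
output references the config hash so parameter provenance is never lost.
"""

from __future__ import annotations

import hashlib
import json
from copy import deepcopy
from pathlib import Path

import yaml

from . import qc as qc_mod
from .align import Scoring, region_identity
from .anchor_select import FLANK3, FLANK5, select_anchored_reads
from .anchored_msa import build_msa, write_afa
from .consensus import call_consensus, write_profile
from .repeat_analysis import (
    compare_all_units,
    count_copies,
    estimate_copies_from_length,
    in_silico_digest,
    scan_motifs,
    segment_units,
)
from .seqio import SeqRecord, read_fasta, read_fastq, revcomp, write_bed, write_fasta, write_fastq
from .synthetic_data import ArraySpec, ErrorModel, build_array, sample_reads

__all__ = ["DEFAULT_CONFIG", "PipelineError", "load_config", "config_hash", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


DEFAULT_CONFIG: dict = {
    "seed": 42,
    "n_reads": 60,
    "array": {
        "unit_length": 500,
        "n_copies": 6.5,
        "unit_gc": 0.70,
        "inter_unit_divergence": 0.02,
        "flank5_length": 500,
        "flank3_length": 500,
        "include_inverted_distractor": False,
        "distractor_offset": 1000,
    },
    "errors": {
        "insertion_rate": 0.07,
        "deletion_rate": 0.02,
        "substitution_rate": 0.01,
        "read_length_mean": 3000,
        "read_length_max": 33000,
    },
    "anchor": {"min_identity": 0.85, "min_anchor_cov": 0.6, "seed_length": 13},
    "msa": {"band": 200, "match": 2, "mismatch": -4, "gap_open": -4, "gap_extend": -2},
    "consensus": {"threshold": 0.14, "min_depth": 3, "stop_window": 50},
    "analysis": {
        "min_identity": 0.8,
        "motifs": [],
        "digest_sites": [["EcoRV", "GATATC"]],
    },
    "qc": {"n_bins": 100},
    # optional real-data inputs; when set, the simulate stage is skipped:
    # "inputs": {"reads": ..., "flank5": ..., "flank3": ..., "probe": ...}
}


def _merge(base: dict, override: dict) -> dict:
    out = deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = deepcopy(v)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Default config, optionally updated from a YAML file and overrides."""
    cfg = deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _scoring(cfg: dict) -> Scoring:
    m = cfg["msa"]
    return Scoring(
        match=m["match"], mismatch=m["mismatch"],
        gap_open=m["gap_open"], gap_extend=m["gap_extend"],
    )


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute all stages; returns the summary (also written as JSON)."""
    outdir = Path(outdir)
    chash = config_hash(config)
    seed = int(config["seed"])

    inputs = config.get("inputs")
    if inputs:
        for key in ("reads", "flank5", "flank3", "probe"):
            p = inputs.get(key)
            if not p or not Path(p).exists():
                raise PipelineError(f"startup: missing input file for {key!r}: {p}")

    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": chash, "seed": seed}

    # --- simulate (or load) ------------------------------------------------
    truth = None
    try:
        if inputs:
            path = Path(inputs["reads"])
            reads = read_fastq(path) if path.suffix in {".fastq", ".fq"} else read_fasta(path)
            flank5 = read_fasta(inputs["flank5"])[0].sequence
            flank3 = read_fasta(inputs["flank3"])[0].sequence
            probe = read_fasta(inputs["probe"])[0].sequence
        else:
            spec = ArraySpec(seed=seed, **config["array"])
            model = ErrorModel(seed=seed + 1, **config["errors"])
            truth = build_array(spec)
            reads = sample_reads(truth, model, int(config["n_reads"]))
            flank5 = truth.full_sequence[truth.flank5.start : truth.flank5.end]
            flank3 = truth.full_sequence[truth.flank3.start : truth.flank3.end]
            probe = truth.unit_template
            write_fasta([SeqRecord("truth", truth.full_sequence)], outdir / "truth.fasta")
            write_bed(truth.intervals(), "truth", outdir / "truth.bed")
            write_fastq(reads, outdir / "reads.fastq")
            write_fasta([SeqRecord("flank5", flank5)], outdir / "flank5.fasta")
            write_fasta([SeqRecord("flank3", flank3)], outdir / "flank3.fasta")
            write_fasta([SeqRecord("unit_probe", probe)], outdir / "probe.fasta")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"simulate: {exc}") from exc

    # --- select ------------------------------------------------------------
    try:
        a = config["anchor"]
        g5, g3, report = select_anchored_reads(
            reads, flank5, flank3,
            min_identity=a["min_identity"], min_anchor_cov=a["min_anchor_cov"],
            seed_length=a["seed_length"], scoring=_scoring(config),
        )
        write_fasta(
            [SeqRecord(ar.read_id, ar.trimmed_sequence) for ar in g5],
            outdir / "selected.flank5.fasta",
        )
        write_fasta(
            [SeqRecord(ar.read_id, ar.trimmed_sequence) for ar in g3],
            outdir / "selected.flank3.fasta",
        )
        with open(outdir / "selection_report.tsv", "w") as fh:
            fh.write("# config=" + chash + "\n")
            fh.write("group\tn_reads\tmax_trimmed_length\tmax_depth\n")
            for row in report.rows():
                fh.write("\t".join(str(x) for x in row) + "\n")
        summary["selection"] = {
            "flank5": {"n_reads": report.n_reads[FLANK5],
                       "max_trimmed_length": report.max_trimmed_length[FLANK5],
                       "max_depth": report.max_depth[FLANK5]},
            "flank3": {"n_reads": report.n_reads[FLANK3],
                       "max_trimmed_length": report.max_trimmed_length[FLANK3],
                       "max_depth": report.max_depth[FLANK3]},
            "n_both_flanks": report.n_both_flanks,
        }
    except Exception as exc:
        raise PipelineError(f"select: {exc}") from exc

    # --- msa + consensus ---------------------------------------------------
    consensi: dict[str, str] = {}
    try:
        c = config["consensus"]
        for name, group, anch in (
            ("flank5", g5, flank5),
            ("flank3", g3, revcomp(flank3)),
        ):
            if not group:
                consensi[name] = ""
                continue
            matrix = build_msa(group, scoring=_scoring(config),
                               band=config["msa"]["band"], anchor=anch)
            write_afa(matrix, outdir / f"alignment.{name}.afa")
            res = call_consensus(matrix, threshold=c["threshold"],
                                 min_depth=c["min_depth"],
                                 stop_window=c["stop_window"])
            consensi[name] = res.sequence
            write_fasta(
                [SeqRecord(f"consensus_{name} config={chash}", res.sequence or "N")],
                outdir / f"consensus.{name}.fasta",
            )
            write_profile(res, outdir / f"consensus.{name}.profile.tsv")
    except Exception as exc:
        raise PipelineError(f"consensus: {exc}") from exc
    summary["consensus"] = {k: {"length": len(v)} for k, v in consensi.items()}

    # --- analyze -----------------------------------------------------------
    try:
        an = config["analysis"]
        blocks = {}
        for name, seq in consensi.items():
            if len(seq) < len(probe):
                continue
            # the flank3 consensus reads the array in reverse orientation
            p = probe if name == "flank5" else revcomp(probe)
            seg = segment_units(seq, p, min_identity=an["min_identity"])
            units = {
                f"{name}_u{i + 1}": seq[iv.start : iv.end]
                for i, iv in enumerate(seg.intervals)
                if not seg.partial_flags[i]
            }
            table = compare_all_units(units, scoring=_scoring(config))
            table.to_csv(outdir / f"unit_comparison.{name}.tsv", sep="\t", index=False)
            blocks[name] = {
                "n_units": len(seg.intervals),
                "copies": count_copies(seg),
                "mean_unit_identity": (
                    float(table["percent_identity"].mean()) if len(table) else None
                ),
            }
        summary["units"] = blocks
        if truth is not None:
            seg_t = segment_units(truth.full_sequence, probe, min_identity=an["min_identity"])
            region_len = truth.flank3.end - truth.flank5.start
            flank_total = len(flank5) + len(flank3)
            summary["truth"] = {
                "copies_from_segmentation": count_copies(seg_t),
                "copies_from_region_length": estimate_copies_from_length(
                    region_len, truth.spec.unit_length, flank_total
                ),
                # identity over the truth region the consensus could reach
                "identity_flank5_consensus": region_identity(
                    consensi["flank5"], truth.full_sequence,
                    (truth.flank5.start,
                     min(len(truth.full_sequence),
                         truth.flank5.start + len(consensi["flank5"]))),
                ) if consensi["flank5"] else None,
                "identity_flank3_consensus": region_identity(
                    consensi["flank3"], revcomp(truth.full_sequence),
                    (len(truth.full_sequence) - truth.flank3.end,
                     min(len(truth.full_sequence),
                         len(truth.full_sequence) - truth.flank3.end
                         + len(consensi["flank3"]))),
                ) if consensi["flank3"] else None,
            }
        if an.get("motifs"):
            units_for_motifs = {}
            for name, seq in consensi.items():
                if len(seq) >= len(probe):
                    p = probe if name == "flank5" else revcomp(probe)
                    seg = segment_units(seq, p, min_identity=an["min_identity"])
                    for i, iv in enumerate(seg.intervals):
                        if not seg.partial_flags[i]:
                            units_for_motifs[f"{name}_u{i + 1}"] = seq[iv.start : iv.end]
            if units_for_motifs:
                hits, cons = scan_motifs(units_for_motifs,
                                         [tuple(m) for m in an["motifs"]])
                hits.to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
                cons.to_csv(outdir / "motif_conservation.tsv", sep="\t", index=False)
        digest_target = truth.full_sequence if truth is not None else consensi.get("flank5", "")
        if digest_target and an.get("digest_sites"):
            frags = in_silico_digest(digest_target, [tuple(s) for s in an["digest_sites"]])
            summary["digest"] = {"n_fragments": len(frags), "fragments": frags}
    except Exception as exc:
        raise PipelineError(f"analyze: {exc}") from exc

    # --- qc ----------------------------------------------------------------
    try:
        stats = qc_mod.read_stats(reads)
        summary["read_stats"] = stats.as_row()
        gc = qc_mod.gc_distribution(reads)
        summary["gc"] = {
            label: {"n": d["n"], "mean": round(d["mean"], 4), "sd": round(d["sd"], 4)}
            for label, d in gc.items()
        }
        contig = consensi.get("flank5", "")
        if contig:
            cov = qc_mod.coverage_profile(reads, contig)
            cov.histogram.to_csv(outdir / "coverage_histogram.tsv", sep="\t", index=False)
            summary["coverage"] = {
                "n_mapped": cov.n_mapped,
                "n_unmapped": cov.n_unmapped,
                "n_multi_hit": cov.n_multi_hit,
                "mean_depth": float(cov.depth.mean()),
            }
    except Exception as exc:
        raise PipelineError(f"qc: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return summary
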