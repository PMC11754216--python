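"""End-to-end orchestration: scan → annotate → cluster → repertoire →
chain features → tree (→ synteny), from a single plain-text (YAML) config.

Every run is deterministic given (inputs, config, seed) and writes a
``manifest.json`` recording the package version, the resolved parameters, the
seed, and SHA-256 checksums of inputs and outputs — enough to reproduce the
output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import (AnnotatorParams, assign_names, build_locus_map,
                       call_segments, count_inversions, find_c_regions)
from .chain_features import classify_chain
from .families import cluster_families, identity_matrix
from .formats import rss_to_bed_frame, write_rss_gff3, write_segments_gff3
from .phylo import bootstrap, write_newick
from .repertoire import analyze_transcript, calls_to_frame, summarize
from .rss import default_model, scan
from .seq_core import Interval, read_fasta, translate, write_fasta
from .simulate import (LocusConfig, RecombinationConfig, generate_locus,
                       simulate_repertoire)
from .synteny import read_region_tsv, shared_flankers

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def _validate(cfg: dict) -> None:
    for key in ("locus_fasta", "transcripts_fasta", "c_db_fasta", "region_a", "region_b"):
        value = cfg.get(key)
        if value and not Path(value).exists():
            raise FileNotFoundError(f"config key {key}: no such file {value}")


def run_pipeline(config: dict | str | Path, out_dir: str | Path, seed: int | None = None) -> Path:
    """Run the full analysis; returns the output directory.

    With no ``locus_fasta`` in the config, a synthetic locus and repertoire
    are generated (the bundled demonstration mode); otherwise the user's
    FASTA inputs are analyzed. Any stage failure aborts with the stage name.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    if seed is not None:
        cfg["seed"] = seed
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        _validate(cfg)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("inputs", exc) from exc
    inputs: dict[str, str] = {}
    outputs: list[Path] = []

    def emit_tsv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        outputs.append(path)

    stage = "inputs"
    try:
        truth = None
        if cfg.get("locus_fasta"):
            inputs["locus_fasta"] = str(cfg["locus_fasta"])
            locus = read_fasta(cfg["locus_fasta"])[0]
        else:
            sim_keys = {k: v for k, v in (cfg.get("locus", {}) or {}).items()}
            locus_cfg = LocusConfig(seed=seed, **sim_keys)
            locus, truth = generate_locus(locus_cfg)
            write_fasta([locus], out / "locus.fasta")
            outputs.append(out / "locus.fasta")
            truth.segments.to_csv(out / "truth_segments.tsv", sep="\t", index=False)
            outputs.append(out / "truth_segments.tsv")

        stage = "scan"
        tolerance = int(cfg.get("spacer_tolerance", 1))
        m12 = default_model(12, spacer_tolerance=tolerance)
        m23 = default_model(23, spacer_tolerance=tolerance)
        threshold = cfg.get("rss_threshold")
        hits12 = scan(locus.seq, m12, threshold)
        hits23 = scan(locus.seq, m23, threshold)
        emit_tsv(rss_to_bed_frame(hits12 + hits23, locus.id), "rss_hits.tsv")
        write_rss_gff3(hits12 + hits23, locus.id, out / "rss.gff3")
        outputs.append(out / "rss.gff3")

        stage = "annotate"
        if cfg.get("c_db_fasta"):
            inputs["c_db_fasta"] = str(cfg["c_db_fasta"])
            c_db = read_fasta(cfg["c_db_fasta"])
            c_regions = find_c_regions(locus.seq, c_db)
        elif truth is not None:
            c_regions = [
                Interval(r.start, r.end, r.strand)
                for r in truth.segments[truth.segments.kind == "C"].itertuples()
            ]
        else:
            c_regions = []
        segments = call_segments(locus.seq, hits12, hits23, c_regions, AnnotatorParams())

        stage = "families"
        prefix = str(cfg.get("locus_prefix", "TRB"))
        v_segs = [s for s in sorted(segments, key=lambda s: s.ivl.start) if s.kind == "V"]
        if v_segs:
            placeholder = [(f"v{i}", s.sequence) for i, s in enumerate(v_segs)]
            matrix = identity_matrix(placeholder)
            fams = cluster_families(matrix, threshold=float(cfg.get("identity_threshold", 80.0)))
            v_families = {i: fams.mapping[f"v{i}"] for i in range(len(v_segs))}
        else:
            v_families = {}
        segments = assign_names(segments, prefix, v_families)
        write_segments_gff3(segments, locus.id, out / "segments.gff3")
        outputs.append(out / "segments.gff3")
        locus_map = build_locus_map(segments, locus_name=locus.id)
        v_named = [s for s in locus_map.segments if s.kind == "V"]
        if v_named:
            matrix = identity_matrix([(s.name, s.sequence) for s in v_named])
            emit_tsv(matrix.to_frame().reset_index(names="segment"), "identity_matrix.tsv")
            emit_tsv(matrix.to_long(), "identity_long.tsv")
            fams = cluster_families(matrix, threshold=float(cfg.get("identity_threshold", 80.0)))
            emit_tsv(fams.to_frame(), "families.tsv")

        stage = "repertoire"
        germ = {k: [] for k in "VDJC"}
        for seg in locus_map.segments:
            from .seq_core import SeqRecord

            germ[seg.kind].append(SeqRecord(id=seg.name, seq=seg.sequence))
        if cfg.get("transcripts_fasta"):
            inputs["transcripts_fasta"] = str(cfg["transcripts_fasta"])
            transcripts = read_fasta(cfg["transcripts_fasta"])
        elif truth is not None:
            rep_keys = {k: v for k, v in (cfg.get("repertoire", {}) or {}).items()}
            rep_cfg = RecombinationConfig(seed=seed, **rep_keys)
            transcripts, truth = simulate_repertoire(truth, rep_cfg)
            write_fasta(transcripts, out / "transcripts.fasta")
            outputs.append(out / "transcripts.fasta")
            truth.transcripts.to_csv(out / "truth_transcripts.tsv", sep="\t", index=False)
            outputs.append(out / "truth_transcripts.tsv")
        else:
            transcripts = []
        if transcripts:
            calls = [
                analyze_transcript(t, germ["V"], germ["D"], germ["J"], germ["C"])
                for t in transcripts
            ]
            emit_tsv(calls_to_frame(calls), "rearrangements.tsv")
            s = summarize(calls)
            emit_tsv(
                pd.DataFrame([vars(s)]),
                "repertoire_summary.tsv",
            )

        stage = "chain_features"
        rows = []
        for seg in locus_map.segments:
            if seg.kind != "C":
                continue
            ann = classify_chain(translate(seg.sequence))
            rows.append(
                dict(chain=seg.name, tm_start=ann.tm_start, tm_end=ann.tm_end,
                     charged="".join(f"{r}{i}" for i, r in ann.charged_positions),
                     chain_class=ann.chain_class)
            )
        if rows:
            emit_tsv(pd.DataFrame(rows), "chain_features.tsv")

        stage = "tree"
        if len(v_named) >= 3:
            aa = [
                SeqRecord(id=s.name, seq=translate(s.sequence), moltype="aa")
                for s in v_named
            ]
            tree = bootstrap(aa, n_reps=int(cfg.get("bootstrap_reps", 1000)), seed=seed)
            write_newick(tree, out / "v_tree.nwk")
            outputs.append(out / "v_tree.nwk")

        stage = "synteny"
        if cfg.get("region_a") and cfg.get("region_b"):
            inputs["region_a"] = str(cfg["region_a"])
            inputs["region_b"] = str(cfg["region_b"])
            report = shared_flankers(
                read_region_tsv(cfg["region_a"]),
                read_region_tsv(cfg["region_b"]),
                five_prime=cfg.get("five_prime_flanker"),
                three_prime=cfg.get("three_prime_flanker"),
                aliases=cfg.get("gene_aliases"),
            )
            emit_tsv(report.to_frame(), "synteny.tsv")
            emit_tsv(
                pd.DataFrame(
                    [dict(locus_gap_a=report.locus_gap_a, locus_gap_b=report.locus_gap_b)]
                ),
                "synteny_gaps.tsv",
            )

        stage = "manifest"
        manifest = dict(
            version=__version__,
            seed=seed,
            parameters=cfg,
            inputs={k: _sha256(Path(v)) for k, v in inputs.items()},
            outputs={p.name: _sha256(p) for p in outputs},
            segment_counts=locus_map.counts(),
            span_bp=locus_map.span_bp,
            n_inverted_v=count_inversions(locus_map),
        )
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
        raise PipelineError(stage, exc) from exc
    return out
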