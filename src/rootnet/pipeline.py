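"""End-to-end orchestration: enrich -> AGO1 filter -> profile -> scan ->
degradome validation -> expression contrast -> network.

All stages exchange data through files under ``out_dir`` (no hidden state),
mirroring how the per-stage commands compose; ``run_all`` simply drives the
library functions in order and records counts at every stage in a run
summary.  Per-stage timings go to the logger (stderr), never into the
summary, so identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

from . import degradome, enrichment, expression, network, seq_profile, target_scan
from .io_core import (
    read_expression_matrix,
    read_srna_library,
    read_transcriptome,
    read_zone_map,
)

logger = logging.getLogger(__name__)


@dataclass
class LibrarySpec:
    path: str
    library_id: str
    group: str


@dataclass
class PipelineConfig:
    transcripts: str
    libraries: list[LibrarySpec]
    out_dir: str
    expression_matrix: str | None = None
    zone_map: str | None = None
    min_rpm: float = 3.0
    fold: float = 3.0
    max_penalty: float = 3.0
    window: tuple[int, int] = (8, 12)
    min_signatures: int = 2
    max_category: int = 1
    min_fold: float = 1.0
    seed: int = 0  # recorded for provenance; the pipeline itself is deterministic

    def __post_init__(self) -> None:
        self.libraries = [
            LibrarySpec(**l) if isinstance(l, dict) else l for l in self.libraries
        ]
        lo, hi = self.window
        if not (1 <= lo <= hi <= 30):
            raise ValueError(f"cleavage window {self.window} must lie within 1..30")
        for name in ("min_rpm", "fold", "max_penalty", "min_fold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def group_ids(self, group: str) -> list[str]:
        return [l.library_id for l in self.libraries if l.group == group]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["window"] = list(self.window)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class StageError(RuntimeError):
    stage: str
    cause: Exception

    def __str__(self) -> str:
        return f"pipeline stage {self.stage!r} failed: {self.cause}"


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise StageError(stage, exc) from exc
            logger.info("stage %-10s done in %.2f s", stage, time.perf_counter() - self.t0)

    return _Timer()


def run_all(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns (and writes) the run summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")

    with _timed("load"):
        transcripts = read_transcriptome(config.transcripts)
        libs = {
            spec.library_id: read_srna_library(spec.path, spec.library_id, spec.group)
            for spec in config.libraries
        }
        rt_ids = config.group_ids("root_tip")
        wr_ids = config.group_ids("whole_root")
        ago_ids = config.group_ids("ago1")
        ctrl_ids = config.group_ids("ago_control")
        deg_ids = config.group_ids("degradome")
        if not (rt_ids and wr_ids):
            raise ValueError("need at least one root_tip and one whole_root library")

    with _timed("enrich"):
        tissue_profiles = enrichment.normalize([libs[i] for i in rt_ids + wr_ids])
        rt_results = enrichment.filter_compartment_enriched(
            tissue_profiles, rt_ids, wr_ids, config.min_rpm, config.fold, "root_tip"
        )
        wr_results = enrichment.filter_compartment_enriched(
            tissue_profiles, wr_ids, rt_ids, config.min_rpm, config.fold, "whole_root"
        )
        enrichment.write_enrichment_results(rt_results, out / "enriched_rt.tsv")
        enrichment.write_enrichment_results(wr_results, out / "enriched_wr.tsv")
        rt_enriched = enrichment.passing_sequences(rt_results)
        wr_enriched = enrichment.passing_sequences(wr_results)

    with _timed("ago_filter"):
        if ago_ids and ctrl_ids:
            ago_profiles = enrichment.normalize([libs[i] for i in ago_ids + ctrl_ids])
            rt_ago = enrichment.passing_sequences(
                enrichment.filter_ago1_enriched(
                    ago_profiles, ago_ids, ctrl_ids, config.min_rpm, config.fold,
                    candidates=rt_enriched,
                )
            )
            wr_ago = enrichment.passing_sequences(
                enrichment.filter_ago1_enriched(
                    ago_profiles, ago_ids, ctrl_ids, config.min_rpm, config.fold,
                    candidates=wr_enriched,
                )
            )
        else:
            rt_ago, wr_ago = rt_enriched, wr_enriched

    with _timed("profile"):
        profiles = [
            seq_profile.profile_set(seqs, label)
            for label, seqs in (
                ("RT_sRNA", rt_enriched),
                ("WR_sRNA", wr_enriched),
                ("RT_sRNA_AGO1", rt_ago),
                ("WR_sRNA_AGO1", wr_ago),
            )
            if seqs
        ]
        seq_profile.write_profiles(profiles, out / "profiles.tsv")

    with _timed("scan"):
        srnas = [(f"RT_AGO1_sRNA{i + 1:04d}", s) for i, s in enumerate(sorted(rt_ago))] + [
            (f"WR_AGO1_sRNA{i + 1:04d}", s) for i, s in enumerate(sorted(wr_ago))
        ]
        compartments = {sid: ("root_tip" if sid.startswith("RT_") else "whole_root") for sid, _ in srnas}
        sites = target_scan.scan_targets(srnas, transcripts, config.max_penalty)
        target_scan.write_sites(sites, out / "sites.tsv")

    with _timed("validate"):
        signals: list[degradome.DegradomeSignal] = []
        for lib_id in deg_ids:
            signals.extend(degradome.map_degradome(libs[lib_id], transcripts))
        interactions = degradome.validate_sites(
            sites,
            signals,
            window=range(config.window[0], config.window[1] + 1),
            min_signatures=config.min_signatures,
            max_category=config.max_category,
        )
        degradome.write_interactions(interactions, out / "interactions.tsv")

    contrasts = None
    n_contrary = 0
    if config.expression_matrix and config.zone_map:
        with _timed("contrast"):
            matrix = read_expression_matrix(config.expression_matrix, read_zone_map(config.zone_map))
            contrasts = expression.contrast_expression(
                matrix, interactions, compartments, config.min_fold
            )
            expression.write_contrasts(contrasts, out / "contrasts.tsv")
            n_contrary = sum(1 for c in contrasts if c.contrary)

    with _timed("network"):
        net = network.build_network(interactions, contrasts, compartments)
        net.write(out / "network.graphml", "GraphML")
        net.write(out / "network.sif", "SIF")
        net.write(out / "network_edges.tsv", "TSV")

    summary = {
        "thresholds": {
            "min_rpm": config.min_rpm,
            "fold": config.fold,
            "max_penalty": config.max_penalty,
            "window": list(config.window),
            "min_signatures": config.min_signatures,
            "max_category": config.max_category,
            "min_fold": config.min_fold,
        },
        "counts": {
            "sequences_profiled": len(tissue_profiles),
            "rt_enriched": len(rt_enriched),
            "wr_enriched": len(wr_enriched),
            "rt_ago1_enriched": len(rt_ago),
            "wr_ago1_enriched": len(wr_ago),
            "sites_predicted": len(sites),
            "interactions_validated": len(interactions),
            "distinct_pairs_validated": len({(v.srna_id, v.transcript_id) for v in interactions}),
            "contrary_targets": n_contrary,
            "network_srna_nodes": len(net.srna_nodes),
            "network_transcript_nodes": len(net.transcript_nodes),
            "network_gene_nodes": len(net.gene_nodes),
            "network_edges": len(net.edges),
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def config_for_synthetic(data_dir: str | Path, out_dir: str | Path, **overrides) -> PipelineConfig:
    """Pipeline config pointing at a directory written by the generator."""
    data_dir = Path(data_dir)
    libraries: list[LibrarySpec] = []
    group_by_prefix = {
        "RT": "root_tip",
        "WR": "whole_root",
        "AGO": "ago1",
        "CTRL": "ago_control",
        "DEG": "degradome",
    }
    for path in sorted(data_dir.glob("library_*.tsv")):
        lib_id = path.stem.removeprefix("library_")
        for prefix, group in group_by_prefix.items():
            if lib_id.startswith(prefix):
                libraries.append(LibrarySpec(str(path), lib_id, group))
                break
        else:
            raise ValueError(f"cannot infer group for library file {path.name}")
    return PipelineConfig(
        transcripts=str(data_dir / "transcripts.fasta"),
        libraries=libraries,
        out_dir=str(out_dir),
        expression_matrix=str(data_dir / "expression.tsv"),
        zone_map=str(data_dir / "zones.tsv"),
        **overrides,
    )
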