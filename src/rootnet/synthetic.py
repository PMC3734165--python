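"""Synthetic pipeline inputs with planted, machine-checkable ground truth.

The generator emulates the study design the pipeline expects: replicated
root-tip and whole-root sRNA libraries, AGO1-immunoprecipitate libraries
with a total-extract control, degradome tag libraries, a zone-labelled
expression matrix, and a small transcriptome carrying embedded binding
sites.  Planted features:

* compartment-enriched sRNAs whose per-library levels pass the enrichment
  rules by construction, against a correlated background that fails them;
* an AGO1-loaded subset with the hallmarks of AGO1 cargo (5'-U bias,
  ~21 nt) and immunoprecipitate counts exceeding the control;
* true sRNA-target interactions as (near-)reverse-complement sites
  overwritten into transcripts, each with >= 2 distinct degradome tag
  sequences whose 5' ends sit at the canonical cleavage position (opposite
  sRNA position 10 by default), above uniform background noise tags;
* contrary expression for every targeted gene, at a planted oriented fold.

Every library is padded with a single non-mapping filler sequence to a
total of exactly 1e6 reads, so raw counts equal RPM and planted pass/fail
margins are exact.  The generator nevertheless re-checks its plantings
against the real filter and scoring implementations before returning, and
raises rather than emit an inconsistent data set.  Identical seeds give
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import enrichment
from .io_core import (
    ExpressionMatrix,
    SRNALibrary,
    Transcript,
    write_expression_matrix,
    write_srna_library,
    write_transcriptome,
    write_zone_map,
)
from .target_scan import score_duplex

ZONES = (
    "root_cap",
    "division_zone",
    "elongation_zone",
    "maturation_zone_I",
    "maturation_zone_II",
    "maturation_zone_III",
    "maturation_zone_IV",
    "maturation_zone_V",
)
N_REPLICATES = 3

_RNA = np.array(list("ACGU"))
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

LIBRARY_TOTAL = 1_000_000  # every emitted library is padded to this total


class GenerationError(RuntimeError):
    """Raised when a generated data set fails its own consistency checks."""


@dataclass
class GeneratorConfig:
    seed: int = 1
    n_transcripts: int = 200
    transcript_len_range: tuple[int, int] = (600, 2000)
    n_background_srnas: int = 2000
    n_planted_rt: int = 40
    n_planted_wr: int = 40
    ago1_loaded_fraction: float = 0.5
    five_prime_u_prob_loaded: float = 0.55
    loaded_len_mode: int = 21
    unloaded_len_mode: int = 24
    n_true_interactions: int = 30
    canonical_signal_rpm_range: tuple[int, int] = (20, 200)
    noise_tag_rate: float = 2.0          # noise tags per transcript-kb per library
    expression_noise_sd: float = 0.15    # lognormal sigma on expression values
    planted_contrary_fold: float = 3.0   # oriented fold planted for targeted genes
    cleavage_srna_position: int = 10     # sRNA position opposite the planted tag 5' end
    min_rpm: float = 3.0                 # filter thresholds the plantings must satisfy
    fold: float = 3.0
    max_penalty: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ago1_loaded_fraction <= 1.0:
            raise ValueError("ago1_loaded_fraction must be in [0, 1]")
        if not 0.0 <= self.five_prime_u_prob_loaded <= 1.0:
            raise ValueError("five_prime_u_prob_loaded must be in [0, 1]")
        if self.n_true_interactions > self.n_transcripts:
            raise ValueError(
                "config infeasible: at most one interaction is planted per transcript, "
                f"so n_true_interactions ({self.n_true_interactions}) cannot exceed "
                f"n_transcripts ({self.n_transcripts})"
            )
        if not 1.0 < self.planted_contrary_fold < 4.0:
            # whole-root means include the tip samples (2 of 8 zones), which
            # caps the achievable oriented fold below 4 for whole-root sRNAs
            raise ValueError("planted_contrary_fold must lie in (1, 4)")
        if min(self.n_transcripts, self.n_background_srnas) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class TrueInteraction:
    srna_id: str
    srna_seq: str
    transcript_id: str
    start: int
    end: int
    cleavage_position: int


@dataclass
class SyntheticTruth:
    planted_rt_srnas: list[tuple[str, str]] = field(default_factory=list)  # (id, seq)
    planted_wr_srnas: list[tuple[str, str]] = field(default_factory=list)
    ago1_loaded: list[str] = field(default_factory=list)  # sequences
    true_interactions: list[TrueInteraction] = field(default_factory=list)
    contrary_genes: list[tuple[str, str, float]] = field(default_factory=list)  # (gene, compartment, fold)


@dataclass
class SyntheticDataset:
    """In-memory view of one generated data set (files optional)."""

    config: GeneratorConfig
    transcripts: list[Transcript]
    libraries: dict[str, SRNALibrary]  # keyed by library_id
    expression: ExpressionMatrix
    truth: SyntheticTruth
    files: dict[str, Path] = field(default_factory=dict)

    def libraries_in_group(self, group: str) -> list[SRNALibrary]:
        return [lib for lib in self.libraries.values() if lib.group == group]


# ---------------------------------------------------------------------------
# sequence sampling helpers
# ---------------------------------------------------------------------------


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_RNA[rng.integers(0, 4, size=length)])


def _peaked_length(rng: np.random.Generator, mode: int, lo: int = 18, hi: int = 30) -> int:
    lengths = np.arange(lo, hi + 1)
    weights = np.exp(-np.abs(lengths - mode) / 1.5)
    return int(rng.choice(lengths, p=weights / weights.sum()))


def _srna_seq(rng: np.random.Generator, loaded: bool, cfg: GeneratorConfig) -> str:
    if loaded:
        length = int(np.clip(round(rng.normal(cfg.loaded_len_mode, 1.0)), 19, 23))
        if rng.random() < cfg.five_prime_u_prob_loaded:
            first = "U"
        else:
            first = str(rng.choice(np.array(list("ACG"))))
        return first + _rand_seq(rng, length - 1)
    length = _peaked_length(rng, cfg.unloaded_len_mode, 18, 26)
    return _rand_seq(rng, length)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _correlated_counts(rng: np.random.Generator, n_libs: int) -> list[int]:
    """Counts that can never satisfy a 3-fold enrichment in either direction."""
    base = int(rng.integers(2, 201))
    return [int(rng.integers(base, int(1.8 * base) + 1)) for _ in range(n_libs)]


def generate(config: GeneratorConfig, out_dir: str | Path | None = None) -> SyntheticDataset:
    """Generate a full synthetic data set and (optionally) write it to disk."""
    rng = np.random.default_rng(config.seed)
    cfg = config

    # --- sRNA species -----------------------------------------------------
    seen: set[str] = set()

    def fresh(maker) -> str:
        for _ in range(1000):
            seq = maker()
            if seq not in seen:
                seen.add(seq)
                return seq
        raise GenerationError("could not draw a fresh unique sequence")

    n_loaded_rt = round(cfg.ago1_loaded_fraction * cfg.n_planted_rt)
    n_loaded_wr = round(cfg.ago1_loaded_fraction * cfg.n_planted_wr)

    planted_rt: list[tuple[str, str, bool]] = []  # (id, seq, loaded)
    for i in range(cfg.n_planted_rt):
        loaded = i < n_loaded_rt
        planted_rt.append(
            (f"RT_sRNA{i + 1:04d}", fresh(lambda: _srna_seq(rng, loaded, cfg)), loaded)
        )
    planted_wr: list[tuple[str, str, bool]] = []
    for i in range(cfg.n_planted_wr):
        loaded = i < n_loaded_wr
        planted_wr.append(
            (f"WR_sRNA{i + 1:04d}", fresh(lambda: _srna_seq(rng, loaded, cfg)), loaded)
        )
    background = [fresh(lambda: _srna_seq(rng, False, cfg)) for _ in range(cfg.n_background_srnas)]

    # --- transcriptome ----------------------------------------------------
    lo, hi = cfg.transcript_len_range
    transcripts_seq: list[str] = [
        _rand_seq(rng, int(rng.integers(lo, hi + 1))) for _ in range(cfg.n_transcripts)
    ]
    transcript_ids = [f"SYNT_{i + 1:04d}.1" for i in range(cfg.n_transcripts)]

    # --- true interactions: embed (near-)reverse-complement sites ---------
    loaded_srnas = [(sid, seq) for sid, seq, ld in planted_rt + planted_wr if ld]
    if cfg.n_true_interactions > 0 and not loaded_srnas:
        raise GenerationError("config infeasible: interactions requested but no AGO1-loaded sRNAs")
    truth = SyntheticTruth(
        planted_rt_srnas=[(sid, seq) for sid, seq, _ in planted_rt],
        planted_wr_srnas=[(sid, seq) for sid, seq, _ in planted_wr],
        ago1_loaded=[seq for _, seq, ld in planted_rt + planted_wr if ld],
    )
    if cfg.n_true_interactions > 0:
        if cfg.n_true_interactions <= len(loaded_srnas):
            srna_picks = list(rng.choice(len(loaded_srnas), cfg.n_true_interactions, replace=False))
        else:  # some sRNAs regulate several transcripts, as real hubs do
            srna_picks = [i % len(loaded_srnas) for i in range(cfg.n_true_interactions)]
        tx_picks = list(rng.choice(cfg.n_transcripts, cfg.n_true_interactions, replace=False))
        for srna_i, tx_i in zip(srna_picks, tx_picks):
            sid, sseq = loaded_srnas[int(srna_i)]
            L = len(sseq)
            tx_len = len(transcripts_seq[int(tx_i)])
            start = int(rng.integers(31, tx_len - L - 29))  # 1-based, >=30 nt margins
            end = start + L - 1
            site = reverse_complement(sseq)
            if rng.random() < 0.3:
                # one mismatch opposite sRNA position 1 (outside the core):
                # penalty 1.0, still comfortably under the cutoff
                s1 = sseq[0]
                forbidden = {s1.translate(_COMPLEMENT)}
                if s1 == "G":
                    forbidden.add("U")
                if s1 == "U":
                    forbidden.add("G")
                choices = [b for b in "ACGU" if b not in forbidden]
                site = site[:-1] + str(rng.choice(np.array(choices)))
            transcripts_seq[int(tx_i)] = (
                transcripts_seq[int(tx_i)][: start - 1] + site + transcripts_seq[int(tx_i)][end:]
            )
            truth.true_interactions.append(
                TrueInteraction(
                    srna_id=sid,
                    srna_seq=sseq,
                    transcript_id=transcript_ids[int(tx_i)],
                    start=start,
                    end=end,
                    cleavage_position=end - cfg.cleavage_srna_position + 1,
                )
            )
    transcripts = [Transcript(tid, seq) for tid, seq in zip(transcript_ids, transcripts_seq)]

    # --- filler sequence (absorbs the remainder of each library total) ----
    tx_blob = "\n".join(transcripts_seq)
    filler = fresh(lambda: _rand_seq(rng, 30))
    while filler in tx_blob:  # pragma: no cover - 4^-30 chance
        filler = fresh(lambda: _rand_seq(rng, 30))

    # --- tissue + AGO1 libraries ------------------------------------------
    rt_ids = [f"RT{i + 1}" for i in range(3)]
    wr_ids = [f"WR{i + 1}" for i in range(2)]
    ago_ids = ["AGO1a", "AGO1b", "AGO1c"]
    ctrl_ids = ["CTRL"]
    deg_ids = ["DEG1", "DEG2"]

    counts: dict[str, dict[str, int]] = {
        lib: {} for lib in rt_ids + wr_ids + ago_ids + ctrl_ids + deg_ids
    }

    def put(lib: str, seq: str, count: int) -> None:
        if count > 0:
            counts[lib][seq] = counts[lib].get(seq, 0) + count

    for _, seq, loaded in planted_rt:
        for lib in rt_ids:
            put(lib, seq, int(rng.integers(30, 301)))
        for lib in wr_ids:
            put(lib, seq, int(rng.integers(0, 10)))
        _fill_ago(rng, put, seq, loaded, ago_ids, ctrl_ids)
    for _, seq, loaded in planted_wr:
        for lib in wr_ids:
            put(lib, seq, int(rng.integers(30, 301)))
        for lib in rt_ids:
            put(lib, seq, int(rng.integers(0, 10)))
        _fill_ago(rng, put, seq, loaded, ago_ids, ctrl_ids)
    for seq in background:
        if rng.random() < 0.9:  # detected in tissue libraries, non-enriched
            for lib, c in zip(rt_ids + wr_ids, _correlated_counts(rng, 5)):
                put(lib, seq, c)
        if rng.random() < 0.8:  # detected in IP + control, non-enriched
            for lib, c in zip(ago_ids + ctrl_ids, _correlated_counts(rng, 4)):
                put(lib, seq, c)

    # --- degradome libraries ----------------------------------------------
    seq_by_tid = dict(zip(transcript_ids, transcripts_seq))
    sig_lo, sig_hi = cfg.canonical_signal_rpm_range
    canonical_positions: dict[str, set[int]] = {}
    for ti in truth.true_interactions:
        canonical_positions.setdefault(ti.transcript_id, set()).add(ti.cleavage_position)
        which = int(rng.integers(0, 3))  # 0: DEG1, 1: DEG2, 2: both
        libs = [deg_ids[0]] if which == 0 else [deg_ids[1]] if which == 1 else list(deg_ids)
        for lib in libs:
            n_sig = int(rng.integers(2, 4))
            total = int(rng.integers(sig_lo, sig_hi + 1))
            parts = [total // n_sig] * n_sig
            parts[0] += total - sum(parts)
            tseq = seq_by_tid[ti.transcript_id]
            c0 = ti.cleavage_position - 1
            for tag_len, part in zip((20, 21, 19), parts):
                put(lib, tseq[c0 : c0 + tag_len], part)
    for lib in deg_ids:
        for tid, tseq in zip(transcript_ids, transcripts_seq):
            n_noise = int(rng.poisson(cfg.noise_tag_rate * len(tseq) / 1000.0))
            if n_noise == 0:
                continue
            avoid = canonical_positions.get(tid, set())
            pool = [p for p in range(1, len(tseq) - 19 + 1) if p not in avoid]
            picks = rng.choice(len(pool), size=min(n_noise, len(pool)), replace=False)
            for pi in picks:
                pos = pool[int(pi)]
                put(lib, tseq[pos - 1 : pos + 19], int(rng.integers(1, 11)))

    # --- pad every library to an exact total so count == RPM --------------
    libraries: dict[str, SRNALibrary] = {}
    group_of = (
        {lib: "root_tip" for lib in rt_ids}
        | {lib: "whole_root" for lib in wr_ids}
        | {lib: "ago1" for lib in ago_ids}
        | {lib: "ago_control" for lib in ctrl_ids}
        | {lib: "degradome" for lib in deg_ids}
    )
    for lib_id, table in counts.items():
        table_sum = sum(table.values())
        if table_sum >= LIBRARY_TOTAL:
            raise GenerationError(
                f"library {lib_id} table sum {table_sum} exceeds the padded total"
            )
        table[filler] = LIBRARY_TOTAL - table_sum
        libraries[lib_id] = SRNALibrary(lib_id, group_of[lib_id], table)

    # --- expression matrix -------------------------------------------------
    compartment_of_srna = {sid: "root_tip" for sid, _, _ in planted_rt}
    compartment_of_srna.update({sid: "whole_root" for sid, _, _ in planted_wr})
    gene_of = {tid: tid.rsplit(".", 1)[0] for tid in transcript_ids}
    contrary: dict[str, str] = {}
    for ti in truth.true_interactions:
        contrary[gene_of[ti.transcript_id]] = compartment_of_srna[ti.srna_id]

    f = cfg.planted_contrary_fold
    samples = [f"{zone}_rep{r}" for zone in ZONES for r in range(1, N_REPLICATES + 1)]
    sample_zones = {f"{zone}_rep{r}": zone for zone in ZONES for r in range(1, N_REPLICATES + 1)}
    import pandas as pd

    values = np.empty((cfg.n_transcripts, len(samples)))
    genes = [gene_of[tid] for tid in transcript_ids]
    for gi, gene in enumerate(genes):
        base = float(rng.lognormal(0.0, 0.5))
        # zone multipliers chosen so the oriented (tip vs whole-root) fold
        # computed downstream equals exactly f for planted contrary genes
        if contrary.get(gene) == "root_tip":
            k_non_tip = (8 * f - 2) / 6
            mult = {z: (1.0 if z in ("root_cap", "division_zone") else k_non_tip) for z in ZONES}
        elif contrary.get(gene) == "whole_root":
            k_tip = 6 * f / (8 - 2 * f)
            mult = {z: (k_tip if z in ("root_cap", "division_zone") else 1.0) for z in ZONES}
        else:
            mult = {z: 1.0 for z in ZONES}
        noise = rng.normal(0.0, cfg.expression_noise_sd, size=len(samples))
        for si, sample in enumerate(samples):
            values[gi, si] = base * mult[sample_zones[sample]] * float(np.exp(noise[si]))
    expression = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), sample_zones
    )
    truth.contrary_genes = sorted((g, comp, f) for g, comp in contrary.items())

    dataset = SyntheticDataset(cfg, transcripts, libraries, expression, truth)
    _verify(dataset)
    if out_dir is not None:
        _write(dataset, Path(out_dir))
    return dataset


def _fill_ago(rng, put, seq: str, loaded: bool, ago_ids, ctrl_ids) -> None:
    if loaded:
        for lib in ago_ids:
            put(lib, seq, int(rng.integers(30, 301)))
        for lib in ctrl_ids:
            put(lib, seq, int(rng.integers(0, 10)))
    else:
        for lib, c in zip(list(ago_ids) + list(ctrl_ids), _correlated_counts(rng, len(ago_ids) + len(ctrl_ids))):
            put(lib, seq, c)


# ---------------------------------------------------------------------------
# emit-time verification against the real pipeline implementations
# ---------------------------------------------------------------------------


def _verify(ds: SyntheticDataset) -> None:
    cfg = ds.config
    rt_libs = [l.library_id for l in ds.libraries_in_group("root_tip")]
    wr_libs = [l.library_id for l in ds.libraries_in_group("whole_root")]
    ago_libs = [l.library_id for l in ds.libraries_in_group("ago1")]
    ctrl_libs = [l.library_id for l in ds.libraries_in_group("ago_control")]

    tissue = ds.libraries_in_group("root_tip") + ds.libraries_in_group("whole_root")
    profiles = enrichment.normalize(tissue)
    rt_pass = set(
        enrichment.passing_sequences(
            enrichment.filter_compartment_enriched(
                profiles, rt_libs, wr_libs, cfg.min_rpm, cfg.fold, "root_tip"
            )
        )
    )
    wr_pass = set(
        enrichment.passing_sequences(
            enrichment.filter_compartment_enriched(
                profiles, wr_libs, rt_libs, cfg.min_rpm, cfg.fold, "whole_root"
            )
        )
    )
    rt_seqs = {s for _, s in ds.truth.planted_rt_srnas}
    wr_seqs = {s for _, s in ds.truth.planted_wr_srnas}
    planted = rt_seqs | wr_seqs
    if not rt_seqs <= rt_pass or not wr_seqs <= wr_pass:
        raise GenerationError("a planted compartment-enriched sRNA fails its filter")
    if (rt_pass | wr_pass) - planted:
        raise GenerationError("a background sRNA passes a compartment filter")

    ago_profiles = enrichment.normalize(
        ds.libraries_in_group("ago1") + ds.libraries_in_group("ago_control")
    )
    ago_pass = set(
        enrichment.passing_sequences(
            enrichment.filter_ago1_enriched(
                ago_profiles, ago_libs, ctrl_libs, cfg.min_rpm, cfg.fold, candidates=planted
            )
        )
    )
    if ago_pass != set(ds.truth.ago1_loaded):
        raise GenerationError("AGO1-loaded planting does not match the AGO1 filter outcome")

    seq_by_tid = {t.transcript_id: t.sequence for t in ds.transcripts}
    for ti in ds.truth.true_interactions:
        window = seq_by_tid[ti.transcript_id][ti.start - 1 : ti.end]
        if score_duplex(ti.srna_seq, window) > cfg.max_penalty:
            raise GenerationError(f"planted site for {ti.srna_id} exceeds the penalty cutoff")


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------


def _write(ds: SyntheticDataset, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    files["transcripts"] = out_dir / "transcripts.fasta"
    write_transcriptome(ds.transcripts, files["transcripts"])
    for lib_id, lib in ds.libraries.items():
        path = out_dir / f"library_{lib_id}.tsv"
        write_srna_library(lib, path)
        files[f"library_{lib_id}"] = path
    files["expression"] = out_dir / "expression.tsv"
    write_expression_matrix(ds.expression, files["expression"])
    files["zones"] = out_dir / "zones.tsv"
    write_zone_map(ds.expression.sample_zones, files["zones"])

    files["truth"] = out_dir / "truth.tsv"
    with open(files["truth"], "w") as fh:
        fh.write(
            "record_type\tsrna_id\tsequence\tloaded\ttranscript_id\tstart\tend\t"
            "cleavage_position\tgene_id\tcompartment\tfold\n"
        )
        loaded = set(ds.truth.ago1_loaded)
        for sid, seq in ds.truth.planted_rt_srnas + ds.truth.planted_wr_srnas:
            fh.write(f"srna\t{sid}\t{seq}\t{seq in loaded}\t\t\t\t\t\t\t\n")
        for ti in ds.truth.true_interactions:
            fh.write(
                f"interaction\t{ti.srna_id}\t{ti.srna_seq}\t\t{ti.transcript_id}\t"
                f"{ti.start}\t{ti.end}\t{ti.cleavage_position}\t\t\t\n"
            )
        for gene, comp, fold in ds.truth.contrary_genes:
            fh.write(f"contrary_gene\t\t\t\t\t\t\t\t{gene}\t{comp}\t{fold:.6g}\n")
    ds.files = files
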