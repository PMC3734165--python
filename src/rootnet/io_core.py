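"""Readers, writers and shared conventions for the pipeline's external formats.

All sequences are held internally as uppercase RNA (``A/C/G/U``); DNA input is
accepted and ``T`` is mapped to ``U`` on read.  Transcript coordinates are
1-based and inclusive everywhere, which keeps them aligned with the way
cleavage positions are counted from an sRNA's 5' end ("10th nucleotide" means
position 10).

Formats handled here:

* sRNA / degradome read libraries: two-column TSV (sequence, count) or FASTA
  with the read count encoded in the header as a ``_xN`` suffix;
* transcriptome FASTA (one record per transcript isoform);
* gene x sample expression matrices as TSV with a zone label per sample;
* network exports as SIF, GraphML or edge-list TSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

#: valid library group labels
GROUPS = ("root_tip", "whole_root", "ago1", "ago_control", "degradome")

_DNA_TO_RNA = str.maketrans("Tt", "Uu")


def normalize_rna(seq: str) -> str:
    """Uppercase a sequence and map T to U (internal RNA alphabet)."""
    return seq.translate(_DNA_TO_RNA).upper()


@dataclass
class SRNALibrary:
    """One sequencing library: a sequence -> raw read count table.

    ``total_reads`` defaults to the table sum, but an explicit total may be
    supplied for libraries whose tabulated species do not cover every raw
    read (the total then exceeds the table sum).
    """

    library_id: str
    group: str
    counts: dict[str, int] = field(default_factory=dict)
    total_reads: int = 0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown library group {self.group!r}; expected one of {GROUPS}")
        table_sum = sum(self.counts.values())
        if self.total_reads == 0 and table_sum > 0:
            self.total_reads = table_sum
        if self.total_reads < table_sum:
            raise ValueError(
                f"total_reads ({self.total_reads}) below table sum ({table_sum}) "
                f"for library {self.library_id}"
            )
        for seq, count in self.counts.items():
            if not seq or not set(seq) <= RNA_ALPHABET:
                raise ValueError(f"invalid RNA sequence in library {self.library_id}: {seq!r}")
            if count < 0:
                raise ValueError(f"negative count for {seq} in library {self.library_id}")

    @property
    def table_sum(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class Transcript:
    """A transcript sequence with its gene identifier.

    The gene id is the transcript id with a single trailing ``.<digits>``
    isoform suffix stripped (e.g. ``LOC_Os02g43370.1`` -> ``LOC_Os02g43370``);
    ids without such a suffix are their own gene id.
    """

    transcript_id: str
    sequence: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for transcript {self.transcript_id}")
        if not self.gene_id:
            object.__setattr__(self, "gene_id", strip_isoform_suffix(self.transcript_id))
        if not self.transcript_id.startswith(self.gene_id):
            raise ValueError(
                f"gene_id {self.gene_id!r} is not a prefix of transcript_id {self.transcript_id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


_ISOFORM_RE = re.compile(r"\.\d+$")


def strip_isoform_suffix(transcript_id: str) -> str:
    """Strip one trailing ``.<digits>`` group from a transcript id."""
    return _ISOFORM_RE.sub("", transcript_id)


class ExpressionMatrix:
    """Gene x sample expression grid with a zone label per sample.

    Thin wrapper around a pandas DataFrame (genes as index, samples as
    columns) plus a ``sample_zones`` map assigning each sample to an
    anatomical zone (root cap, division zone, ...).
    """

    def __init__(self, values: pd.DataFrame, sample_zones: Mapping[str, str]):
        missing = [s for s in values.columns if s not in sample_zones]
        if missing:
            raise ValueError(f"samples missing from zone map: {missing}")
        if values.isna().any().any():
            raise ValueError("expression matrix contains missing cells")
        if (values.to_numpy() < 0).any():
            raise ValueError("expression matrix contains negative values")
        self.values = values.astype(float)
        self.sample_zones = {s: sample_zones[s] for s in values.columns}

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def zones(self) -> set[str]:
        return set(self.sample_zones.values())

    def samples_in_zones(self, zones: Iterable[str]) -> list[str]:
        zones = set(zones)
        return [s for s, z in self.sample_zones.items() if z in zones]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.values.equals(other.values) and self.sample_zones == other.sample_zones


# ---------------------------------------------------------------------------
# sRNA / degradome libraries
# ---------------------------------------------------------------------------

_FASTA_COUNT_RE = re.compile(r"_x(\d+)$")


def read_srna_library(
    path: str | Path,
    library_id: str,
    group: str,
    total_reads: int | None = None,
) -> SRNALibrary:
    """Read a read library from a count TSV or a ``_xN``-suffixed FASTA.

    TSV rows are ``sequence<TAB>count``; FASTA headers carry the count as a
    trailing ``_xN``.  T is normalized to U.  Duplicate sequences are summed.
    An explicit ``total_reads`` overrides the table-sum default.
    """
    path = Path(path)
    counts: dict[str, int] = {}
    with open(path) as handle:
        first = handle.read(1)
    if first == ">":
        for record in SeqIO.parse(str(path), "fasta"):
            m = _FASTA_COUNT_RE.search(record.id)
            if not m:
                raise ValueError(
                    f"{path}: FASTA header {record.id!r} lacks a _xN count suffix"
                )
            seq = normalize_rna(str(record.seq))
            counts[seq] = counts.get(seq, 0) + int(m.group(1))
    else:
        with open(path) as handle:
            for lineno, line in enumerate(handle, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
                seq, raw = fields
                try:
                    count = int(raw)
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-integer count {raw!r}") from None
                if count < 0:
                    raise ValueError(f"{path}:{lineno}: negative count {count}")
                seq = normalize_rna(seq)
                counts[seq] = counts.get(seq, 0) + count
    return SRNALibrary(
        library_id=library_id,
        group=group,
        counts=counts,
        total_reads=total_reads if total_reads is not None else 0,
    )


def write_srna_library(library: SRNALibrary, path: str | Path) -> None:
    """Write a library as a two-column TSV, sequences in lexicographic order."""
    with open(path, "w") as handle:
        for seq in sorted(library.counts):
            handle.write(f"{seq}\t{library.counts[seq]}\n")


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------


def read_transcriptome(path: str | Path) -> list[Transcript]:
    """Read a transcriptome FASTA into Transcript records (RNA alphabet)."""
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate transcript id {record.id!r} in {path}")
        seen.add(record.id)
        transcripts.append(Transcript(record.id, normalize_rna(str(record.seq))))
    return transcripts


def write_transcriptome(transcripts: Sequence[Transcript], path: str | Path) -> None:
    """Write transcripts as FASTA in DNA convention (U written as T)."""
    rna_to_dna = str.maketrans("Uu", "Tt")
    with open(path, "w") as handle:
        for t in transcripts:
            handle.write(f">{t.transcript_id}\n{t.sequence.translate(rna_to_dna)}\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | Path, zone_map: Mapping[str, str]) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene id) with zone labels."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression cell ({exc})") from None
    if values.isna().any().any():
        raise ValueError(f"{path}: missing or non-numeric cells in expression matrix")
    return ExpressionMatrix(values, zone_map)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def write_zone_map(sample_zones: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("sample_id\tzone\n")
        for sample, zone in sample_zones.items():
            handle.write(f"{sample}\t{zone}\n")


def read_zone_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample_id"], df["zone"]))


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("SIF", "GraphML", "TSV")


def write_network(
    edges: Iterable[tuple[str, str] | tuple[str, str, Mapping[str, object]]],
    path: str | Path,
    format: str = "SIF",
) -> None:
    """Write sRNA -> transcript edges as SIF, GraphML or edge-list TSV.

    Edges may carry an attribute mapping as a third element (kept in GraphML
    and TSV output).  Lines are ordered lexicographically by (sRNA id,
    transcript id) so output is deterministic.
    """
    norm: list[tuple[str, str, dict[str, object]]] = []
    for edge in edges:
        if len(edge) == 2:
            s, t = edge  # type: ignore[misc]
            attrs: dict[str, object] = {}
        else:
            s, t, a = edge  # type: ignore[misc]
            attrs = dict(a)
        if not s or not t:
            raise ValueError("network node ids must be non-empty")
        norm.append((s, t, attrs))
    norm.sort(key=lambda e: (e[0], e[1]))

    if format == "SIF":
        with open(path, "w") as handle:
            for s, t, _ in norm:
                handle.write(f"{s} cleaves {t}\n")
    elif format == "GraphML":
        graph = nx.Graph()
        for s, t, attrs in norm:
            graph.add_node(s, type="srna")
            graph.add_node(t, type="transcript")
            graph.add_edge(s, t, **attrs)
        nx.write_graphml(graph, str(path))
    elif format == "TSV":
        attr_keys = sorted({k for _, _, a in norm for k in a})
        with open(path, "w") as handle:
            handle.write("\t".join(["srna_id", "transcript_id", *attr_keys]) + "\n")
            for s, t, attrs in norm:
                row = [s, t] + [str(attrs.get(k, "")) for k in attr_keys]
                handle.write("\t".join(row) + "\n")
    else:
        raise ValueError(f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}")


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
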