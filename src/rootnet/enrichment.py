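"""RPM normalization and differential-accumulation filters for sRNA libraries.

Two filters share one rule shape, applied between a "target" library group A
and a "reference" group B:

1. the sRNA must be present (count > 0) in at least one library of group A;
2. in at least one group-A library its normalized level must reach
   ``min_rpm`` (default 3 reads per million) AND be at least ``fold``
   (default 3) times its level in *every* group-B library.

Both conditions are evaluated in the *same* group-A library: a library
qualifies if it alone satisfies the abundance floor and the fold excess over
the whole reference group.  With the compartment groups (root tip vs whole
root) this yields the sRNAs highly accumulated in one compartment; with
AGO1-immunoprecipitate libraries against a total-extract control it yields
the AGO1-enriched sRNAs, i.e. those loaded into slicing-competent silencing
complexes.

Absent sequences count as 0 RPM, with no pseudocount; all comparisons are
inclusive (>=), so a level of exactly 3 RPM against an undetected reference
passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_core import SRNALibrary


@dataclass
class NormalizedProfile:
    """Per-library RPM levels of one sRNA sequence (absent = 0 RPM)."""

    sequence: str
    rpm_by_library: dict[str, float] = field(default_factory=dict)

    def rpm(self, library_id: str) -> float:
        return self.rpm_by_library.get(library_id, 0.0)


@dataclass
class EnrichmentResult:
    """Outcome of one filter application for one sequence."""

    sequence: str
    target_group: str
    qualifying_libraries: list[str]
    rpm_by_library: dict[str, float]
    passed: bool


def normalize(libraries: Sequence[SRNALibrary]) -> dict[str, NormalizedProfile]:
    """Normalize raw counts to reads per million across a set of libraries.

    RPM = raw_count / total_reads * 1e6.  The result covers the union of all
    sequences; a sequence absent from a library is reported at 0 RPM.
    """
    profiles: dict[str, NormalizedProfile] = {}
    for lib in libraries:
        if lib.total_reads <= 0:
            raise ValueError(f"library {lib.library_id} has total_reads = 0; cannot normalize")
        scale = 1e6 / lib.total_reads
        for seq, count in lib.counts.items():
            prof = profiles.get(seq)
            if prof is None:
                prof = profiles[seq] = NormalizedProfile(seq)
            prof.rpm_by_library[lib.library_id] = count * scale
    for prof in profiles.values():
        for lib in libraries:
            prof.rpm_by_library.setdefault(lib.library_id, 0.0)
    return profiles


def _filter_enriched(
    profiles: Mapping[str, NormalizedProfile],
    group_a_libs: Sequence[str],
    group_b_libs: Sequence[str],
    target_group: str,
    min_rpm: float,
    fold: float,
) -> list[EnrichmentResult]:
    if not group_a_libs or not group_b_libs:
        raise ValueError("both library groups must be non-empty")
    if set(group_a_libs) & set(group_b_libs):
        raise ValueError("library groups must be disjoint")
    results = []
    for seq in sorted(profiles):
        prof = profiles[seq]
        qualifying = [
            lib
            for lib in group_a_libs
            if prof.rpm(lib) >= min_rpm
            and all(prof.rpm(lib) >= fold * prof.rpm(ref) for ref in group_b_libs)
        ]
        results.append(
            EnrichmentResult(
                sequence=seq,
                target_group=target_group,
                qualifying_libraries=qualifying,
                rpm_by_library=dict(prof.rpm_by_library),
                passed=bool(qualifying),
            )
        )
    return results


def filter_compartment_enriched(
    profiles: Mapping[str, NormalizedProfile],
    group_a_libs: Sequence[str],
    group_b_libs: Sequence[str],
    min_rpm: float = 3.0,
    fold: float = 3.0,
    target_group: str = "root_tip",
) -> list[EnrichmentResult]:
    """sRNAs highly accumulated in compartment A relative to compartment B.

    Swap the groups (and ``target_group`` label) for the opposite direction.
    """
    return _filter_enriched(profiles, group_a_libs, group_b_libs, target_group, min_rpm, fold)


def filter_ago1_enriched(
    profiles: Mapping[str, NormalizedProfile],
    ago_libs: Sequence[str],
    control_libs: Sequence[str],
    min_rpm: float = 3.0,
    fold: float = 3.0,
    candidates: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """sRNAs enriched in AGO1 immunoprecipitates over a total-extract control.

    ``candidates`` restricts the test to sequences that already passed a
    compartment filter (the serial workflow); pass ``None`` for standalone
    use on every profiled sequence.
    """
    if candidates is not None:
        wanted = set(candidates)
        profiles = {s: p for s, p in profiles.items() if s in wanted}
    return _filter_enriched(profiles, ago_libs, control_libs, "ago1", min_rpm, fold)


def passing_sequences(results: Iterable[EnrichmentResult]) -> list[str]:
    """Sorted sequences flagged as passed in a result list."""
    return sorted(r.sequence for r in results if r.passed)


def write_enrichment_results(results: Sequence[EnrichmentResult], path) -> None:
    """TSV: sequence, passed, qualifying libraries, one RPM column per library."""
    lib_ids = sorted({lib for r in results for lib in r.rpm_by_library})
    with open(path, "w") as handle:
        handle.write("\t".join(["sequence", "passed", "qualifying_libraries", *[f"rpm_{l}" for l in lib_ids]]) + "\n")
        for r in sorted(results, key=lambda r: r.sequence):
            row = [
                r.sequence,
                str(r.passed),
                ",".join(r.qualifying_libraries),
                *[f"{r.rpm_by_library.get(l, 0.0):.6g}" for l in lib_ids],
            ]
            handle.write("\t".join(row) + "\n")
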