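"""Degradome (PARE) based validation of predicted sRNA binding sites.

Degradome sequencing captures the 5' ends of uncapped mRNA fragments; an
AGO-sliced target leaves a fragment whose 5' end sits opposite the 10th-11th
nucleotide of the guiding sRNA (the canonical cleavage site).  Validation
proceeds in three steps:

1. ``map_degradome`` places every tag at each transcript position where it
   matches exactly (full length, forward strand) and aggregates, per
   (transcript, position, library), the normalized signal (RPM) and the
   number of distinct tag sequences sharing that 5' end;
2. ``validate_sites`` asks, for each predicted site, whether a signal with
   at least ``min_signatures`` distinct tag sequences falls opposite sRNA
   positions 8-12 (transcript position ``end - p + 1``), the window within
   which published cleavage signals concentrate;
3. ``classify_tplot`` grades each such signal against the full signal
   profile of its transcript (the "target plot"), replacing by-eye t-plot
   screening with a reproducible category:

   * 0 - the signal is the unique maximum on the transcript,
   * 1 - it equals the maximum, shared with at most two other positions,
   * 2 - above the median positive signal but not maximal,
   * 3 - otherwise (buried in noise).

An interaction is retained when any library yields evidence at category
<= ``max_category`` (default 1); evidence at p in {10, 11} is flagged
canonical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

from .io_core import SRNALibrary, Transcript
from .target_scan import BindingSite

logger = logging.getLogger(__name__)

CANONICAL_POSITIONS = (10, 11)
DEFAULT_WINDOW = range(8, 13)  # sRNA positions 8..12 inclusive


@dataclass
class DegradomeSignal:
    """Aggregated degradome signal at one transcript position in one library."""

    transcript_id: str
    five_prime_pos: int  # 1-based transcript position of the tags' 5' ends
    library_id: str
    rpm: float
    n_distinct_signatures: int


@dataclass
class CleavageEvidence:
    """One degradome signal supporting one binding site in one library."""

    site: BindingSite
    library_id: str
    srna_position: int          # p, counted from the sRNA 5' end
    transcript_position: int    # site.end - p + 1
    signal_rpm: float
    n_distinct_signatures: int
    canonical: bool
    category: int


@dataclass
class ValidatedInteraction:
    """A binding site with passing cleavage evidence in >= 1 library."""

    srna_id: str
    transcript_id: str
    site: BindingSite
    best_evidence: CleavageEvidence
    supporting_libraries: list[str]
    evidences: list[CleavageEvidence] = field(default_factory=list)


def map_degradome(
    tags: SRNALibrary,
    transcripts: Sequence[Transcript],
) -> list[DegradomeSignal]:
    """Map a degradome library's tags onto transcripts by exact match.

    Each tag is placed at every transcript position where its full sequence
    occurs (multi-mapping tags contribute to every transcript they match,
    unweighted).  Signals are aggregated per (transcript, 5' position):
    RPM summed over tags, distinct tag sequences counted.  Unmatched tags
    are dropped (count reported at debug level).
    """
    if tags.group != "degradome":
        raise ValueError(f"library {tags.library_id} has group {tags.group!r}, expected degradome")
    if tags.total_reads <= 0:
        raise ValueError(f"degradome library {tags.library_id} has total_reads = 0")
    scale = 1e6 / tags.total_reads

    # (transcript_id, pos) -> [rpm, {signatures}]
    agg: dict[tuple[str, int], list] = {}
    unmatched = 0
    for tag, count in tags.counts.items():
        hit = False
        for t in transcripts:
            start = t.sequence.find(tag)
            while start != -1:
                hit = True
                key = (t.transcript_id, start + 1)
                entry = agg.get(key)
                if entry is None:
                    entry = agg[key] = [0.0, set()]
                entry[0] += count * scale
                entry[1].add(tag)
                start = t.sequence.find(tag, start + 1)
        if not hit:
            unmatched += 1
    if unmatched:
        logger.debug(
            "library %s: %d tag species did not match any transcript", tags.library_id, unmatched
        )
    return [
        DegradomeSignal(
            transcript_id=tid,
            five_prime_pos=pos,
            library_id=tags.library_id,
            rpm=rpm,
            n_distinct_signatures=len(sigs),
        )
        for (tid, pos), (rpm, sigs) in sorted(agg.items())
    ]


def classify_tplot(signal: DegradomeSignal, transcript_profile: Sequence[DegradomeSignal]) -> int:
    """Grade a signal against all signals on its transcript in its library."""
    if not transcript_profile:
        raise ValueError("transcript profile is empty")
    if signal not in transcript_profile:
        raise ValueError("query signal is not part of the supplied transcript profile")
    rpms = [s.rpm for s in transcript_profile]
    peak = max(rpms)
    if signal.rpm == peak:
        n_at_peak = sum(1 for r in rpms if r == peak)
        if n_at_peak == 1:
            return 0
        if n_at_peak <= 3:  # shared with at most two other positions
            return 1
        return 3
    positive = [r for r in rpms if r > 0]
    if positive and signal.rpm > median(positive):
        return 2
    return 3


def validate_sites(
    sites: Sequence[BindingSite],
    signals: Sequence[DegradomeSignal],
    window: Iterable[int] = DEFAULT_WINDOW,
    min_signatures: int = 2,
    max_category: int = 1,
) -> list[ValidatedInteraction]:
    """Retain sites supported by clean cleavage signals in any library.

    For each site, library and sRNA position p in ``window``, evidence is
    created when a signal with >= ``min_signatures`` distinct tag sequences
    sits at transcript position ``site.end - p + 1``; the site is validated
    if any evidence is graded at category <= ``max_category``.  The reported
    ``best_evidence`` is the passing evidence with the highest RPM (ties
    broken by lower category, then lower p).
    """
    window = sorted(set(window))
    if not window:
        raise ValueError("cleavage window must be non-empty")

    by_lib_tid: dict[tuple[str, str], dict[int, DegradomeSignal]] = {}
    for sig in signals:
        by_lib_tid.setdefault((sig.library_id, sig.transcript_id), {})[sig.five_prime_pos] = sig
    profiles = {key: list(d.values()) for key, d in by_lib_tid.items()}

    interactions: list[ValidatedInteraction] = []
    for site in sites:
        evidences: list[CleavageEvidence] = []
        for (lib_id, tid), positions in by_lib_tid.items():
            if tid != site.transcript_id:
                continue
            for p in window:
                tpos = site.end - p + 1
                sig = positions.get(tpos)
                if sig is None or sig.n_distinct_signatures < min_signatures:
                    continue
                evidences.append(
                    CleavageEvidence(
                        site=site,
                        library_id=lib_id,
                        srna_position=p,
                        transcript_position=tpos,
                        signal_rpm=sig.rpm,
                        n_distinct_signatures=sig.n_distinct_signatures,
                        canonical=p in CANONICAL_POSITIONS,
                        category=classify_tplot(sig, profiles[(lib_id, tid)]),
                    )
                )
        passing = [e for e in evidences if e.category <= max_category]
        if not passing:
            continue
        best = min(passing, key=lambda e: (-e.signal_rpm, e.category, e.srna_position))
        interactions.append(
            ValidatedInteraction(
                srna_id=site.srna_id,
                transcript_id=site.transcript_id,
                site=site,
                best_evidence=best,
                supporting_libraries=sorted({e.library_id for e in passing}),
                evidences=evidences,
            )
        )
    interactions.sort(key=lambda v: (v.srna_id, v.transcript_id, v.site.start))
    return interactions


def export_tplot_data(
    transcript_id: str,
    library_id: str,
    signals: Sequence[DegradomeSignal],
    sites: Sequence[BindingSite] = (),
):
    """Per-position signal table plus site spans for drawing a target plot.

    Returns a pandas DataFrame with ``row_type`` "signal" (position, rpm)
    and "site" (start, end, srna_id) rows; signal intensity vs transcript
    position is the global t-plot, restricting to a site's span gives the
    local view.
    """
    import pandas as pd

    rows = []
    found = False
    for sig in signals:
        if sig.transcript_id == transcript_id and sig.library_id == library_id:
            found = True
            rows.append(
                {
                    "row_type": "signal",
                    "position": sig.five_prime_pos,
                    "rpm": sig.rpm,
                    "n_distinct_signatures": sig.n_distinct_signatures,
                    "srna_id": "",
                    "start": "",
                    "end": "",
                }
            )
    if not found:
        raise ValueError(f"no degradome signal for transcript {transcript_id!r} in {library_id!r}")
    for site in sites:
        if site.transcript_id == transcript_id:
            rows.append(
                {
                    "row_type": "site",
                    "position": "",
                    "rpm": "",
                    "n_distinct_signatures": "",
                    "srna_id": site.srna_id,
                    "start": site.start,
                    "end": site.end,
                }
            )
    return pd.DataFrame(rows)


def write_interactions(interactions: Sequence[ValidatedInteraction], path) -> None:
    header = (
        "srna_id\tsrna_seq\ttranscript_id\tstart\tend\tpenalty\tbest_library\t"
        "srna_position\ttranscript_position\tsignal_rpm\tn_signatures\tcanonical\t"
        "category\tsupporting_libraries\n"
    )
    with open(path, "w") as handle:
        handle.write(header)
        for v in interactions:
            e = v.best_evidence
            handle.write(
                f"{v.srna_id}\t{v.site.srna_seq}\t{v.transcript_id}\t{v.site.start}\t"
                f"{v.site.end}\t{v.site.penalty:.6g}\t{e.library_id}\t{e.srna_position}\t"
                f"{e.transcript_position}\t{e.signal_rpm:.6g}\t{e.n_distinct_signatures}\t"
                f"{e.canonical}\t{e.category}\t{','.join(v.supporting_libraries)}\n"
            )
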