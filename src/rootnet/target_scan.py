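"""Predict sRNA binding sites on transcripts by antiparallel complementarity.

Plant sRNAs (miRNAs and miRNA-like species) recognize targets through
near-perfect, ungapped base pairing.  The scanner slides each sRNA along
every transcript and scores the antiparallel duplex at each window with the
standard plant-target penalty convention:

* Watson-Crick pair          -> 0
* G:U wobble pair            -> 0.5
* mismatch                   -> 1.0
* penalties doubled at sRNA positions 2-13 (the core region, counted from
  the sRNA 5' end), where pairing is required for AGO-mediated slicing.

Windows whose total penalty does not exceed ``max_penalty`` (default 3.0,
inclusive) are reported as binding sites.  Coordinates are 1-based and
inclusive on the transcript; because the duplex is antiparallel, sRNA
position p pairs with transcript position ``end - p + 1``, the formula the
degradome stage later inverts to place cleavage signals.

All scoring constants are configurable via ``ScoringScheme``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_core import RNA_ALPHABET, Transcript

#: pairing codes used in ``BindingSite.pairing_string``
MATCH, WOBBLE, MISMATCH = "|", "o", "."

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
_WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE_PAIRS = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class ScoringScheme:
    """Per-position penalties and the core-region weighting."""

    match: float = 0.0
    wobble: float = 0.5
    mismatch: float = 1.0
    core_start: int = 2   # sRNA positions (1-based, 5'->3') with doubled weight
    core_end: int = 13
    core_weight: float = 2.0

    def position_weight(self, p: int) -> float:
        return self.core_weight if self.core_start <= p <= self.core_end else 1.0

    def pair_penalty(self, srna_base: str, transcript_base: str) -> float:
        if transcript_base == _WC_PARTNER[srna_base]:
            return self.match
        if (srna_base, transcript_base) in _WOBBLE_PAIRS:
            return self.wobble
        return self.mismatch


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class BindingSite:
    """A predicted sRNA binding location on a transcript.

    ``pairing_string`` is indexed by sRNA position 1..L from the 5' end
    ('|' match, 'o' wobble, '.' mismatch); sRNA position p pairs with
    transcript position ``end - p + 1``.
    """

    srna_id: str
    srna_seq: str
    transcript_id: str
    start: int
    end: int
    pairing_string: str
    penalty: float


def _encode(seq: str) -> np.ndarray:
    return np.frompyfunc(_BASE_INDEX.__getitem__, 1, 1)(np.array(list(seq))).astype(np.uint8)


def _pair_string(srna: str, window: str, scheme: ScoringScheme) -> str:
    # window is the transcript slice start..end 5'->3'; sRNA position p faces
    # window position L-p (0-based from the window start)
    L = len(srna)
    codes = []
    for p in range(1, L + 1):
        s, t = srna[p - 1], window[L - p]
        pen = scheme.pair_penalty(s, t)
        codes.append(MATCH if pen == scheme.match else WOBBLE if pen == scheme.wobble else MISMATCH)
    return "".join(codes)


def score_duplex(srna: str, window: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Penalty of one sRNA against one equal-length transcript window."""
    if len(srna) != len(window):
        raise ValueError("sRNA and window must have equal length")
    L = len(srna)
    total = 0.0
    for p in range(1, L + 1):
        total += scheme.position_weight(p) * scheme.pair_penalty(srna[p - 1], window[L - p])
    return total


def scan_targets(
    srnas: Sequence[tuple[str, str]],
    transcripts: Sequence[Transcript],
    max_penalty: float = 3.0,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_len: int = 18,
    max_len: int = 26,
) -> list[BindingSite]:
    """Scan every transcript window against every sRNA, ungapped.

    Returns all sites with penalty <= ``max_penalty`` (boundary inclusive),
    sorted by (srna_id, transcript_id, start).  sRNA lengths outside
    ``min_len..max_len`` or non-ACGU characters raise ``ValueError``.
    """
    for srna_id, seq in srnas:
        if not set(seq) <= RNA_ALPHABET:
            raise ValueError(f"sRNA {srna_id} contains non-ACGU characters: {seq!r}")
        if not min_len <= len(seq) <= max_len:
            raise ValueError(
                f"sRNA {srna_id} length {len(seq)} outside {min_len}-{max_len} nt"
            )

    encoded = {t.transcript_id: _encode(t.sequence) for t in transcripts}
    seq_by_id = {t.transcript_id: t.sequence for t in transcripts}

    # base penalty lookup: rows = sRNA base, cols = transcript base
    pen_base = np.empty((4, 4))
    for s, si in _BASE_INDEX.items():
        for t, ti in _BASE_INDEX.items():
            pen_base[si, ti] = scheme.pair_penalty(s, t)

    sites: list[BindingSite] = []
    for srna_id, srna in sorted(srnas):
        L = len(srna)
        srna_idx = _encode(srna)
        # column j of a length-L window faces sRNA position p = L - j;
        # fold position weights into a per-column lookup table
        colpen = np.empty((L, 4))
        for j in range(L):
            p = L - j
            colpen[j] = scheme.position_weight(p) * pen_base[srna_idx[p - 1]]
        for tid in sorted(encoded):
            arr = encoded[tid]
            if len(arr) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, L)
            totals = colpen[np.arange(L)[None, :], windows].sum(axis=1)
            for i in np.flatnonzero(totals <= max_penalty + 1e-12):
                start = int(i) + 1
                end = start + L - 1
                window = seq_by_id[tid][int(i) : int(i) + L]
                sites.append(
                    BindingSite(
                        srna_id=srna_id,
                        srna_seq=srna,
                        transcript_id=tid,
                        start=start,
                        end=end,
                        pairing_string=_pair_string(srna, window, scheme),
                        penalty=float(score_duplex(srna, window, scheme)),
                    )
                )
    sites.sort(key=lambda s: (s.srna_id, s.transcript_id, s.start))
    return sites


def write_sites(sites: Sequence[BindingSite], path) -> None:
    with open(path, "w") as handle:
        handle.write("srna_id\tsrna_seq\ttranscript_id\tstart\tend\tpenalty\tpairing_string\n")
        for s in sites:
            handle.write(
                f"{s.srna_id}\t{s.srna_seq}\t{s.transcript_id}\t{s.start}\t{s.end}\t"
                f"{s.penalty:.6g}\t{s.pairing_string}\n"
            )
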