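"""Sequence characteristics of an sRNA set: 5' nucleotide and length makeup.

AGO proteins sort sRNAs largely by 5' terminal nucleotide and length; AGO1
preferentially loads 5'-uridine, 19-21 nt species.  These profiles summarize
a set of sRNA species (each distinct sequence counted once, unweighted by
read abundance) as percentages, so a shift toward 5'-U / 21 nt after an
AGO1-enrichment filter is directly visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io_core import RNA_ALPHABET

NUCLEOTIDES = ("A", "C", "G", "U")


@dataclass
class SequenceProfile:
    set_label: str
    five_prime_pct: dict[str, float]
    length_pct: dict[int, float]
    n_sequences: int


def profile_set(sequences: Sequence[str], set_label: str) -> SequenceProfile:
    """Profile a set of sRNA species.

    Duplicates are collapsed first; percentages are over distinct sequences.
    All four nucleotides appear in ``five_prime_pct`` (possibly at 0); only
    observed lengths appear in ``length_pct``.
    """
    unique = set(sequences)
    if not unique:
        raise ValueError("cannot profile an empty sequence set")
    for seq in unique:
        if not set(seq) <= RNA_ALPHABET:
            raise ValueError(f"non-RNA sequence in profile input: {seq!r}")
    n = len(unique)
    five_counts = {nt: 0 for nt in NUCLEOTIDES}
    length_counts: dict[int, int] = {}
    for seq in unique:
        five_counts[seq[0]] += 1
        length_counts[len(seq)] = length_counts.get(len(seq), 0) + 1
    return SequenceProfile(
        set_label=set_label,
        five_prime_pct={nt: 100.0 * c / n for nt, c in five_counts.items()},
        length_pct={ln: 100.0 * c / n for ln, c in sorted(length_counts.items())},
        n_sequences=n,
    )


def write_profiles(profiles: Sequence[SequenceProfile], path) -> None:
    """TSV with one row per (set, metric, key) triple."""
    with open(path, "w") as handle:
        handle.write("set_label\tmetric\tkey\tpercent\n")
        for prof in profiles:
            for nt in NUCLEOTIDES:
                handle.write(f"{prof.set_label}\tfive_prime\t{nt}\t{prof.five_prime_pct[nt]:.6g}\n")
            for ln in sorted(prof.length_pct):
                handle.write(f"{prof.set_label}\tlength\t{ln}\t{prof.length_pct[ln]:.6g}\n")
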