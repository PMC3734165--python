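"""Complementarity scanner: hand-scored duplexes, an independent exhaustive
oracle, and the structural invariants of the site list."""

import numpy as np
import pytest

from rootnet.io_core import Transcript
from rootnet.synthetic import reverse_complement
from rootnet.target_scan import ScoringScheme, scan_targets, score_duplex

WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def oracle_penalty(srna, window):
    """Independent restatement of the scoring scheme (dict/loop based)."""
    total = 0.0
    L = len(srna)
    for p in range(1, L + 1):
        s, t = srna[p - 1], window[L - p]
        if t == WC[s]:
            pen = 0.0
        elif (s, t) in {("G", "U"), ("U", "G")}:
            pen = 0.5
        else:
            pen = 1.0
        if 2 <= p <= 13:
            pen *= 2.0
        total += pen
    return total


def oracle_scan(srnas, transcripts, max_penalty):
    hits = set()
    for sid, srna in srnas:
        L = len(srna)
        for t in transcripts:
            for i in range(len(t.sequence) - L + 1):
                window = t.sequence[i : i + L]
                pen = oracle_penalty(srna, window)
                if pen <= max_penalty:
                    hits.add((sid, t.transcript_id, i + 1, pen))
    return hits


def rand_rna(rng, n):
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, n)])


class TestScoring:
    def test_perfect_complement_scores_zero(self):
        rng = np.random.default_rng(0)
        srna = rand_rna(rng, 21)
        assert score_duplex(srna, reverse_complement(srna)) == 0.0

    def test_core_wobble_scores_one(self):
        # G at sRNA position 5; transcript carries U opposite it (G:U wobble):
        # penalty 0.5 doubled in the core region -> 1.0
        srna = "AAAAGAAAAAAAAAAAAAAA"
        window = list(reverse_complement(srna))
        window[len(srna) - 5] = "U"
        assert score_duplex(srna, "".join(window)) == 1.0

    def test_non_core_plus_core_mismatch_scores_three(self):
        # mismatch opposite position 1 (weight 1) and position 10 (weight 2)
        srna = "AAAAAAAAAAAAAAAAAAAA"
        window = list(reverse_complement(srna))
        window[len(srna) - 1] = "C"  # opposite position 1; C:A is a mismatch
        window[len(srna) - 10] = "C"
        assert score_duplex(srna, "".join(window)) == 3.0

    def test_custom_scheme_constants(self):
        scheme = ScoringScheme(wobble=1.0, core_weight=1.0)
        srna = "GAAAAAAAAAAAAAAAAAAA"
        window = list(reverse_complement(srna))
        window[len(srna) - 1] = "U"  # wobble opposite position 1
        assert score_duplex(srna, "".join(window), scheme) == 1.0


class TestScanTargets:
    def test_reverse_complement_transcript_yields_one_zero_site(self):
        rng = np.random.default_rng(1)
        srna = rand_rna(rng, 21)
        tx = Transcript("t1", reverse_complement(srna))
        sites = scan_targets([("s1", srna)], [tx])
        assert len(sites) == 1
        (site,) = sites
        assert (site.start, site.end, site.penalty) == (1, 21, 0.0)
        assert site.pairing_string == "|" * 21

    def test_boundary_inclusive_at_cutoff(self):
        srna = "AAAAAAAAAAAAAAAAAAAA"
        window = list(reverse_complement(srna))
        window[len(srna) - 1] = "C"
        window[len(srna) - 10] = "C"
        tx = Transcript("t1", "".join(window))
        assert len(scan_targets([("s1", srna)], [tx], max_penalty=3.0)) == 1
        assert scan_targets([("s1", srna)], [tx], max_penalty=2.9) == []

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(2)
        transcripts = [Transcript(f"t{i}", rand_rna(rng, 400)) for i in range(5)]
        srnas = [(f"s{i}", rand_rna(rng, 21)) for i in range(3)]
        # plant two recoverable sites (one perfect, one with a non-core mismatch)
        seq = transcripts[0].sequence
        site = reverse_complement(srnas[0][1])
        transcripts[0] = Transcript("t0", seq[:50] + site + seq[50 + len(site):])
        found = {
            (s.srna_id, s.transcript_id, s.start, s.penalty)
            for s in scan_targets(srnas, transcripts, 3.0)
        }
        assert found == oracle_scan(srnas, transcripts, 3.0)
        assert ("s0", "t0", 51, 0.0) in found

    def test_monotone_in_max_penalty(self):
        rng = np.random.default_rng(3)
        srna = rand_rna(rng, 20)
        tx = Transcript("t1", rand_rna(rng, 200) + reverse_complement(srna))
        key = lambda sites: {(s.transcript_id, s.start) for s in sites}
        loose = key(scan_targets([("s", srna)], [tx], 6.0))
        tight = key(scan_targets([("s", srna)], [tx], 2.0))
        assert tight <= loose

    def test_sorted_output(self, default_dataset):
        tx = default_dataset.transcripts[:20]
        srnas = [(sid, seq) for sid, seq in default_dataset.truth.planted_rt_srnas[:5]]
        sites = scan_targets(srnas, tx, 5.0)
        keys = [(s.srna_id, s.transcript_id, s.start) for s in sites]
        assert keys == sorted(keys)

    @pytest.mark.parametrize("bad", ["ACGT" * 5, "ACGU" * 3, "ACGU" * 7, "ACGUN" * 4])
    def test_invalid_srnas_rejected(self, bad):
        with pytest.raises(ValueError):
            scan_targets([("s", bad)], [Transcript("t", "ACGU" * 30)])
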