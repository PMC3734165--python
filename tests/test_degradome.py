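"""Degradome mapping, cleavage-window coordinates, t-plot categories and
site validation."""

import numpy as np
import pytest

from rootnet.degradome import (
    DegradomeSignal,
    classify_tplot,
    export_tplot_data,
    map_degradome,
    validate_sites,
)
from rootnet.io_core import SRNALibrary, Transcript
from tests.conftest import make_site


def rand_rna(rng, n):
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, n)])


@pytest.fixture
def transcript():
    rng = np.random.default_rng(11)
    return Transcript("t1", rand_rna(rng, 400))


def deg_lib(counts, total=None):
    lib = SRNALibrary("DEG1", "degradome", counts)
    if total is not None:
        lib.total_reads = total
    return lib


def signal(pos, rpm, n_sig=2, tid="t1", lib="DEG1"):
    return DegradomeSignal(tid, pos, lib, rpm, n_sig)


class TestMapDegradome:
    def test_exact_substring_with_closed_form_rpm(self, transcript):
        tag = transcript.sequence[100:120]  # 1-based positions 101..120
        lib = deg_lib({tag: 10}, total=1_000_000)
        (sig,) = map_degradome(lib, [transcript])
        assert (sig.five_prime_pos, sig.rpm, sig.n_distinct_signatures) == (101, 10.0, 1)

    def test_distinct_signatures_aggregate_at_one_position(self, transcript):
        t20 = transcript.sequence[100:120]
        t21 = transcript.sequence[100:121]
        lib = deg_lib({t20: 4, t21: 6}, total=1_000_000)
        (sig,) = map_degradome(lib, [transcript])
        assert sig.n_distinct_signatures == 2
        assert sig.rpm == pytest.approx(10.0)

    def test_multimapping_tag_hits_every_transcript(self, transcript):
        tag = transcript.sequence[50:70]
        other = Transcript("t2", "AUGC" * 10 + tag + "GCAU" * 10)
        lib = deg_lib({tag: 2}, total=1_000_000)
        sigs = map_degradome(lib, [transcript, other])
        assert {(s.transcript_id, s.five_prime_pos) for s in sigs} == {("t1", 51), ("t2", 41)}

    def test_unmatched_tags_silently_dropped(self, transcript):
        lib = deg_lib({"U" * 25: 5}, total=1_000_000)
        assert map_degradome(lib, [transcript]) == []

    def test_non_degradome_group_rejected(self, transcript):
        lib = SRNALibrary("L", "root_tip", {"ACGU" * 5: 1})
        with pytest.raises(ValueError, match="degradome"):
            map_degradome(lib, [transcript])


class TestClassifyTplot:
    def test_unique_maximum_is_category_0(self):
        prof = [signal(111, 50), signal(40, 5), signal(300, 1)]
        assert classify_tplot(prof[0], prof) == 0

    def test_shared_maximum_is_category_1(self):
        prof = [signal(111, 50), signal(40, 50)]
        assert classify_tplot(prof[0], prof) == 1

    def test_below_median_is_category_3(self):
        prof = [signal(111, 2), signal(40, 50), signal(300, 10), signal(55, 1)]
        # median of positive signals {2, 50, 10, 1} is 6; 2 <= 6
        assert classify_tplot(prof[0], prof) == 3

    def test_above_median_non_maximal_is_category_2(self):
        prof = [signal(111, 20), signal(40, 50), signal(300, 10), signal(55, 1)]
        assert classify_tplot(prof[0], prof) == 2

    def test_widely_shared_maximum_is_noise(self):
        prof = [signal(p, 7) for p in (10, 20, 30, 40, 50)]
        assert classify_tplot(prof[0], prof) == 3

    def test_query_must_belong_to_profile(self):
        prof = [signal(40, 5)]
        with pytest.raises(ValueError):
            classify_tplot(signal(111, 50), prof)


class TestValidateSites:
    # site spans transcript positions 101..120 (L = 20)

    def test_canonical_position_formula(self):
        site = make_site(start=101)
        sigs = [signal(111, 50)]
        (v,) = validate_sites([site], sigs)
        e = v.best_evidence
        assert (e.srna_position, e.transcript_position) == (10, 111)  # 120 - 10 + 1
        assert e.canonical and e.category == 0

    def test_position_outside_window_excluded(self):
        site = make_site(start=101)
        assert validate_sites([site], [signal(114, 50)]) == []  # p = 7

    def test_minimum_signature_threshold(self):
        site = make_site(start=101)
        assert validate_sites([site], [signal(111, 50, n_sig=1)]) == []

    def test_noisy_signal_rejected_by_category(self):
        site = make_site(start=101)
        sigs = [signal(111, 2), signal(40, 50, n_sig=1), signal(300, 10, n_sig=1)]
        assert validate_sites([site], sigs, max_category=1) == []
        (v,) = validate_sites([site], sigs, max_category=3)
        assert v.best_evidence.category == 3

    def test_any_library_suffices(self):
        site = make_site(start=101)
        sigs = [signal(111, 2, lib="DEG1"), signal(40, 50, lib="DEG1"),
                signal(111, 80, lib="DEG2")]
        (v,) = validate_sites([site], sigs)
        assert v.supporting_libraries == ["DEG2"]
        assert v.best_evidence.library_id == "DEG2"

    def test_window_coordinates_round_trip(self):
        site = make_site(start=101)
        for p in range(8, 13):
            tpos = site.end - p + 1
            assert site.end - tpos + 1 == p
            (v,) = validate_sites([site], [signal(tpos, 50)])
            assert v.best_evidence.srna_position == p
            assert v.best_evidence.canonical == (p in (10, 11))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            validate_sites([make_site()], [signal(111, 50)], window=[])

    def test_best_evidence_tie_breaks(self):
        site = make_site(start=101)
        # equal rpm at p=10 and p=12 in one library: both share the maximum
        sigs = [signal(111, 50), signal(109, 50)]
        (v,) = validate_sites([site], sigs)
        assert v.best_evidence.srna_position == 10  # lower p wins the tie


class TestExportTplot:
    def test_signal_and_site_rows(self):
        sigs = [signal(111, 50)]
        df = export_tplot_data("t1", "DEG1", sigs, [make_site(start=101)])
        assert list(df.row_type) == ["signal", "site"]
        assert df[df.row_type == "signal"].iloc[0].rpm == 50

    def test_no_sites_gives_data_rows_only(self):
        df = export_tplot_data("t1", "DEG1", [signal(111, 50)], [])
        assert list(df.row_type) == ["signal"]

    def test_unknown_transcript_rejected(self):
        with pytest.raises(ValueError):
            export_tplot_data("nope", "DEG1", [signal(111, 50)], [])
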