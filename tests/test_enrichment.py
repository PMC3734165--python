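"""RPM normalization and the two enrichment filters, pinned against an
independent brute-force restatement of the rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rootnet import enrichment
from rootnet.io_core import SRNALibrary


def lib(lib_id, group, counts):
    return SRNALibrary(lib_id, group, counts)


def profiles_from_rpm(rpm_table):
    """Build NormalizedProfile objects directly from an rpm table."""
    return {
        seq: enrichment.NormalizedProfile(seq, dict(rpms)) for seq, rpms in rpm_table.items()
    }


def brute_force_pass(rpm_table, a_libs, b_libs, min_rpm=3.0, fold=3.0):
    """Independent literal re-application of the filter rules."""
    passed = set()
    for seq in rpm_table:
        for a in a_libs:
            level = rpm_table[seq].get(a, 0.0)
            if level < min_rpm:
                continue
            ok = True
            for b in b_libs:
                if level < fold * rpm_table[seq].get(b, 0.0):
                    ok = False
                    break
            if ok:
                passed.add(seq)
                break
    return passed


class TestNormalize:
    def test_closed_forms(self):
        l1 = lib("L1", "root_tip", {"AAAA": 30}, )
        l1.total_reads = 10_000_000
        l2 = lib("L2", "whole_root", {"CCCC": 1})
        profiles = enrichment.normalize([l1, l2])
        assert profiles["AAAA"].rpm("L1") == pytest.approx(3.0)
        assert profiles["AAAA"].rpm("L2") == 0.0  # absent sequence
        assert profiles["CCCC"].rpm("L2") == pytest.approx(1_000_000.0)

    def test_zero_total_rejected(self):
        empty = SRNALibrary("L", "root_tip", {})
        with pytest.raises(ValueError, match="total_reads"):
            enrichment.normalize([empty])

    def test_rpm_sums_to_1e6_with_table_totals(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGU"))
        counts = {}
        while len(counts) < 50:
            seq = "".join(bases[rng.integers(0, 4, 20)])
            counts[seq] = int(rng.integers(1, 1000))
        library = SRNALibrary("L", "root_tip", counts)
        profiles = enrichment.normalize([library])
        total = sum(p.rpm("L") for p in profiles.values())
        assert total == pytest.approx(1e6, rel=1e-9)


class TestCompartmentFilter:
    A = ["A1", "A2", "A3"]
    B = ["B1", "B2"]

    def run(self, rpm_table, **kw):
        res = enrichment.filter_compartment_enriched(
            profiles_from_rpm(rpm_table), self.A, self.B, **kw
        )
        return {r.sequence: r for r in res}

    def test_passes_with_one_qualifying_library(self):
        res = self.run({"S": {"A1": 9, "A2": 0, "A3": 0, "B1": 2.9, "B2": 1.0}})
        assert res["S"].passed
        assert res["S"].qualifying_libraries == ["A1"]

    def test_fails_fold_against_any_reference_library(self):
        res = self.run({"S": {"A1": 9, "B1": 3.1}})
        assert not res["S"].passed

    def test_fold_against_zero_reference_is_satisfied(self):
        res = self.run({"S": {"A1": 3.0, "B1": 0, "B2": 0}})
        assert res["S"].passed  # "three times or more" than 0 holds at the rpm floor

    def test_min_rpm_boundary_inclusive(self):
        assert self.run({"S": {"A1": 3.0}})["S"].passed
        assert not self.run({"S": {"A1": 2.999999}})["S"].passed

    def test_same_library_must_satisfy_both_conditions(self):
        # A1 meets the floor but not the fold; A2 meets the fold but not the
        # floor: no single library qualifies
        res = self.run({"S": {"A1": 4.0, "A2": 2.9, "B1": 2.0, "B2": 0.5}})
        assert not res["S"].passed

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            enrichment.filter_compartment_enriched({}, ["L1"], ["L1"])

    def test_empty_profiles_give_empty_result(self):
        assert enrichment.filter_compartment_enriched({}, self.A, self.B) == []


class TestAgo1Filter:
    def test_hand_examples(self):
        table = {
            "PASS": {"G1": 10, "G2": 0, "G3": 0, "C1": 3},
            "LOW": {"G1": 2.9, "G2": 2.9, "G3": 2.9, "C1": 0},
            "ABSENT": {"C1": 5},
        }
        res = {
            r.sequence: r.passed
            for r in enrichment.filter_ago1_enriched(
                profiles_from_rpm(table), ["G1", "G2", "G3"], ["C1"]
            )
        }
        assert res == {"PASS": True, "LOW": False, "ABSENT": False}

    def test_candidates_restrict_to_compartment_survivors(self):
        table = {"X": {"G1": 100, "C1": 1}, "Y": {"G1": 100, "C1": 1}}
        res = enrichment.filter_ago1_enriched(
            profiles_from_rpm(table), ["G1"], ["C1"], candidates=["X"]
        )
        assert enrichment.passing_sequences(res) == ["X"]


@st.composite
def rpm_tables(draw):
    n = draw(st.integers(1, 30))
    libs = ["A1", "A2", "B1", "B2"]
    table = {}
    for i in range(n):
        table[f"S{i:03d}"] = {
            l: draw(st.floats(0, 20).filter(lambda x: x == x)) for l in libs
        }
    return table


class TestFilterProperties:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(rpm_tables())
    def test_matches_brute_force_oracle(self, table):
        res = enrichment.filter_compartment_enriched(
            profiles_from_rpm(table), ["A1", "A2"], ["B1", "B2"]
        )
        assert set(enrichment.passing_sequences(res)) == brute_force_pass(
            table, ["A1", "A2"], ["B1", "B2"]
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(rpm_tables(), st.floats(0, 10), st.floats(1, 6))
    def test_monotone_in_thresholds(self, table, extra_rpm, extra_fold):
        base = set(
            enrichment.passing_sequences(
                enrichment.filter_compartment_enriched(
                    profiles_from_rpm(table), ["A1", "A2"], ["B1", "B2"], 3.0, 3.0
                )
            )
        )
        tighter = set(
            enrichment.passing_sequences(
                enrichment.filter_compartment_enriched(
                    profiles_from_rpm(table),
                    ["A1", "A2"],
                    ["B1", "B2"],
                    3.0 + extra_rpm,
                    3.0 * extra_fold,
                )
            )
        )
        assert tighter <= base

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(rpm_tables())
    def test_opposite_directions_disjoint(self, table):
        fwd = set(
            enrichment.passing_sequences(
                enrichment.filter_compartment_enriched(
                    profiles_from_rpm(table), ["A1", "A2"], ["B1", "B2"]
                )
            )
        )
        rev = set(
            enrichment.passing_sequences(
                enrichment.filter_compartment_enriched(
                    profiles_from_rpm(table), ["B1", "B2"], ["A1", "A2"]
                )
            )
        )
        assert not (fwd & rev)
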