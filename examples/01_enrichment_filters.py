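"""Compartment- and AGO1-enrichment filtering of sRNA count libraries.

Builds three root-tip and two whole-root libraries with one obviously
tip-enriched sRNA, normalizes to reads per million (RPM) and applies the
two-step filter: present in >= 1 tip library at >= 3 RPM and >= 3x its
level in every whole-root library.
"""

from rootnet import SRNALibrary, filter_compartment_enriched, normalize

tip_srna = "UGACAGAAGAGAGUGAGCAC"   # planted: high in the tip, low elsewhere
flat_srna = "AAGCUCAGGAGGGAUAGCGC"  # similar everywhere: must not pass

libraries = [
    SRNALibrary("RT1", "root_tip", {tip_srna: 90, flat_srna: 40}, total_reads=1_000_000),
    SRNALibrary("RT2", "root_tip", {tip_srna: 60, flat_srna: 55}, total_reads=1_000_000),
    SRNALibrary("RT3", "root_tip", {flat_srna: 45}, total_reads=1_000_000),
    SRNALibrary("WR1", "whole_root", {tip_srna: 8, flat_srna: 50}, total_reads=1_000_000),
    SRNALibrary("WR2", "whole_root", {tip_srna: 2, flat_srna: 60}, total_reads=1_000_000),
]

profiles = normalize(libraries)
results = filter_compartment_enriched(
    profiles, ["RT1", "RT2", "RT3"], ["WR1", "WR2"], min_rpm=3.0, fold=3.0
)

for r in results:
    rpms = ", ".join(f"{lib}={rpm:.0f}" for lib, rpm in sorted(r.rpm_by_library.items()))
    print(f"{r.sequence}  passed={r.passed}  qualifying={r.qualifying_libraries}")
    print(f"    RPM: {rpms}")

# The tip sRNA passes via RT1 and RT2 (e.g. 90 RPM >= 3, >= 3x8 and >= 3x2);
# the flat sRNA fails because no tip library reaches 3x its whole-root levels.
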