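# Methods

This note documents the models, conventions and design choices behind each
pipeline stage, what the synthetic-data generator does and does not
emulate, and the numerical details that affect results.

## Conventions

* Sequences are held as uppercase RNA; `T` is mapped to `U` on input, and
  transcriptome FASTA is written back in DNA convention. sRNA and degradome
  tags arrive in both conventions in practice, so normalizing once on read
  keeps every downstream comparison alphabet-safe.
* Transcript coordinates are 1-based and inclusive everywhere, matching the
  field's habit of counting "the 10th nucleotide of the sRNA".
* Gene ids derive from transcript ids by stripping one trailing
  `.<digits>` isoform suffix (the TIGR/MSU rice naming convention, e.g.
  `LOC_Os02g43370.1` → `LOC_Os02g43370`); ids without the suffix are their
  own gene.
* Library totals default to the count-table sum; an explicit total can be
  supplied for libraries whose tables omit some raw reads (totals from all
  reads vs mapped reads are both representable — the data decide).

## Enrichment filters

RPM = raw count / total reads × 10⁶. The enrichment rule between a target
group A and reference group B: a sequence passes iff **some single library
L ∈ A** has rpm(L) ≥ `min_rpm` (default 3) and rpm(L) ≥ `fold` ×
rpm(M) for **every** M ∈ B (default fold 3). Reading both conditions
against the same library is the strictest conjunction of the two published
rules; the alternative (floor in any detecting library) can be emulated by
composing the primitives, and the brute-force oracle test pins whichever
reading is configured. Absent sequences count 0 RPM with no pseudocount,
so a reference level of 0 is beaten by any level ≥ the floor — a
consequence worth knowing: raising `fold` alone never removes candidates
whose reference group is all-zero. All comparisons are inclusive. No
statistical test is performed (the procedure is a deterministic screen,
not an inference); replicate-aware shrinkage is out of scope.

The AGO1 filter is the same rule over immunoprecipitate vs control
libraries, applied to the compartment survivors (serial workflow); a
`candidates=None` call runs it standalone.

## Sequence profiles

Profiles are computed over distinct sequence species, unweighted by read
abundance, because the filtered sets are species lists; percentages (5′
nucleotide over {A, C, G, U}; lengths over observed values) each sum
to 100.

## Target scanning

Every length-L window of every transcript is scored against each sRNA,
ungapped and antiparallel: sRNA position p (1-based from the 5′ end) faces
transcript position `end − p + 1`. Per-position penalties: Watson–Crick 0,
G:U wobble 0.5, mismatch 1.0, doubled at sRNA positions 2–13 (the core
region where pairing is required for slicing); sites with total penalty
≤ 3.0 (inclusive) are reported. This is the widely used plant
target-prediction convention; all constants live in a `ScoringScheme` and
are configurable. Gapped alignments/bulges are excluded so that site
coordinates are unambiguous for the degradome stage. The implementation is
a vectorized sliding-window lookup; a pure-Python exhaustive enumerator in
the test suite serves as its independent oracle.

## Degradome validation

Tags are matched to transcripts exactly, full-length, forward strand
(a direct substring search — with transcript-scale inputs nothing faster is
needed, and exactness is the contract). Multi-mapping tags count toward
every position they match, unweighted. Signals aggregate per (transcript,
5′ position, library): RPM summed over tags, distinct tag *sequences*
counted — "distinct signatures with accordant 5′ ends" is read as distinct
sequences, not distinct reads, which is what differing tag lengths at one
cleavage point produce in real PARE data.

Evidence requires a signal with ≥ 2 distinct signatures at transcript
position `end − p + 1` for some p in 8..12; p ∈ {10, 11} is flagged
canonical. Signals are then graded against the transcript's full signal
profile in that library (the target plot):

| category | meaning |
|---|---|
| 0 | unique maximum on the transcript |
| 1 | equals the maximum, shared with ≤ 2 other positions |
| 2 | above the median positive signal, not maximal |
| 3 | otherwise |

An interaction passes when any library yields evidence at category ≤ 1
(default). The category cutoff is the package's reproducible surrogate for
manual t-plot inspection: category ≤ 1 corresponds to "the cleavage signal
is the transcript's peak", the unambiguous case. Evidence is evaluated per
library; support in any one library suffices. `export_tplot_data` emits
the per-position table from which global and local t-plots are drawn.

## Contrary expression

The root-tip mean pools the root-cap and division-zone samples (6 samples
at 3 replicates each); the whole-root mean pools **all** samples — the
whole root anatomically contains the tip, and pooling all 24 arrays keeps
the contrast consistent with whole-root sRNA libraries. The oriented fold
is whole-root/tip for targets of tip-enriched sRNAs and tip/whole-root
otherwise; `contrary` means fold ≥ `min_fold`, defaulting to 1.0 (any
contrary direction) since the screen is qualitative. A zero denominator
with positive numerator gives +inf (contrary at any threshold); genes
absent from the matrix are reported with a missing marker and never
flagged. Expression values are consumed as given — microarray
preprocessing is out of scope.

## Network

The transcript-level bipartite graph is primary; the gene-collapsed view
is always derived by suffix-stripping, never stored. Multiple validated
sites for one (sRNA, transcript) pair collapse to one edge keeping the
best evidence (lowest category, then canonical first). Exports: GraphML
(typed node/edge attributes, lossless round-trip), SIF
(`srna cleaves transcript`), edge-list TSV; lines ordered
lexicographically for determinism.

## Synthetic data generator

The generator emulates the study design the pipeline expects: 3 root-tip +
2 whole-root sRNA libraries, 3 AGO1 IP libraries + 1 total-extract
control, 2 degradome libraries, an 8-zone × 3-replicate expression matrix,
and a 200-transcript transcriptome (600–2000 nt). Defaults: 2000
background sRNAs, 40 planted per compartment, half of each AGO1-loaded,
30 true interactions.

Key constructions:

* **Exact-RPM padding.** Every library is padded with one shared 30-nt
  filler sequence (checked not to occur in the transcriptome) to a total
  of exactly 10⁶ reads, so raw counts equal RPM and planted pass/fail
  margins are exact rather than approximate. The filler behaves as one
  more background species.
* **Enriched vs background counts.** Planted sRNAs get 30–300 RPM in
  their compartment and 0–9 in the other (30 ≥ 3 × 9, so they always
  pass); background sRNAs get per-library counts within a 1.8× band of a
  shared base level, which can never satisfy a 3-fold rule in either
  direction. The loaded subset repeats the scheme for IP vs control.
  Regardless of construction, the generator re-runs the real enrichment
  filters and the real duplex scorer on its output and raises if any
  planting is inconsistent — recovery tests cannot be flaky.
* **AGO1-loaded sequence bias**: 5′-U probability 0.55 and lengths near
  21 nt (mode ±1); unloaded and background species peak at 24 nt with
  uniform 5′ composition — the compositional signature of AGO1 sorting.
* **Interactions**: each planted interaction overwrites a transcript
  window (≥ 30 nt from both ends) with the sRNA's reverse complement
  (30% receive one non-core mismatch, penalty 1); at most one interaction
  per transcript so each planted cleavage signal can be its transcript's
  maximum. Degradome tags of lengths 19/20/21 (2–3 distinct signatures)
  share the 5′ end at the position opposite sRNA nucleotide 10
  (configurable via `cleavage_srna_position`, which the boundary tests
  move to 7/8/12/13), with aggregate signal 20–200 RPM; noise tags are
  real transcript substrings at ~2 per kb per library, 1–10 RPM,
  single-signature, drawn away from the planted positions.
* **Expression**: per-gene lognormal base level; targeted genes get zone
  multipliers solved so the oriented fold equals the planted value
  (default 3.0 — comfortably above the 1.5 recovery threshold yet under
  the ceiling of 4 imposed by the tip samples being part of the whole-root
  mean); multiplicative lognormal noise with σ = 0.15, small enough that
  null-gene folds stay below 2 across hundreds of genes.

Not emulated: sequencing error, adapter contamination, compositional
realism of the rice genome, isoform families (one isoform per gene), or
abundance-correlated degradome background. Passing recovery tests
therefore demonstrate correctness of the pipeline's logic under the
declared study design, not performance on real libraries, where
signal/noise margins are far less favorable.

## Problem sizes and determinism

The default generator design (200 transcripts, ~2100 sRNA species, ~10⁶
reads per library) runs the full pipeline in a few seconds; the test-suite
oracles use 5–20 transcripts so exhaustive enumeration stays fast. All
randomness flows from one `numpy` `default_rng(seed)`; identical seeds
give byte-identical files, and the pipeline itself is deterministic given
its inputs (stage outputs sort their rows; run summaries exclude timings,
which go to the logger).
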