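# Methods

## Coordinate model

Reference coordinates are 0-based and half-open everywhere internally.  A
guide target stores the protospacer footprint on the plus strand
(`proto_start`) and a between-bases cleavage coordinate `cut_site` (the
integer *k* means "between ref[k−1] and ref[k]"): `proto_start + 17` for a
plus-strand guide and `proto_start + 3` for a minus-strand guide, i.e.
always 3 nt upstream of the PAM in guide orientation.  User-facing positions
are signed cut-relative labels with no 0 — the base immediately left of the
cut is −1, immediately right +1.  For minus-strand guides the labels follow
the guide's own 5'→3' orientation, so −1 is always the PAM-distal neighbour
of the cut; this choice is not forced by anything in the data (figures in
the field report per-target labels without defining the minus-strand case)
and is recorded in the run report's `conventions` block.  The PAM is stored
and validated but never used to gate analysis, so relaxed-PAM experiments
(NGA/NGC/NG) are handled identically.

## Read merging

Mate 2 is reverse-complemented and slid over mate 1; among overlaps of at
least `min_overlap` (default 10) whose mismatch fraction is at most
`max_mismatch_frac` (default 0.1), the merger picks the overlap maximizing
matches − mismatches, preferring the longer overlap on ties.  Consensus
bases take the higher-quality mate (mate 1 on quality ties); consensus
quality is max(q₁, q₂) on agreement and |q₁ − q₂| on conflict.  This is a
deliberate simplification of the maximum-likelihood assembly test used by
dedicated mergers: merging is a commodity step whose pass rate is ~99% on
real libraries, the downstream analysis is insensitive to merger internals,
and users can run any external merger and enter via the `--pre-merged`
single-end path.  Quality handling is fixed to Sanger Phred+33.

## Trimming, N filtering, tag dedup

Quality trimming removes bases from each end until the terminal base reaches
`q_threshold` (default Q20) and drops reads shorter than `min_len` (default
50 nt); this flank rule stands in for an external trimmer whose exact
settings are a user choice, and both parameters are exposed in the config.
Reads containing any N are then removed entirely (on real data ~0.02% of
reads), which also guarantees that the subsequent 5-nt tags are N-free.
After stripping the two 5-nt tags, identical inserts are collapsed: the raw
count is the number of reads, the adjusted count the number of distinct
(tag5, tag3) pairs — reads identical in sequence *and* both tags are PCR
duplicates of one founder molecule.  Tag identity is exact string equality;
no edit-distance clustering of near-identical tags is attempted, because
the tag's job here is duplicate marking, not molecule barcoding.  Both
counts are carried through every downstream table so the size of the
duplicate correction (`tag_effect`, reported as raw/adjusted frequency
folds) is always measurable.

## Alignment and score filter

Each unique sequence is aligned globally to the amplicon reference with an
affine-gap Needleman–Wunsch (Gotoh three-state DP, numba-compiled).  The
scoring follows the EMBOSS `needle` defaults for nucleotides: match +5 and
mismatch −4 (the EDNAFULL matrix restricted to A/C/G/T), gap opening 10.0
and extension 0.5.  Two conventions had to be fixed where tool versions
disagree:

* a gap of length L costs `gap_open + L·gap_extend` (the first gapped base
  pays opening *and* extension);
* end gaps are free by default (`end_gaps_free=True`), which keeps
  truncated inserts alignable over the full reference; the flag is exposed
  because it shifts scores of short fragments near the retention threshold.

Tie-breaking is deterministic — diagonal first, then gap-in-query, then
gap-in-ref — which places every indel at its leftmost score-equivalent
position.  This left-shift is what makes insertion anchors at repeats
reproducible (an "insertion at −1" vs "+1" is otherwise alignment-arbitrary)
and is stated in the run report.  Alignments scoring below `min_score`
(default 200 ≙ 40 cleanly matched bases) are discarded as unrelated to the
amplicon; the threshold is a config default, not a constant, and the
discard fraction is reported per unique sequence, not per read.

The DP is verified two ways in the test suite: exhaustive enumeration of all
global alignments for short pairs (an independent scorer that walks move
strings), and Biopython's `PairwiseAligner` configured to the same cost
model for long pairs.

## Mutation calling and tallies

A maximal run of gap-in-query columns is one deletion event (reference
interval); a maximal run of gap-in-ref columns is one insertion event
anchored at the first reference base to its right; each substituted column
is a one-base mismatch event.  Applying an alignment's events back to the
reference reconstructs the query exactly (property-tested), so the event set
is a lossless encoding of the read.  Adjacent but distinct events (mismatch
next to an indel) stay separate; no complex-event merging is attempted.

Per-position tallies cover non-primer positions only.  A deletion increments
every position it covers (matching the logo's "absence of a base at this
position" semantics); spectra count each deletion interval once.  Insertions
increment only their anchor.  Frequencies divide by all retained reads
(adjusted by default, raw in parallel): amplicon-wide coverage is uniform by
construction in this assay, so per-position denominators equal the retained
total.

## Summaries

* **Enrichment** compares weighted events *starting or ending* inside the
  20-nt protospacer window against those outside, per base (window length
  20 vs non-primer length − 20).  A zero outside rate yields an explicit
  +∞ fold with the raw counts alongside, never a silent NaN.
* **Large deletions** on dual-guide amplicons are deletion events whose
  interval spans both cut sites; endpoints are labelled per target and the
  reported length is the reference interval length, which equals the
  cut-to-cut distance plus the absolute endpoint labels.
* **Substitution profiles** cover the window plus a 10-nt flank (truncated
  at primers).  The C→T fraction is the share of window mismatches that are
  C→T on the guide strand; the editing window is the set of guide-strand C
  positions edited above `editing_min_freq` (default 5% of retained reads,
  comfortably above the sequencing-error floor of ~0.03% per transition and
  below practically relevant editing rates).
* **Condition comparisons** are descriptive frequency folds over shared
  spectrum keys against a baseline run; no hypothesis testing is attached,
  and comparisons are only meaningful for runs from one experiment.

## Logo

The logo model holds, per non-primer column: the reference base, the
consensus (modal observed state among reference/alternative bases/deleted,
reference winning ties) and alternative outcomes ranked by frequency, capped
at 4 rows.  Insertion glyphs are overlaid on their anchor column (keyed by
first inserted base) rather than given inter-column slots.  Rendering is a
pure function of the model: fixed glyph grid, opacity = frequency divided by
the column maximum (floor 0.05 so rare outcomes stay visible — per-column
rather than global normalization keeps low-efficiency runs legible),
purple for substituted/inserted bases, green for deletion 'D', an arrow at
each cut site.  Re-rendering the same model is byte-identical.

## Simulator

The generator draws founder molecules i.i.d. from an event spectrum
(deletion/insertion/substitution templates in cut-relative labels, plus an
unedited fraction), tags each end with a uniform random 5-mer, duplicates
each founder `1 + Poisson(pcr_dup_mean − 1)` times with the same tags, and
cuts overlapping paired reads from the tagged insert, applying per-base
substitution errors and N conversions independently per copy and mate.
Defaults are the study conditions this package is built around: 20,000
founders, 15× mean duplication, 0.1% per-base substitution error (the
PCR + sequencer mismatch floor), 0.02% N rate, 150-nt reads, 5-nt tags.
Everything is driven by one seed and is byte-deterministic.

What the simulator does *not* model: cycle-dependent quality profiles,
PCR chimeras, polymerase indel errors (an optional homopolymer-deletion
error mode exists for exploring that failure class), tag-sequence biases,
and coverage falloff.  Passing recovery tests therefore demonstrate the
pipeline's correctness under substitution-type noise and heavy duplication,
not robustness to every instrument artifact.

Recovered template frequencies are measured by canonical event signatures:
each template's molecule is aligned back to the reference, so a template's
nominal coordinates are replaced by whatever the left-shifting aligner
produces; a unique sequence is assigned to the most specific template whose
signature its calls contain (exact equality in zero-noise closed-loop
tests).  Per-read (raw) weights reproduce founder fractions exactly when
duplication is 1; tag-adjusted weights are the right estimator under uneven
duplication, at the cost of a small undercount from birthday-collision tag
pairs (≈0.5% relative at 10⁴ same-sequence founders over the 4¹⁰ tag-pair
space).

## Numerical and degenerate-input choices

Scores are float64 (multiples of 0.5 under the default scheme, so
comparisons at the 200 threshold are exact).  Empty inputs abort with a
named pipeline stage.  Reads shorter than two tag lengths are dropped with a
counted reason.  Collapse order (descending adjusted count, then sequence)
and every spectrum/table sort are total orders, making all outputs
permutation-invariant to input read order.  Enrichment folds with zero
events on both sides report 1.0 with zero counts attached (no evidence of
enrichment) rather than NaN.

## Problem sizes used in the checks

Statistical recovery checks run at 20,000 founders × 15× duplication
(~300k read pairs, ~6k unique sequences) with all tolerances at 3 binomial
σ of the realized truth; closed-loop identity runs at 5,000 founders with a
10-template spectrum; oracle equivalences use 200 random pairs of length
≤ 8 (alignment enumeration), 1,000 toy read sets (dedup grouping) and 1,000
random alignments (event round-trip).  These sizes were chosen so that each
check's discriminating power is set by the 3σ bands, and the whole suite
runs in a few minutes on one CPU.
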