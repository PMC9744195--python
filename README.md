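# amplimut

Quantification of CRISPR/Cas9 targeted-mutagenesis and base-editing outcomes
from amplicon deep sequencing of pooled cells (e.g. transiently transformed
plant protoplasts), with PCR-duplicate correction via random 5-nt primer
tags.

When a pool of cells is edited and the target locus amplified and sequenced,
every read is a sample from the spectrum of repair outcomes: deletions and
insertions centred on the Cas9 cleavage site (3 nt upstream of the PAM,
between protospacer positions 17 and 18) after double-strand break repair,
or C→T transitions in a deaminase window for cytidine base editors.  The
difficulty is turning ~10⁷ reads into unbiased per-outcome frequencies: PCR
re-amplifies each founder molecule unevenly, sequencing errors masquerade as
mutations, and indel-bearing reads must still be aligned over the full
amplicon.  `amplimut` implements a seven-step pipeline for exactly this:

1. **Merge** overlapping paired-end reads into one insert (consensus takes
   the higher-quality base; conflict quality = |q₁−q₂|).
2. **Quality-trim** low-quality flanks and **drop** reads containing N.
3. **Extract the 5-nt random end tags** and **collapse** to unique
   sequences; a read count is *tag-adjusted* by counting only distinct
   (tag5, tag3) pairs per sequence, so PCR duplicates of one founder
   molecule count once.
4. **Align** each unique sequence globally to the amplicon reference with
   Needleman–Wunsch under EMBOSS-needle-style scoring — match +5,
   mismatch −4 (the EDNAFULL values for plain A/C/G/T), a gap of length *L*
   costing `gapopen 10.0 + L × gapextend 0.5`, end gaps free — and
   **discard** alignments scoring below 200.
5. **Call mutations** (deletion intervals, anchored insertions, per-base
   mismatches) and tally them per reference position in cut-site-relative
   coordinates (−1 is the first base left of the cut, +1 the first base
   right; there is no position 0), excluding primer regions.
6. **Summarize**: deletion/insertion spectra, target-window vs flank
   enrichment, large deletions spanning dual guides, per-position
   substitution matrices with C→T fraction and editing window, tag-effect
   folds, and between-condition fold changes.
7. **Render a mutation logo**: reference row, consensus row, and ranked
   alternative outcomes with letter intensity proportional to frequency
   ('D' marks deletion).

A synthetic-read simulator (`amplimut.simulate`) generates the same kind of
data with a known ground truth — editing-outcome templates with
probabilities, Poisson PCR duplication with shared tags, substitution/N
sequencing errors — so the whole pipeline is testable end to end without
any sequencing run.

## Worked example

```python
from amplimut import SimConfig, run_pipeline, simulate_dataset
from amplimut.example import example_spec, example_spectrum, example_target
from amplimut.simulate import recovered_frequencies, truth_frequencies

spec = example_spec()            # 178-bp amplicon, one NGG guide, cut at 79
target = example_target(spec)
spectrum = example_spectrum()    # del(-2,-1) 25%, ins(-1,T) 10%,
                                 # C->T at -13 15%, unedited 50%

cfg = SimConfig(n_molecules=2000, pcr_dup_mean=3.0, seq_error_rate=0.001,
                n_rate=0.0002, seed=7)
pairs, truth = simulate_dataset(spec, target, spectrum, cfg)
result = run_pipeline(spec, pairs=pairs)

print(f"read pairs: {result.counts['pairs_in']},",
      f"merged: {result.counts['merged']},",
      f"unique sequences: {result.counts['unique_sequences']}")
weights = {a.query_id: a.weight for a in result.kept}
recovered = recovered_frequencies(spec, target, spectrum,
                                  result.events_by_source, weights)
for tid, p in truth_frequencies(truth, spectrum).items():
    print(f"{tid:12s} truth {p:.3f}  recovered {recovered[tid]:.3f}")
g1 = result.report["summaries"]["targets"]["g1"]
print("editing window:", g1["editing_window"],
      " C>T fraction: %.2f" % g1["ct_fraction"])
```

prints

```
read pairs: 6076, merged: 6076, unique sequences: 768
del_-2_-1    truth 0.243  recovered 0.240
ins_-1_T     truth 0.112  recovered 0.115
sub_-13_C_T  truth 0.152  recovered 0.154
unedited     truth 0.493  recovered 0.491
editing window: [-13]  C>T fraction: 0.81
```

i.e. from 6,076 noisy read pairs the pipeline recovers each outcome
frequency to within a few tenths of a percent of the realized truth,
localizes the base edit to position −13 and reports that 81% of
protospacer-window mismatches are C→T.

## Command line

```sh
amplimut simulate --config run.yaml --out-dir sim/      # FASTQ + truth
amplimut run --config run.yaml --fastq1 sim/reads_1.fastq \
             --fastq2 sim/reads_2.fastq --out-dir out/  # full pipeline
amplimut run --config run.yaml --pre-merged merged.fastq --out-dir out/
amplimut align --config run.yaml --query seqs.fasta     # alignments
amplimut logo out/                                      # re-render SVG
amplimut compare outA/ outB/                            # condition folds
```

The run config is a single YAML file naming the amplicon (inline sequence or
FASTA), the primer sequences or intervals, the guides (protospacer + IUPAC
PAM), all thresholds, and optionally a `simulate:` section.  `run` writes
collapsed FASTA, per-position/event/spectrum/enrichment/substitution TSVs,
the logo (SVG + JSON) and a JSON run report with per-step counts and every
parameter.

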