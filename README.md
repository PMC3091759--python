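# beskit

A toolkit for BAC-end-sequence (BES) genome surveys. Before a genome is
fully sequenced, end-sequencing tens of thousands of large-insert BAC
clones yields an inexpensive ~5% sample of it. From that sample a survey
estimates GC content, the microsatellite spectrum and density,
transposable-element content, the coding fraction, and — because the two
reads of a clone are linked by a ~100–150 kb insert — microsynteny with
already-sequenced relatives. `beskit` implements each survey stage as a
tested library (plus a thin `beskit` CLI), together with a synthetic-data
generator that plants features with a ground-truth ledger so every stage
can be validated by exact recovery.

## What it computes

- **Redundancy assembly** — greedy overlap clustering of reads into
  contigs and singletons at a minimum overlap *L* ≥ 80 bp and identity
  ≥ 95% over the aligned overlap (gaps count as mismatches), both
  orientations considered; plus a two-stage cross-assembly of two
  libraries with a redundancy report.
- **SSR scanning** — maximal perfect tandem repeats with unit length
  *k* = 1–6; reported when total length ≥ 12 nt (*k* ≤ 3) or ≥ 4 units
  (*k* ≥ 4). Motifs are collapsed into strand/rotation classes: the
  canonical unit is min over all rotations of the motif and of its
  reverse complement (TTC, GAA, CTT ↦ AAG/CTT). Summaries report density
  (kb per SSR), length bins, and class I counts (> 20 nt).
- **Repeat classification** — maps repeat-annotation rows
  (RepeatMasker-style tables) into the plant-repeat taxonomy
  (Ty1-Copia/Ty3-Gypsy LTR retroelements, LINEs, DNA-transposon
  superfamilies, Helitrons, rRNA, telomeric), computes class ratios and
  hard-masks annotated spans.
- **EST homology tiers** — a query is assigned to the first transcript
  database in precedence order (own species → close relatives → all
  plants) with a hit at E ≤ 10⁻²⁰; E ≤ 10⁻⁵⁰ flags high stringency. The
  two totals bracket the coding fraction, and the own-species share of
  hits scales the unigene count into a transcriptome-size estimate.
- **Paired-BES microsynteny** — each end's hits are merged into anchors
  (same subject/strand within 10 kb); every same-subject anchor pair is a
  mapping locus, classified collinear when anchor separation lies in
  50–500 kb (inclusive) and the reads are convergent on opposite strands.
  Orientation can be relaxed to admit localized inversions; loci per pair
  measure subject-genome duplication.
- **Survey arithmetic** — genome-equivalent coverage
  (clones × true fraction × insert / genome size), GC content, length
  statistics, and a structured report; percentages rounded half-up to one
  decimal.

## Worked example

`examples/05_paired_end_synteny.py` simulates a 500-kb source genome, a
related target sharing two 200-kb blocks (each inverted with probability
0.5), and 60 BAC pairs with ~130-kb inserts, then runs the collinearity
funnel:

```
pairs simulated: 60
both ends mapped: 36; same subject: 28; in 50-500 kb window: 28; correctly oriented: 28
collinear share of all pairs: 46.7%
```

All 28 pairs whose inserts lie inside a shared block pass all three
criteria — wholesale-inverted blocks still pass because both reads flip
together and stay convergent. The other examples cover SSR scanning
(`01`), assembly (`02`), repeat classification and masking (`03`), EST
tiers (`04`) and coverage arithmetic (`06`); each prints the numbers it
computes with a closing comment on what they mean.

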