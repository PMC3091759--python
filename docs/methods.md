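# Methods

## Scope and model

A BAC-end-sequence (BES) survey samples a genome with paired end-reads
of large-insert clones. `beskit` models the downstream analysis of such
a survey: the homology and repeat searches themselves are external (their
tabular outputs are inputs here), while redundancy clustering, SSR
detection, repeat-class accounting, tiered EST classification,
paired-end collinearity and all summary arithmetic are implemented in
the package. One coordinate convention holds internally — 0-based,
half-open, strand as an explicit field — with 1-based inclusive
coordinates (and swapped-coordinate minus strands) only at file
boundaries.

## SSR scanner

An SSR is a maximal perfect tandem run of a primitive unit of 1–6 nt.
Reporting thresholds default to total length ≥ 12 nt for units of 1–3 nt
and ≥ 4 whole units for 4–6 nt; both are expressed internally as a
minimum total length per unit size, so a run may end mid-unit and copy
number is real-valued (a length criterion, not a whole-copy criterion).
Ns never match, so runs break at ambiguity codes. Primitivity of the
unit (no smaller period divides it) prevents the same run from being
reported once per divisor of its period.

Canonicalization takes the lexicographic minimum over all rotations of
the unit and all rotations of its reverse complement; the class label
shows the minimum rotation on each strand (AAG/CTT) or a single form
when both strands agree (AT). Every summary is therefore invariant under
reverse-complementing the input, which the tests check.

Nested-run suppression: candidates are ranked by longest total span,
then smallest unit, then leftmost start, and a candidate wholly inside
an accepted locus is dropped. Tools differ and rarely document their
tie-breaking; this rule is deterministic and is the one the exhaustive
oracle implements too. Length bins are inclusive of their lower bound
(12–20, 21–50, 51–100, >100 nt), making 21 nt the class I threshold
(consistent with "longer than 20 nt"). Density is kb of scanned sequence
per SSR, one decimal.

## Redundancy assembly

Reads are clustered greedily: sorted by descending length (ties by id),
each read joins the first cluster, in creation order, whose current
consensus gives an accepted overlap — a semi-global dovetail/containment
alignment (free end gaps, match +2 / mismatch −3 / gap open −6 /
extend −2) spanning ≥ 80 columns at ≥ 95% identity, with gaps counted as
mismatches and both orientations of the incoming read tried. Because
consensus growth can reveal overlaps between clusters founded early, a
cluster-merge pass then runs to a fixed point; on clean data this makes
membership equal the connected components of the all-pairs overlap
graph, which is the property the oracle tests assert.

Consensus is a gap-free layout: members are placed at integer offsets
from their accepted alignments and each column takes the majority base,
ties resolved by the longest member (then smallest id). This is exact in
the substitution-dominated regime the 95% identity threshold admits;
overlaps requiring indel-aware layout would need a true multiple
alignment, which is out of scope. Cross-assembly feeds two assemblies'
contigs and singletons through the same algorithm under prefixed ids and
reports the sequence-count and bp reduction.

The "minimum match of 95%" threshold is interpreted as per-overlap
identity (not whole-sequence identity); this is an assumption, stated
here because clustering tools are ambiguous about it.

## Repeat summary

The counting unit is the annotation row; fragmented elements are not
defragmented, matching how surveys count homology matches rather than
reconstructed elements. Classification is by a longest-substring alias
table over the family and declared-class labels, editable per
RepeatMasker version; labels matching nothing fall back to the
Unclassified leaf of a recognisable declared class, else to a global
Unclassified bucket. Transposable elements are retroelements + DNA
transposons + rolling circles; rRNA and telomere-related sequences are
counted but excluded from TE ratios. Masking is hard-N by default (the
mode used before homology searches); masked bp is the union of spans,
so masking is idempotent.

## EST homology tiers

Databases are consulted in caller-supplied precedence order; a query
consults database *k* only if none of databases 1..k−1 gave a hit at the
low cut-off (default 10⁻²⁰), so tier counts partition queries with hits.
The high-stringency flag (default 10⁻⁵⁰) is judged on the assigned
tier's best hit only — later databases are not re-searched at high
stringency — which reproduces the two-column structure of published
tier tables and guarantees high ≤ low per tier. Best hit per (query,
database) is lowest E-value, then highest bit score, then file order.
The transcriptome-size estimate is capture-style: if the own-species
unigene set explains fraction *f* of all EST-homologous sequences, the
transcriptome is unigene count / *f*, reported to the nearest 1,000.
Published lower bounds derived by other (unstated) routes are not
asserted equal to this formula's output.

## Paired-BES synteny

A "mapping locus" needs an operational definition before it can be
counted: here, each end's hits are first merged into anchors — hits on
the same subject and strand whose midpoints fall within a 10-kb merge
window collapse to their best-E representative — and every same-subject
(anchor, anchor) combination is one locus. Separation is measured
between anchor midpoints; the 50–500 kb window is inclusive at both
bounds. Correct orientation means opposite strands with the plus-strand
anchor not to the right of the minus-strand anchor (the two reads of a
clone face inward on the insert); relaxing it admits regions that
underwent localized inversions, and can only grow the collinear count.
A block inverted wholesale keeps its pairs collinear — both reads flip
together — so inversion breaks orientation only when it separates the
two ends. Subject sequence ids are treated uniformly as "chromosomes";
no adjacency is inferred across scaffolds. The funnel (both ends hit ≥
same subject ≥ in window ≥ correctly oriented) is monotone by
construction.

## Synthetic data

The generator's defaults are the survey conditions: background bases
i.i.d. at 35.2% GC; end-reads 50–879 bp with mean 543 bp drawn from a
truncated normal whose sd puts ~99% of mass inside the bounds on the
tighter side; insert sizes normal truncated at ±3 sd; the number of
non-empty clones is round(n_clones × (1 − empty fraction)); SSR motifs
weighted toward A-rich mono-, AT di- and AAT trinucleotides; repeat
families weighted toward LTR retroelements with a Ty1-Copia majority.
Restriction libraries draw both insert boundaries from ledgered
restriction-site positions (BamHI motif occurrences), reproducing the
coverage bias of one-enzyme libraries; random-shear libraries draw
starts uniformly.

Exact recovery requires that scanning noise-free output return precisely
the ledger, so backgrounds are scrubbed: spans that could meet the SSR
thresholds (found with whole-unit backreference patterns, with the
length cut-off lowered by unit−1 to cover partial final units) are
resampled until none remain; planted SSRs get flank guards that stop
periodic extension; and a final pass rewrites any stray run created at
feature junctions, never touching planted spans. Planted repeat and gene
interiors are scrubbed the same way.

The related-genome simulator copies non-overlapping source blocks
(placed by stick-breaking so dense requests cannot fragment-fail) into
the target with per-copy wholesale inversion, substitution-only
divergence (indels are excluded so exact search remains a valid oracle),
and copies of one block on distinct target chromosomes whenever the
multiplicity allows. In planted-recovery experiments the spacers between
blocks are chosen longer than the collinearity window, so anchors in
different blocks can never satisfy the separation criterion and the
planted truth set is unambiguous. A gap-free exact-seed matcher
(`naive_search`) stands in for the external homology search in these
synthetic end-to-end runs only; its crude m·n·2^−bits E-value is for
thresholding synthetic data, not a search-tool replacement.

What the generator does not emulate: chimeric clones, cloning bias
beyond restriction-site placement, chemistry-specific error profiles,
indel divergence, and compound/interrupted SSRs. Passing recovery tests
therefore demonstrates correctness of the survey logic on
substitution-only data, not robustness to those artefacts.

## Numerical conventions and problem sizes

Percentages, coverages and densities are rounded half-up to one decimal
(integer counts never rounded); this convention reproduces the published
derived ratios recomputed in the validation suite, with a handful of
published figures that no stated rounding reproduces excluded from
assertion. Validation problem sizes are chosen to exercise each property
at small scale: oracle equivalence on ~1,000 random sequences up to
5 kb, assembly-vs-components on 200 fragmented templates, planted-feature
recovery over 5 seeds, and loci-per-pair convergence with 1,000
simulated pairs on a duplicated target.

## Known limitations

Consensus quality degrades near the 95% identity floor (gap-free
layout); the alias table ships tuned to common RepeatMasker label
conventions and should be edited for other annotators; anchor-merge
window and midpoint separation are the two knobs in the locus
definition, and published locus counts from surveys that defined loci
differently will not be bit-reproducible; clustering at survey scale
(tens of thousands of reads) is quadratic in the worst case and is meant
for reduced-scale studies, not production assembly.
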