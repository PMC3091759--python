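"""Synthetic genomes, BAC libraries and related genomes with ground truth.

Every simulator here records what it planted in a ledger, so downstream
scanners and classifiers can be validated by exact recovery: a scanner
run over noise-free simulated data must return precisely the ledger.

The defaults emulate a two-library BAC-end survey of a mid-sized plant
genome: background base composition at 35.2% GC, end-reads of 50-879 bp
with mean 543 bp, insert sizes around 120-139 kb, one library drawing
insert boundaries only from restriction sites (coverage bias) and one
random-shear library, SSR motifs in realistic proportions (A-rich
mononucleotides dominating, then AT dimers and AAT trimers), and
transposable-element fragments dominated by LTR retroelements with a
Ty1-Copia majority. A related target genome shares collinear blocks with
the source, optionally duplicated across target chromosomes and inverted
wholesale, with substitution-only divergence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from beskit._util import revcomp, round_half_up
from beskit.io_formats import (
    BesPair, BesRead, End, Library, RepeatHit, SequenceRecord,
)
from beskit.ssr_scanner import DEFAULT_SSR_THRESHOLDS, canonical_motif

__all__ = [
    "GenomeModel", "FeatureLedger", "FeatureRequest", "LibrarySpec",
    "SyntenySpec", "CloneTruth", "BlockPlacement", "BlockOrientation",
    "simulate_genome", "simulate_library", "simulate_library_detailed",
    "simulate_related_genome", "gene_records",
]

DEFAULT_GC = 0.352
RESTRICTION_MOTIF = "GGATCC"  # BamHI

#: default SSR motif pool (unit, relative weight), survey-like proportions
DEFAULT_SSR_MOTIFS: tuple[tuple[str, float], ...] = (
    ("A", 0.36), ("C", 0.02),
    ("AT", 0.16), ("AG", 0.06), ("AC", 0.02),
    ("AAT", 0.15), ("AAG", 0.08), ("ATC", 0.012), ("AAC", 0.01), ("AGG", 0.01),
    ("AAAT", 0.022), ("AAAG", 0.01), ("ACAT", 0.004),
    ("AGCCG", 0.012), ("AAAAG", 0.007), ("AAAAT", 0.003),
    ("AAAAAG", 0.002), ("AAAAAT", 0.001),
)

#: default repeat-family pool: (family label, declared class, leaf path, weight)
DEFAULT_REPEAT_FAMILIES: tuple[tuple[str, str, tuple[str, ...], float], ...] = (
    ("Copia-%d_Syn", "LTR/Copia", ("Retroelements", "LTR", "Ty1/Copia"), 0.503),
    ("Gypsy-%d_Syn", "LTR/Gypsy", ("Retroelements", "LTR", "Ty3/Gypsy"), 0.285),
    ("L1-%d_Syn", "LINE/L1", ("Retroelements", "LINES", "L1"), 0.012),
    ("LTRX-%d_Syn", "LTR", ("Retroelements", "LTR", "Unclassified"), 0.017),
    ("hobo-%d_Syn", "DNA/hAT", ("DNA transposons", "", "hobo-Activator"), 0.014),
    ("EnSpm-%d_Syn", "DNA/En-Spm", ("DNA transposons", "", "En-Spm"), 0.069),
    ("MuDR-%d_Syn", "DNA/MuDR", ("DNA transposons", "", "MuDR"), 0.041),
    ("Harbinger-%d_Syn", "DNA/Harbinger", ("DNA transposons", "", "Harbinger"), 0.002),
    ("DNAX-%d_Syn", "DNA", ("DNA transposons", "", "Unclassified"), 0.009),
    ("Helitron-%d_Syn", "RC/Helitron", ("Rolling circles", "", "Helitron"), 0.005),
    ("telomeric-%d_Syn", "Telomere", ("Telomere-related", "", "Telomere-related"), 0.001),
    ("SSU-18S-%d_Syn", "rRNA", ("rRNA genes", "", "Small subunit"), 0.015),
    ("LSU-25S-%d_Syn", "rRNA", ("rRNA genes", "", "Large subunit"), 0.025),
    ("45S-ITS-%d_Syn", "rRNA", ("rRNA genes", "", "45S and Internal spacer region"), 0.003),
)


class BlockOrientation(str, Enum):
    SAME = "SAME"
    INVERTED = "INVERTED"


@dataclass
class GeneSpan:
    seq_id: str
    start: int
    end: int


@dataclass
class FeatureLedger:
    """Everything the simulator planted, appended as it happens."""

    ssrs: list = field(default_factory=list)  # list[SsrLocus]
    repeats: list[RepeatHit] = field(default_factory=list)
    genes: list[GeneSpan] = field(default_factory=list)
    restriction_sites: dict[str, list[int]] = field(default_factory=dict)


@dataclass
class GenomeModel:
    sequences: list[SequenceRecord]
    ledger: FeatureLedger

    @property
    def total_bp(self) -> int:
        return sum(len(s.sequence) for s in self.sequences)


@dataclass(frozen=True)
class FeatureRequest:
    """What to plant per chromosome set (totals over the whole genome)."""

    n_ssrs: int = 0
    ssr_motifs: tuple[tuple[str, float], ...] = DEFAULT_SSR_MOTIFS
    ssr_len_range: tuple[int, int] = (12, 60)
    n_repeats: int = 0
    repeat_families: tuple[tuple[str, str, tuple[str, ...], float], ...] = DEFAULT_REPEAT_FAMILIES
    repeat_len_range: tuple[int, int] = (150, 800)
    n_genes: int = 0
    gene_len_range: tuple[int, int] = (300, 1500)
    n_restriction_sites: int = 0
    gc: float = DEFAULT_GC


@dataclass(frozen=True)
class LibrarySpec:
    class Method(str, Enum):
        RESTRICTION = "RESTRICTION"
        RANDOM_SHEAR = "RANDOM_SHEAR"

    n_clones: int
    mean_insert: int
    insert_sd: int
    method: "LibrarySpec.Method"
    seed: int
    empty_fraction: float = 0.0
    read_len_min: int = 50
    read_len_max: int = 879
    read_len_mean: int = 543
    library: Library = Library.OTHER
    clone_prefix: str = "clone"

    def __post_init__(self) -> None:
        if not 0 < self.read_len_min <= self.read_len_mean <= self.read_len_max:
            raise ValueError("need 0 < read_len_min <= read_len_mean <= read_len_max")
        if not 0.0 <= self.empty_fraction < 1.0:
            raise ValueError("empty_fraction must be in [0, 1)")


@dataclass(frozen=True)
class SyntenySpec:
    n_blocks: int
    block_len: tuple[int, int]
    seed: int
    inversion_prob: float = 0.0
    duplication_multiplicity: int | tuple[int, ...] = 1
    divergence: float = 0.0
    n_target_chrom: int = 2
    spacer_len: int = 25_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.inversion_prob <= 1.0:
            raise ValueError("inversion_prob must be in [0, 1]")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must be in [0, 1)")


@dataclass(frozen=True)
class CloneTruth:
    clone_id: str
    chrom: str
    insert_start: int
    insert_end: int


@dataclass(frozen=True)
class BlockPlacement:
    source_chrom: str
    source_start: int
    source_end: int
    target_chrom: str
    target_start: int
    target_end: int
    orientation: BlockOrientation
    copy_index: int


# ---------------------------------------------------------------------------
# random background free of reportable chance SSRs

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=n, p=p)
    return _BASES[idx].tobytes().decode()


def _chance_ssr_spans(seq: str) -> list[tuple[int, int]]:
    """Conservative spans that might hold a reportable SSR.

    Backreference regexes catch only whole-unit tandems, so the length
    cut-off is lowered by unit-1 to cover partial final units.
    """
    spans = []
    for k, min_total in DEFAULT_SSR_THRESHOLDS.items():
        pat = re.compile(r"([ACGT]{%d})\1+" % k)
        for m in pat.finditer(seq):
            if m.end() - m.start() >= min_total - (k - 1):
                spans.append((m.start(), m.end()))
    return spans


def _scrubbed_random(rng: np.random.Generator, n: int, gc: float, max_iter: int = 60) -> str:
    """Random bases with no span that the SSR scanner could report."""
    seq = list(_random_bases(rng, n, gc))
    for _ in range(max_iter):
        spans = _chance_ssr_spans("".join(seq))
        if not spans:
            return "".join(seq)
        for s, e in spans:
            seq[s:e] = _random_bases(rng, e - s, gc)
    raise RuntimeError("could not scrub chance SSRs from background")


# ---------------------------------------------------------------------------
# genome simulation

class _Packer:
    """Non-overlapping interval placement with a guard gap."""

    def __init__(self, length: int, gap: int = 2):
        self.length = length
        self.gap = gap
        self.taken: list[tuple[int, int]] = []

    def place(self, rng: np.random.Generator, size: int, max_tries: int = 50) -> int:
        if size + 2 * self.gap > self.length:
            raise ValueError("feature larger than chromosome")
        for _ in range(max_tries):
            start = int(rng.integers(self.gap, self.length - size - self.gap + 1))
            if all(e + self.gap <= start or start + size + self.gap <= s
                   for s, e in self.taken):
                self.taken.append((start, start + size))
                return start
        # dense regime: enumerate the free gaps and draw uniformly from
        # the starts that actually fit
        feasible: list[tuple[int, int]] = []  # [lo, hi] inclusive start ranges
        edges = sorted(self.taken)
        prev_end = 0
        for s, e in edges + [(self.length, self.length)]:
            lo = max(prev_end + self.gap, self.gap)
            hi = min(s - self.gap, self.length - self.gap) - size
            if hi >= lo:
                feasible.append((lo, hi))
            prev_end = max(prev_end, e)
        if not feasible:
            raise ValueError("infeasible feature packing: density too high")
        weights = np.array([hi - lo + 1 for lo, hi in feasible], dtype=float)
        gi = int(rng.choice(len(feasible), p=weights / weights.sum()))
        lo, hi = feasible[gi]
        start = int(rng.integers(lo, hi + 1))
        self.taken.append((start, start + size))
        return start


def simulate_genome(
    n_chrom: int,
    chrom_len: int,
    features: FeatureRequest = FeatureRequest(),
    seed: int = 0,
) -> GenomeModel:
    """Simulate pseudomolecules with planted, ledgered features.

    Background bases are i.i.d. at the requested GC and scrubbed of chance
    runs that would meet the SSR reporting thresholds, so an SSR scan of
    the output returns exactly the ledger. Planted SSRs get flank guards
    that stop the run from extending into the background. Deterministic
    given the seed.
    """
    from beskit.ssr_scanner import SsrLocus  # local to avoid cycles at import time

    rng = np.random.default_rng(seed)
    ledger = FeatureLedger()
    chroms: list[list[str]] = []
    packers: list[_Packer] = []
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    for _ in range(n_chrom):
        chroms.append(list(_scrubbed_random(rng, chrom_len, features.gc)))
        packers.append(_Packer(chrom_len))

    def pick_chrom() -> int:
        return int(rng.integers(0, n_chrom))

    # --- SSRs
    motifs, weights = zip(*features.ssr_motifs) if features.ssr_motifs else ((), ())
    wsum = sum(weights) if weights else 0.0
    for _ in range(features.n_ssrs):
        ci = pick_chrom()
        motif = str(motifs[int(rng.choice(len(motifs), p=[w / wsum for w in weights]))])
        k = len(motif)
        lo, hi = features.ssr_len_range
        min_total = DEFAULT_SSR_THRESHOLDS.get(k, 4 * k)
        total = int(rng.integers(max(lo, min_total), max(hi, min_total) + 1))
        start = packers[ci].place(rng, total)
        run = (motif * (total // k + 1))[:total]
        chrom = chroms[ci]
        chrom[start:start + total] = list(run)
        # flank guards: stop periodic extension into the background
        left_ref = chrom[start + k - 1]
        choices = [b for b in "ACGT" if b != left_ref]
        chrom[start - 1] = choices[int(rng.integers(0, 3))]
        right_ref = chrom[start + total - k]
        choices = [b for b in "ACGT" if b != right_ref]
        chrom[start + total] = choices[int(rng.integers(0, 3))]
        canonical, _ = canonical_motif(motif)
        ledger.ssrs.append(SsrLocus(
            seq_id=names[ci], start=start, end=start + total,
            unit_length=k, canonical_motif=canonical, copy_number=total / k,
        ))

    # --- repeat fragments
    if features.n_repeats:
        fam_labels, fam_classes, fam_paths, fam_w = zip(*features.repeat_families)
        fw = np.array(fam_w, dtype=float)
        fw /= fw.sum()
        for i in range(features.n_repeats):
            ci = pick_chrom()
            fi = int(rng.choice(len(fam_labels), p=fw))
            lo, hi = features.repeat_len_range
            size = int(rng.integers(lo, hi + 1))
            start = packers[ci].place(rng, size)
            frag = _scrubbed_random(rng, size, features.gc)
            chroms[ci][start:start + size] = list(frag)
            ledger.repeats.append(RepeatHit(
                seq_id=names[ci], start=start, end=start + size,
                family_label=fam_labels[fi] % (i + 1),
                class_path=list(fam_paths[fi]),
                declared_class=fam_classes[fi],
            ))

    # --- gene spans
    for _ in range(features.n_genes):
        ci = pick_chrom()
        lo, hi = features.gene_len_range
        size = int(rng.integers(lo, hi + 1))
        start = packers[ci].place(rng, size)
        chroms[ci][start:start + size] = list(_scrubbed_random(rng, size, features.gc))
        ledger.genes.append(GeneSpan(seq_id=names[ci], start=start, end=start + size))

    # --- restriction sites (planted motifs; ledger lists actual occurrences)
    for _ in range(features.n_restriction_sites):
        ci = pick_chrom()
        start = packers[ci].place(rng, len(RESTRICTION_MOTIF))
        chroms[ci][start:start + len(RESTRICTION_MOTIF)] = list(RESTRICTION_MOTIF)

    # final pass: rewrite any stray chance SSR created at feature junctions
    sequences: list[SequenceRecord] = []
    planted = {(L.seq_id, L.start, L.end) for L in ledger.ssrs}
    shielded: dict[str, list[tuple[int, int]]] = {}
    for h in ledger.repeats:
        shielded.setdefault(h.seq_id, []).append((h.start, h.end))
    for g in ledger.genes:
        shielded.setdefault(g.seq_id, []).append((g.start, g.end))
    for ci, name in enumerate(names):
        chrom = chroms[ci]
        for _ in range(60):
            text = "".join(chrom)
            stray = [
                (s, e) for s, e in _chance_ssr_spans(text)
                if not any(ps <= s and e <= pe for pid, ps, pe in planted if pid == name)
            ]
            if not stray:
                break
            for s, e in stray:
                for pos in range(s, e):
                    inside = any(ss <= pos < se for ss, se in shielded.get(name, ()))
                    inside = inside or any(
                        ps <= pos < pe for pid, ps, pe in planted if pid == name)
                    if not inside:
                        cur = chrom[pos]
                        alt = [b for b in "ACGT" if b != cur]
                        chrom[pos] = alt[int(rng.integers(0, 3))]
        else:
            raise RuntimeError("could not remove stray chance SSRs")
        text = "".join(chrom)
        sequences.append(SequenceRecord(id=name, sequence=text))
        sites = []
        pos = text.find(RESTRICTION_MOTIF)
        while pos != -1:
            sites.append(pos)
            pos = text.find(RESTRICTION_MOTIF, pos + 1)
        ledger.restriction_sites[name] = sites
    return GenomeModel(sequences=sequences, ledger=ledger)


def gene_records(genome: GenomeModel) -> list[SequenceRecord]:
    """Planted gene spans as sequence records (a synthetic unigene set)."""
    by_id = {s.id: s.sequence for s in genome.sequences}
    return [
        SequenceRecord(id=f"gene_{i + 1:05d}", sequence=by_id[g.seq_id][g.start:g.end])
        for i, g in enumerate(genome.ledger.genes)
    ]


# ---------------------------------------------------------------------------
# BAC library simulation

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(min(max(mean, lo), hi))


def simulate_library_detailed(
    genome: GenomeModel,
    spec: LibrarySpec,
) -> tuple[list[BesPair], list[CloneTruth]]:
    """Simulate paired end-reads of BAC clones, with insert ground truth.

    RANDOM_SHEAR draws insert starts uniformly along the genome;
    RESTRICTION draws both insert boundaries from the ledger's restriction
    sites, reproducing the coverage bias of one-enzyme libraries. The
    forward read is the first bases of the insert; the reverse read is the
    reverse complement of its last bases. Read lengths are truncated
    normal within [min, max]. The number of non-empty clones is
    round(n_clones x (1 - empty_fraction)).
    """
    rng = np.random.default_rng(spec.seed)
    lengths = np.array([len(s.sequence) for s in genome.sequences], dtype=float)
    if spec.method is LibrarySpec.Method.RESTRICTION:
        usable = [
            (s, genome.ledger.restriction_sites.get(s.id, []))
            for s in genome.sequences
        ]
        if all(len(sites) < 2 for _, sites in usable):
            raise ValueError("RESTRICTION library requires at least two restriction sites")
    n_true = int(round_half_up(spec.n_clones * (1 - spec.empty_fraction), 0))
    # sd such that ~99% of mass lies inside [min, max] on the tighter side
    read_sd = min((spec.read_len_mean - spec.read_len_min),
                  (spec.read_len_max - spec.read_len_mean)) / 3.0
    pairs: list[BesPair] = []
    truths: list[CloneTruth] = []
    insert_lo = max(2 * spec.read_len_min, spec.mean_insert - 3 * spec.insert_sd)
    insert_hi = spec.mean_insert + 3 * spec.insert_sd
    for i in range(n_true):
        for _attempt in range(200):
            ci = int(rng.choice(len(lengths), p=lengths / lengths.sum()))
            chrom = genome.sequences[ci]
            L = len(chrom.sequence)
            insert_len = int(_truncated_normal(rng, spec.mean_insert, spec.insert_sd,
                                               insert_lo, min(insert_hi, L)))
            if insert_len > L:
                continue
            if spec.method is LibrarySpec.Method.RANDOM_SHEAR:
                start = int(rng.integers(0, L - insert_len + 1))
                end = start + insert_len
            else:
                sites = genome.ledger.restriction_sites.get(chrom.id, [])
                if len(sites) < 2:
                    continue
                si = int(rng.integers(0, len(sites)))
                start = sites[si]
                target_end = start + insert_len
                later = [s for s in sites if s > start]
                if not later:
                    continue
                end = min(later, key=lambda s: abs(s - target_end))
                if end - start < 2 * spec.read_len_min or end > L:
                    continue
            break
        else:
            raise ValueError("could not draw a feasible insert; genome too small?")
        insert = chrom.sequence[start:end]
        l1 = int(round(_truncated_normal(rng, spec.read_len_mean, read_sd,
                                         spec.read_len_min, min(spec.read_len_max, len(insert)))))
        l2 = int(round(_truncated_normal(rng, spec.read_len_mean, read_sd,
                                         spec.read_len_min, min(spec.read_len_max, len(insert)))))
        clone_id = f"{spec.clone_prefix}{i + 1:06d}"
        fwd = BesRead(
            record=SequenceRecord(id=f"{clone_id}.f", sequence=insert[:l1]),
            library=spec.library, clone_id=clone_id, end=End.FORWARD,
        )
        rev = BesRead(
            record=SequenceRecord(id=f"{clone_id}.r", sequence=revcomp(insert[-l2:])),
            library=spec.library, clone_id=clone_id, end=End.REVERSE,
        )
        pairs.append(BesPair(clone_id=clone_id, forward=fwd, reverse=rev))
        truths.append(CloneTruth(clone_id=clone_id, chrom=chrom.id,
                                 insert_start=start, insert_end=end))
    return pairs, truths


def simulate_library(genome: GenomeModel, spec: LibrarySpec) -> list[BesPair]:
    """As :func:`simulate_library_detailed`, without the truth ledger."""
    return simulate_library_detailed(genome, spec)[0]


# ---------------------------------------------------------------------------
# related genome with collinear blocks

def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    for pos in np.nonzero(hit)[0]:
        cur = chr(arr[pos])
        alt = [b for b in "ACGT" if b != cur]
        arr[pos] = ord(alt[int(rng.integers(0, 3))])
    return arr.tobytes().decode()


def simulate_related_genome(
    genome: GenomeModel,
    spec: SyntenySpec,
) -> tuple[GenomeModel, list[BlockPlacement]]:
    """Build a target genome sharing collinear blocks with the source.

    Non-overlapping source blocks are drawn, then each is copied
    `duplication_multiplicity` times into the target, each copy possibly
    inverted wholesale (probability `inversion_prob`) and diverged by
    per-base substitutions. Copies of one block land on distinct target
    chromosomes whenever the multiplicity allows, separated from their
    neighbours by random spacers. Every placement is ledgered.
    """
    rng = np.random.default_rng(spec.seed)
    # draw source blocks, non-overlapping; sizes first, then stick-breaking
    # placement per chromosome so dense requests never fragment-fail
    by_id = {s.id: s.sequence for s in genome.sequences}
    names = [s.id for s in genome.sequences]
    lengths = {s.id: len(s.sequence) for s in genome.sequences}
    lo, hi = spec.block_len
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_blocks)]
    assigned: dict[str, list[int]] = {n: [] for n in names}
    remaining = dict(lengths)
    for bi, size in enumerate(sizes):
        feasible = [n for n in names if remaining[n] >= size]
        if not feasible:
            raise ValueError("infeasible block packing: blocks exceed source genome")
        weights = np.array([remaining[n] for n in feasible], dtype=float)
        pick = feasible[int(rng.choice(len(feasible), p=weights / weights.sum()))]
        assigned[pick].append(bi)
        remaining[pick] -= size
    blocks: list[tuple[str, int, int] | None] = [None] * spec.n_blocks
    for name in names:
        idxs = list(assigned[name])
        if not idxs:
            continue
        rng.shuffle(idxs)
        slack = lengths[name] - sum(sizes[i] for i in idxs)
        cuts = np.sort(rng.uniform(0, slack, size=len(idxs)))
        pos = 0.0
        prev_cut = 0.0
        for order, bi in enumerate(idxs):
            pos += cuts[order] - prev_cut
            prev_cut = cuts[order]
            start = int(pos)
            blocks[bi] = (name, start, start + sizes[bi])
            pos += sizes[bi]
    blocks = [b for b in blocks if b is not None]
    # assign copies to target chromosomes
    per_target: dict[int, list[tuple[int, str, BlockOrientation]]] = {
        t: [] for t in range(spec.n_target_chrom)}
    placements_meta: list[list[int]] = []
    for bi, (chrom, s, e) in enumerate(blocks):
        if isinstance(spec.duplication_multiplicity, int):
            m = spec.duplication_multiplicity
        else:
            m = int(rng.choice(list(spec.duplication_multiplicity)))
        perm = list(rng.permutation(spec.n_target_chrom))
        for copy_idx in range(m):
            seq = by_id[chrom][s:e]
            orient = (BlockOrientation.INVERTED
                      if rng.random() < spec.inversion_prob else BlockOrientation.SAME)
            if orient is BlockOrientation.INVERTED:
                seq = revcomp(seq)
            seq = _mutate(rng, seq, spec.divergence)
            per_target[perm[copy_idx % spec.n_target_chrom]].append((bi, seq, orient))
    # lay out each target chromosome: spacer, block, spacer, block, ...
    target_seqs: list[SequenceRecord] = []
    ledger: list[BlockPlacement] = []
    copy_counters: dict[int, int] = {}
    for t in range(spec.n_target_chrom):
        entries = per_target[t]
        order = list(rng.permutation(len(entries)))
        parts: list[str] = []
        pos = 0
        tname = f"target_chr{t + 1}"
        for oi in order:
            bi, seq, orient = entries[oi]
            spacer = _random_bases(rng, spec.spacer_len, DEFAULT_GC)
            parts.append(spacer)
            pos += len(spacer)
            chrom, s, e = blocks[bi]
            copy_idx = copy_counters.get(bi, 0)
            copy_counters[bi] = copy_idx + 1
            ledger.append(BlockPlacement(
                source_chrom=chrom, source_start=s, source_end=e,
                target_chrom=tname, target_start=pos, target_end=pos + len(seq),
                orientation=orient, copy_index=copy_idx,
            ))
            parts.append(seq)
            pos += len(seq)
        parts.append(_random_bases(rng, spec.spacer_len, DEFAULT_GC))
        target_seqs.append(SequenceRecord(id=tname, sequence="".join(parts)))
    target = GenomeModel(sequences=target_seqs, ledger=FeatureLedger())
    return target, ledger
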