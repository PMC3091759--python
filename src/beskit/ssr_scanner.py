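"""Perfect microsatellite (SSR) detection and motif canonicalization.

An SSR here is a maximal perfect tandem run of a primitive 1-6 nt unit.
Default reporting thresholds are the standard survey settings: mono- to
trinucleotide runs of total length >= 12 nt, and tetra- to hexanucleotide
runs of at least four full unit copies. Motifs are collapsed into
strand/rotation classes (e.g. TTC, GAA and CTT all belong to class
AAG/CTT): the canonical motif is the lexicographic minimum over all
rotations of the unit and of its reverse complement, which makes every
summary invariant under reverse-complementing the input.

A run may end mid-unit ("at least 12 nt in length" is a length criterion,
not a whole-copy criterion), so copy number is real-valued. Nested runs
are suppressed: a candidate wholly inside an already-reported locus is not
reported separately; priority is longest span, then smallest unit, then
leftmost start.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from beskit._util import revcomp, round_half_up
from beskit.io_formats import SequenceRecord

__all__ = [
    "SsrLocus", "SsrSummary", "DEFAULT_SSR_THRESHOLDS", "LENGTH_BINS",
    "canonical_motif", "motif_class_label", "find_ssrs", "summarize_ssrs",
]

#: minimum total run length (nt) per unit length
DEFAULT_SSR_THRESHOLDS: dict[int, int] = {1: 12, 2: 12, 3: 12, 4: 16, 5: 20, 6: 24}

#: reporting bins for total SSR length, lower bound inclusive
LENGTH_BINS: tuple[tuple[int, float], ...] = (
    (12, 20), (21, 50), (51, 100), (101, float("inf")),
)

#: class I microsatellites are longer than this many nt
CLASS_I_MIN_EXCLUSIVE = 20


@dataclass(frozen=True)
class SsrLocus:
    seq_id: str
    start: int
    end: int
    unit_length: int
    canonical_motif: str
    copy_number: float

    @property
    def total_length(self) -> int:
        return self.end - self.start


@dataclass
class SsrSummary:
    n_loci: int
    counts_by_motif: dict[str, int]
    counts_by_unit: dict[int, int]
    length_bin_counts: dict[str, int]
    class_i_count: int
    total_ssr_bp: int
    density_kb: float | None  # kb of sequence per SSR; None when no loci
    total_sequence_bp: int = 0
    extras: dict = field(default_factory=dict)


def _is_primitive(motif: str) -> bool:
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


def canonical_motif(motif: str) -> tuple[str, str]:
    """Canonicalize a primitive repeat unit.

    Returns ``(canonical, class_label)`` where canonical is the
    lexicographic minimum over all rotations of the motif and all rotations
    of its reverse complement, and the class label is the conventional
    two-sided form (e.g. ``"AAG/CTT"``, or just ``"AT"`` when both strands
    canonicalize identically).
    """
    motif = motif.upper()
    if not motif or not set(motif) <= set("ACGT"):
        raise ValueError(f"motif {motif!r} must be a non-empty string over ACGT")
    if len(motif) > 6:
        raise ValueError(f"motif {motif!r} longer than 6 nt")
    if not _is_primitive(motif):
        raise ValueError(
            f"motif {motif!r} is not primitive; reduce it to its shortest repeated unit"
        )
    rots = {motif[i:] + motif[:i] for i in range(len(motif))}
    rc = revcomp(motif)
    rc_rots = {rc[i:] + rc[:i] for i in range(len(rc))}
    canonical = min(rots | rc_rots)
    # label shows the minimum rotation on each strand of the canonical unit
    rc_min = min(revcomp(canonical)[i:] + revcomp(canonical)[:i] for i in range(len(canonical)))
    label = canonical if rc_min == canonical else f"{canonical}/{rc_min}"
    return canonical, label


def motif_class_label(motif: str) -> str:
    """Convenience: just the strand/rotation class label for a unit."""
    return canonical_motif(motif)[1]


def _maximal_runs(seq: str, k: int) -> list[tuple[int, int]]:
    """Maximal tandem runs of period k with a primitive unit.

    Returns (start, end) half-open intervals of total length >= k + 1 bases
    beyond a single unit is not required here; thresholding happens later.
    N (or any ambiguity code) never matches, so runs break at Ns.
    """
    n = len(seq)
    runs: list[tuple[int, int]] = []
    if n < 2 * k:
        # a tandem needs at least one period of self-overlap; still allow
        # partial second units below via the match array
        pass
    i = 0
    limit = n - k
    while i < limit:
        if seq[i] == seq[i + k] and seq[i] in "ACGT":
            j = i
            while j < limit and seq[j] in "ACGT" and seq[j] == seq[j + k]:
                j += 1
            start, end = i, j + k  # run covers [i, j-1] matches plus one period
            unit = seq[start:start + k]
            if _is_primitive(unit) and "N" not in unit:
                runs.append((start, end))
            i = j + 1
        else:
            i += 1
    return runs


def find_ssrs(
    seq: SequenceRecord,
    thresholds: Mapping[int, int] = DEFAULT_SSR_THRESHOLDS,
) -> list[SsrLocus]:
    """Scan one sequence for maximal perfect SSRs meeting the thresholds.

    `thresholds` maps unit length to the minimum total run length in nt.
    Output is sorted by (start, unit_length); no reported locus lies wholly
    inside another reported locus.
    """
    s = seq.sequence.upper()
    candidates: list[SsrLocus] = []
    for k, min_total in thresholds.items():
        for start, end in _maximal_runs(s, k):
            if end - start < min_total:
                continue
            canonical, _ = canonical_motif(s[start:start + k])
            candidates.append(SsrLocus(
                seq_id=seq.id, start=start, end=end, unit_length=k,
                canonical_motif=canonical,
                copy_number=(end - start) / k,
            ))
    # nested-run suppression: longest span first, then smallest unit, then leftmost
    candidates.sort(key=lambda L: (-(L.end - L.start), L.unit_length, L.start))
    accepted: list[SsrLocus] = []
    for cand in candidates:
        if any(a.start <= cand.start and cand.end <= a.end for a in accepted):
            continue
        accepted.append(cand)
    accepted.sort(key=lambda L: (L.start, L.unit_length))
    return accepted


def scan_many(
    records: Sequence[SequenceRecord],
    thresholds: Mapping[int, int] = DEFAULT_SSR_THRESHOLDS,
) -> list[SsrLocus]:
    out: list[SsrLocus] = []
    for rec in records:
        out.extend(find_ssrs(rec, thresholds))
    return out


def summarize_ssrs(loci: Sequence[SsrLocus], total_sequence_bp: int) -> SsrSummary:
    """Aggregate loci into the survey summary.

    Density is kb of scanned sequence per SSR (one microsatellite every
    `density_kb` kb), rounded half-up to one decimal; it is None for an
    empty locus list. Class I microsatellites are those longer than 20 nt.
    """
    if total_sequence_bp <= 0:
        raise ValueError("total_sequence_bp must be positive")
    by_motif = Counter(L.canonical_motif for L in loci)
    by_unit = Counter(L.unit_length for L in loci)
    bins: dict[str, int] = {}
    for lo, hi in LENGTH_BINS:
        label = f"{lo}-{int(hi)}" if hi != float("inf") else f">{lo - 1}"
        bins[label] = sum(1 for L in loci if lo <= L.total_length <= hi)
    class_i = sum(1 for L in loci if L.total_length > CLASS_I_MIN_EXCLUSIVE)
    total_bp = sum(L.total_length for L in loci)
    density = round_half_up(total_sequence_bp / len(loci) / 1000.0, 1) if loci else None
    return SsrSummary(
        n_loci=len(loci),
        counts_by_motif=dict(sorted(by_motif.items())),
        counts_by_unit=dict(sorted(by_unit.items())),
        length_bin_counts=bins,
        class_i_count=class_i,
        total_ssr_bp=total_bp,
        density_kb=density,
        total_sequence_bp=total_sequence_bp,
    )
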