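"""Greedy overlap clustering of BES into contigs and singletons.

End-sequence surveys must collapse redundant reads before estimating
genome properties, otherwise heavily sampled regions (e.g. around
over-used restriction sites) bias every downstream density. The
clustering here is deliberately strict and deterministic: a read joins a
cluster only if a semi-global (dovetail or containment) alignment against
the cluster's current consensus reaches the minimum overlap length and
minimum percent identity (defaults 80 bp and 95%), considering both
orientations. Reads are processed by descending length (ties by id), each
joining the first cluster that accepts it; identity is computed over the
aligned overlap columns with gaps counted as mismatches.

Consensus is maintained as a gap-free layout of members: each member is
placed at an integer offset in the cluster frame from its accepted
alignment, and each consensus column is the majority base over members
covering it, ties resolved by the longest member (then smallest id). This
is exact for substitution-dominated overlaps, which is the regime the
identity threshold admits.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from Bio import Align

from beskit._util import revcomp
from beskit.io_formats import SequenceRecord

__all__ = [
    "Orientation", "OverlapResult", "AssemblyResult", "RedundancyReport",
    "overlap_align", "greedy_assemble", "cross_assemble",
]

DEFAULT_MIN_OVERLAP = 80
DEFAULT_MIN_IDENTITY = 95.0

SINGLETON = "SINGLETON"


class Orientation(str, Enum):
    SAME = "SAME"
    REVCOMP = "REVCOMP"


@dataclass(frozen=True)
class OverlapResult:
    accepted: bool
    overlap_length: int
    identity: float
    relative_orientation: Orientation
    offset: int  # start of b in a's coordinate frame (may be negative)


@dataclass
class AssemblyResult:
    contigs: list[tuple[SequenceRecord, list[str]]]
    singletons: list[SequenceRecord]
    membership: dict[str, str]

    @property
    def sequences(self) -> list[SequenceRecord]:
        """Contig consensus records followed by singleton records."""
        return [c for c, _ in self.contigs] + list(self.singletons)

    @property
    def n_placed(self) -> int:
        return len(self.membership)


@dataclass(frozen=True)
class RedundancyReport:
    input_sequences: int
    output_sequences: int
    input_bp: int
    output_bp: int

    @property
    def sequences_removed(self) -> int:
        return self.input_sequences - self.output_sequences

    @property
    def bp_removed(self) -> int:
        return self.input_bp - self.output_bp


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -2
    # free end gaps -> overlap (dovetail/containment) alignment
    try:
        aligner.open_end_insertion_score = 0
        aligner.extend_end_insertion_score = 0
        aligner.open_end_deletion_score = 0
        aligner.extend_end_deletion_score = 0
    except AttributeError:  # older attribute names
        aligner.target_end_open_gap_score = 0
        aligner.target_end_extend_gap_score = 0
        aligner.query_end_open_gap_score = 0
        aligner.query_end_extend_gap_score = 0
    return aligner


_ALIGNER = _make_aligner()


def _overlap_stats(a: str, b: str) -> tuple[int, float, int]:
    """Best overlap alignment of b against a (given orientation).

    Returns (overlap_columns, identity_percent, offset). Overlap columns
    are the alignment columns between the first and last column where both
    sequences are present; internal gaps count as mismatches.
    """
    alignments = _ALIGNER.align(a, b)
    aln = alignments[0]
    ta, tb = str(aln[0]), str(aln[1])  # aligned strings with '-'
    fa, la = _first_base(ta), _last_base(ta)
    fb, lb = _first_base(tb), _last_base(tb)
    first, last = max(fa, fb), min(la, lb)
    if last < first:
        return 0, 0.0, 0
    cols = last - first + 1
    matches = sum(1 for i in range(first, last + 1) if ta[i] == tb[i] and ta[i] != "-")
    identity = 100.0 * matches / cols
    # offset of b's start in a's frame (negative when b hangs off a's left end)
    offset = sum(1 for c in ta[:fb] if c != "-") - sum(1 for c in tb[:fa] if c != "-")
    return cols, identity, offset


def _first_base(aligned: str) -> int:
    for i, c in enumerate(aligned):
        if c != "-":
            return i
    return len(aligned)


def _last_base(aligned: str) -> int:
    for i in range(len(aligned) - 1, -1, -1):
        if aligned[i] != "-":
            return i
    return -1


def overlap_align(
    a: SequenceRecord,
    b: SequenceRecord,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> OverlapResult:
    """Best dovetail/containment overlap between two sequences.

    Both orientations of `b` are tried; the result is accepted only if the
    overlap spans at least `min_overlap` columns at `min_identity` percent
    identity or better.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("overlap_align requires non-empty sequences")
    best: OverlapResult | None = None
    for orient, bseq in ((Orientation.SAME, b.sequence), (Orientation.REVCOMP, revcomp(b.sequence))):
        cols, ident, offset = _overlap_stats(a.sequence, bseq)
        accepted = cols >= min_overlap and ident >= min_identity
        res = OverlapResult(
            accepted=accepted, overlap_length=cols, identity=round(ident, 2),
            relative_orientation=orient, offset=offset,
        )
        if best is None or (res.accepted, res.overlap_length * res.identity) > (
            best.accepted, best.overlap_length * best.identity
        ):
            best = res
    assert best is not None
    return best


class _Cluster:
    __slots__ = ("members", "consensus")

    def __init__(self, rec: SequenceRecord):
        # members: (id, oriented sequence, offset in cluster frame)
        self.members: list[tuple[str, str, int]] = [(rec.id, rec.sequence, 0)]
        self.consensus: str = rec.sequence

    def try_add(self, rec: SequenceRecord, min_overlap: int, min_identity: float) -> bool:
        cons = SequenceRecord(id="__consensus__", sequence=self.consensus)
        res = overlap_align(cons, rec, min_overlap, min_identity)
        if not res.accepted:
            return False
        seq = rec.sequence if res.relative_orientation is Orientation.SAME else revcomp(rec.sequence)
        offset = res.offset
        if offset < 0:
            self.members = [(i, s, o - offset) for i, s, o in self.members]
            offset = 0
        self.members.append((rec.id, seq, offset))
        self._rebuild_consensus()
        return True

    def absorb(self, other: "_Cluster", min_overlap: int, min_identity: float) -> bool:
        """Merge another cluster in if the two consensus sequences overlap."""
        cons = SequenceRecord(id="__consensus__", sequence=self.consensus)
        res = overlap_align(cons, SequenceRecord(id="__other__", sequence=other.consensus),
                            min_overlap, min_identity)
        if not res.accepted:
            return False
        other_len = len(other.consensus)
        for rid, seq, off in other.members:
            if res.relative_orientation is Orientation.SAME:
                self.members.append((rid, seq, res.offset + off))
            else:
                flipped_off = other_len - (off + len(seq))
                self.members.append((rid, revcomp(seq), res.offset + flipped_off))
        shift = min(o for _, _, o in self.members)
        if shift < 0:
            self.members = [(i, s, o - shift) for i, s, o in self.members]
        self._rebuild_consensus()
        return True

    def _rebuild_consensus(self) -> None:
        length = max(o + len(s) for _, s, o in self.members)
        # majority per column; tie -> base of longest member (then smallest id)
        ranked = sorted(self.members, key=lambda m: (-len(m[1]), m[0]))
        cols: list[str] = []
        for pos in range(length):
            votes: dict[str, int] = {}
            tiebreak: dict[str, int] = {}
            for rank, (_, s, o) in enumerate(ranked):
                if o <= pos < o + len(s):
                    base = s[pos - o]
                    votes[base] = votes.get(base, 0) + 1
                    if base not in tiebreak:
                        tiebreak[base] = rank
            best = min(votes, key=lambda b: (-votes[b], tiebreak[b]))
            cols.append(best)
        self.consensus = "".join(cols)


def greedy_assemble(
    seqs: Sequence[SequenceRecord],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> AssemblyResult:
    """Cluster sequences greedily by overlap against cluster consensus.

    Deterministic: reads are processed by (descending length, id); each
    joins the first accepting cluster in creation order, else founds a new
    cluster. Clusters with one member are singletons.
    """
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in assembly input")
    ordered = sorted(seqs, key=lambda r: (-len(r.sequence), r.id))
    clusters: list[_Cluster] = []
    for rec in ordered:
        for cluster in clusters:
            if cluster.try_add(rec, min_overlap, min_identity):
                break
        else:
            clusters.append(_Cluster(rec))
    # consensus growth can reveal overlaps between clusters founded early;
    # merge clusters until a fixed point so membership equals the
    # connected components of the overlap graph on clean data
    merged = True
    while merged:
        merged = False
        i = 0
        while i < len(clusters):
            j = i + 1
            while j < len(clusters):
                if clusters[i].absorb(clusters[j], min_overlap, min_identity):
                    del clusters[j]
                    merged = True
                else:
                    j += 1
            i += 1
    contigs: list[tuple[SequenceRecord, list[str]]] = []
    singletons: list[SequenceRecord] = []
    membership: dict[str, str] = {}
    by_id = {s.id: s for s in seqs}
    n_contig = 0
    for cluster in clusters:
        if len(cluster.members) == 1:
            rid = cluster.members[0][0]
            singletons.append(by_id[rid])
            membership[rid] = SINGLETON
        else:
            n_contig += 1
            cid = f"contig_{n_contig:05d}"
            member_ids = [m[0] for m in cluster.members]
            contigs.append((SequenceRecord(id=cid, sequence=cluster.consensus), member_ids))
            for rid in member_ids:
                membership[rid] = cid
    return AssemblyResult(contigs=contigs, singletons=singletons, membership=membership)


def cross_assemble(
    asm1: AssemblyResult,
    asm2: AssemblyResult,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    prefixes: tuple[str, str] = ("A", "B"),
) -> tuple[AssemblyResult, RedundancyReport]:
    """Jointly cluster the outputs of two assemblies.

    Inputs are each assembly's contig consensus sequences and singletons,
    treated as plain sequences (ids prefixed to keep the id spaces
    disjoint; a collision after prefixing is an error). The redundancy
    report gives the sequence-count and bp reduction achieved by the
    cross-assembly.
    """
    inputs: list[SequenceRecord] = []
    for prefix, asm in zip(prefixes, (asm1, asm2)):
        for rec in asm.sequences:
            inputs.append(SequenceRecord(id=f"{prefix}:{rec.id}", sequence=rec.sequence,
                                         description=rec.description))
    ids = [r.id for r in inputs]
    if len(set(ids)) != len(ids):
        raise ValueError("id collision between cross-assembly inputs")
    result = greedy_assemble(inputs, min_overlap, min_identity)
    report = RedundancyReport(
        input_sequences=len(inputs),
        output_sequences=len(result.sequences),
        input_bp=sum(len(r.sequence) for r in inputs),
        output_bp=sum(len(r.sequence) for r in result.sequences),
    )
    return result, report
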