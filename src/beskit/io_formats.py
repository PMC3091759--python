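"""Readers/writers for the survey's file formats and BES pairing.

One coordinate convention holds throughout the package: 0-based, half-open
intervals, with strand stored as an explicit field. File boundaries (BLAST
tabular, RepeatMasker-style annotation tables) use 1-based inclusive
coordinates and encode minus-strand subject hits by swapped coordinates;
conversion happens here and only here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord", "BesRead", "BesPair", "HitRecord", "RepeatHit",
    "Library", "End", "Strand", "EndSuffixScheme", "DEFAULT_SUFFIX_SCHEME",
    "read_fasta", "write_fasta", "filter_bes", "parse_bes_reads",
    "pair_bes", "read_hits_tabular", "read_repeat_annotations",
]

_IUPAC = frozenset("ACGTRYSWKMBDHVN")


class Library(str, Enum):
    """BAC library of origin: restriction-digest (BCM-like), random-shear
    (RCM-like), or anything else."""

    BCM = "BCM"
    RCM = "RCM"
    OTHER = "OTHER"


class End(str, Enum):
    FORWARD = "FORWARD"
    REVERSE = "REVERSE"


class Strand(str, Enum):
    PLUS = "PLUS"
    MINUS = "MINUS"


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BesRead:
    """One BAC-end sequence: a read from one end of a clone insert."""

    record: SequenceRecord
    library: Library
    clone_id: str
    end: End


@dataclass(frozen=True)
class BesPair:
    """The two mated end-reads of a single BAC clone."""

    clone_id: str
    forward: BesRead
    reverse: BesRead

    def __post_init__(self) -> None:
        if self.forward.clone_id != self.clone_id or self.reverse.clone_id != self.clone_id:
            raise ValueError(f"pair {self.clone_id}: member clone ids disagree")
        if self.forward.library != self.reverse.library:
            raise ValueError(f"pair {self.clone_id}: ends from different libraries")


@dataclass(frozen=True)
class HitRecord:
    """One homology hit, BLAST-tabular style, in internal coordinates."""

    query_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    subject_strand: Strand
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not self.q_start < self.q_end:
            raise ValueError(f"hit {self.query_id}: q_start must be < q_end")
        if not self.s_start < self.s_end:
            raise ValueError(f"hit {self.query_id}: s_start must be < s_end")
        if self.e_value < 0:
            raise ValueError(f"hit {self.query_id}: negative E-value")


@dataclass
class RepeatHit:
    """One repeat annotation; `class_path` is resolved by the taxonomy later."""

    seq_id: str
    start: int
    end: int
    family_label: str
    class_path: list[str] = field(default_factory=list)
    declared_class: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"repeat on {self.seq_id}: start must be < end")


@dataclass(frozen=True)
class EndSuffixScheme:
    """How a read id encodes clone and end (never stated by sequencing
    centres consistently, so configurable). Suffixes are matched
    case-sensitively at the end of the id; the clone id is what precedes."""

    forward: tuple[str, ...] = (".f", "_F", ".F", "_f")
    reverse: tuple[str, ...] = (".r", "_R", ".R", "_r")

    def parse(self, read_id: str) -> tuple[str, End] | None:
        for suf in self.forward:
            if read_id.endswith(suf):
                return read_id[: -len(suf)], End.FORWARD
        for suf in self.reverse:
            if read_id.endswith(suf):
                return read_id[: -len(suf)], End.REVERSE
        return None


DEFAULT_SUFFIX_SCHEME = EndSuffixScheme()


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into upper-cased records.

    Raises on a missing file, a duplicate id, or any non-IUPAC character
    (reported with its record and 1-based position).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        for i, base in enumerate(seq):
            if base not in _IUPAC:
                raise ValueError(
                    f"non-IUPAC character {base!r} at position {i + 1} "
                    f"of record {rec.id!r} in {path}"
                )
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        out.append(SequenceRecord(id=rec.id, sequence=seq, description=desc))
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA wrapped at `width` columns."""
    bio = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def filter_bes(records: Sequence[SequenceRecord], min_len: int) -> list[SequenceRecord]:
    """Drop reads shorter than `min_len` bp (surveys discard sub-50 bp
    reads as uninformative); order is preserved."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [r for r in records if len(r.sequence) >= min_len]


# ---------------------------------------------------------------------------
# BES pairing

def parse_bes_reads(
    records: Sequence[SequenceRecord],
    library: Library = Library.OTHER,
    scheme: EndSuffixScheme = DEFAULT_SUFFIX_SCHEME,
) -> list[BesRead]:
    """Interpret records as BES reads, parsing clone and end from the id.

    Ids that match no suffix are treated as unmated forward reads with the
    whole id as clone id.
    """
    reads = []
    for rec in records:
        parsed = scheme.parse(rec.id)
        if parsed is None:
            clone, end = rec.id, End.FORWARD
        else:
            clone, end = parsed
        reads.append(BesRead(record=rec, library=library, clone_id=clone, end=end))
    return reads


def pair_bes(reads: Sequence[BesRead]) -> tuple[list[BesPair], list[BesRead]]:
    """Mate reads into clone pairs.

    Every read lands in exactly one bucket, so 2·|pairs| + |unpaired| equals
    the input count. Two reads claiming the same (library, clone, end) is an
    error naming the clone.
    """
    by_clone: dict[tuple[Library, str], dict[End, BesRead]] = {}
    order: list[tuple[Library, str]] = []
    for read in reads:
        key = (read.library, read.clone_id)
        ends = by_clone.setdefault(key, {})
        if not ends:
            order.append(key)
        if read.end in ends:
            raise ValueError(
                f"duplicate {read.end.value} read for clone {read.clone_id!r} "
                f"in library {read.library.value}"
            )
        ends[read.end] = read
    pairs: list[BesPair] = []
    unpaired: list[BesRead] = []
    for key in order:
        ends = by_clone[key]
        if End.FORWARD in ends and End.REVERSE in ends:
            pairs.append(BesPair(clone_id=key[1], forward=ends[End.FORWARD], reverse=ends[End.REVERSE]))
        else:
            unpaired.extend(ends.values())
    return pairs, unpaired


# ---------------------------------------------------------------------------
# Tabular homology hits (12-column BLAST outfmt-6 dialect)

def read_hits_tabular(path: str | Path, max_e: float = float("inf")) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit table.

    Columns: query, subject, %identity, alignment length, mismatches, gap
    opens, qstart, qend, sstart, send, evalue, bitscore — coordinates
    1-based inclusive, with a minus-strand subject encoded as sstart > send.
    Hits with E-value above `max_e` are dropped. Internally everything is
    0-based half-open with an explicit strand field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            try:
                (query, subject, pid, alen, _mm, _go,
                 qs, qe, ss, se, ev, bits) = fields
                pid_f, alen_i = float(pid), int(alen)
                qs_i, qe_i, ss_i, se_i = int(qs), int(qe), int(ss), int(se)
                ev_f, bits_f = float(ev), float(bits)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed field ({exc})") from None
            if ev_f > max_e:
                continue
            if ss_i <= se_i:
                strand, s0, s1 = Strand.PLUS, ss_i - 1, se_i
            else:
                strand, s0, s1 = Strand.MINUS, se_i - 1, ss_i
            hits.append(HitRecord(
                query_id=query, subject_id=subject, percent_identity=pid_f,
                aln_length=alen_i, q_start=qs_i - 1, q_end=qe_i,
                s_start=s0, s_end=s1, subject_strand=strand,
                e_value=ev_f, bit_score=bits_f,
            ))
    return hits


def write_hits_tabular(hits: Iterable[HitRecord], path: str | Path) -> None:
    """Inverse of :func:`read_hits_tabular` (mismatch/gap columns written as 0)."""
    with open(path, "w") as fh:
        for h in hits:
            if h.subject_strand is Strand.PLUS:
                ss, se = h.s_start + 1, h.s_end
            else:
                ss, se = h.s_end, h.s_start + 1
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_id, h.percent_identity, h.aln_length,
                0, 0, h.q_start + 1, h.q_end, ss, se,
                f"{h.e_value:.2g}", h.bit_score,
            ])) + "\n")


# ---------------------------------------------------------------------------
# Repeat annotation tables (RepeatMasker .out dialect)

_RM_HEADER = re.compile(r"^\s*(SW|score|$)")


def read_repeat_annotations(
    path: str | Path,
    seq_lengths: dict[str, int] | None = None,
) -> list[RepeatHit]:
    """Parse a whitespace-delimited repeat-annotation table.

    Expected columns follow the RepeatMasker .out layout: score, div, del,
    ins, query id, begin, end, (left), strand, repeat family, repeat
    class/family, ... Spans are 1-based inclusive in the file. Overlapping
    annotations are both kept; nothing is merged at parse time. If
    `seq_lengths` is given, a span beyond the sequence end is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    hits: list[RepeatHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if _RM_HEADER.match(raw):
                continue
            fields = raw.split()
            if len(fields) < 11:
                raise ValueError(f"{path}:{lineno}: expected >=11 whitespace-delimited columns")
            seq_id = fields[4]
            try:
                begin, end = int(fields[5]), int(fields[6])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer span") from None
            family, declared = fields[9], fields[10]
            start0, end0 = begin - 1, end
            if seq_lengths is not None and seq_id in seq_lengths and end0 > seq_lengths[seq_id]:
                raise ValueError(
                    f"{path}:{lineno}: span [{begin},{end}] exceeds length "
                    f"{seq_lengths[seq_id]} of {seq_id!r}"
                )
            hits.append(RepeatHit(
                seq_id=seq_id, start=start0, end=end0,
                family_label=family, declared_class=declared,
            ))
    return hits


def write_repeat_annotations(hits: Iterable[RepeatHit], path: str | Path) -> None:
    """Write hits back in the annotation dialect (scores/divergences zeroed)."""
    with open(path, "w") as fh:
        fh.write("   SW  perc perc perc  query     begin  end  (left) strand repeat  class/family  begin end (left) ID\n\n")
        for i, h in enumerate(hits, start=1):
            fh.write(
                f"  100   0.0  0.0  0.0  {h.seq_id}  {h.start + 1}  {h.end}  (0)  +  "
                f"{h.family_label}  {h.declared_class or 'Unknown'}  1  {h.end - h.start}  (0)  {i}\n"
            )
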