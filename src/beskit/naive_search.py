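"""Gap-free seed-and-extend homology matcher for synthetic end-to-end tests.

Real surveys use an external search tool and consume its tabular output;
this matcher exists so that fully synthetic pipelines (simulated reads
against simulated subject genomes, substitution-only divergence) can be
run end to end without external binaries. It indexes exact k-mer seeds of
the subject, extends each seed gap-free over the full query length, and
reports hits passing an identity floor, with a crude bit score
(+2/match, -3/mismatch) and the Karlin-Altschul-shaped E-value
``m·n·2^-bits`` — adequate for thresholding synthetic data, not a BLAST
replacement.
"""

from __future__ import annotations

from typing import Sequence

from beskit._util import revcomp
from beskit.io_formats import HitRecord, SequenceRecord, Strand

__all__ = ["SubjectIndex", "search"]

DEFAULT_SEED = 24


class SubjectIndex:
    """Exact k-mer index over a set of subject sequences."""

    def __init__(self, subjects: Sequence[SequenceRecord], seed_length: int = DEFAULT_SEED):
        self.seed_length = seed_length
        self.subjects = list(subjects)
        self.total_bp = sum(len(s.sequence) for s in subjects)
        self._index: dict[str, list[tuple[int, int]]] = {}
        for si, rec in enumerate(self.subjects):
            seq = rec.sequence
            for pos in range(0, len(seq) - seed_length + 1):
                kmer = seq[pos:pos + seed_length]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((si, pos))

    def lookup(self, kmer: str) -> list[tuple[int, int]]:
        return self._index.get(kmer, [])


def _extend(query: str, subject: str, q_seed: int, s_seed: int) -> tuple[int, int, int] | None:
    """Place the full query gap-free at the seed's implied offset.

    Returns (s_start, s_end, mismatches) or None if the query does not fit
    inside the subject at that offset.
    """
    s_start = s_seed - q_seed
    s_end = s_start + len(query)
    if s_start < 0 or s_end > len(subject):
        return None
    window = subject[s_start:s_end]
    mism = sum(1 for a, b in zip(query, window) if a != b)
    return s_start, s_end, mism


def search(
    query: SequenceRecord,
    index: SubjectIndex,
    min_identity: float = 90.0,
    seed_stride: int | None = None,
) -> list[HitRecord]:
    """Find gap-free full-length placements of the query (both strands)."""
    k = index.seed_length
    stride = seed_stride if seed_stride is not None else k
    hits: list[HitRecord] = []
    seen: set[tuple[int, int, Strand]] = set()
    for strand, qseq in ((Strand.PLUS, query.sequence), (Strand.MINUS, revcomp(query.sequence))):
        if len(qseq) < k:
            continue
        starts = list(range(0, len(qseq) - k + 1, stride))
        if starts[-1] != len(qseq) - k:
            starts.append(len(qseq) - k)
        for q_pos in starts:
            kmer = qseq[q_pos:q_pos + k]
            for si, s_pos in index.lookup(kmer):
                subject = index.subjects[si]
                placed = _extend(qseq, subject.sequence, q_pos, s_pos)
                if placed is None:
                    continue
                s_start, s_end, mism = placed
                key = (si, s_start, strand)
                if key in seen:
                    continue
                seen.add(key)
                n = len(qseq)
                identity = 100.0 * (n - mism) / n
                if identity < min_identity:
                    continue
                bits = 2.0 * (n - mism) - 3.0 * mism
                e_value = index.total_bp * n * 2.0 ** (-bits)
                hits.append(HitRecord(
                    query_id=query.id, subject_id=subject.id,
                    percent_identity=round(identity, 2), aln_length=n,
                    q_start=0, q_end=n,
                    s_start=s_start, s_end=s_end, subject_strand=strand,
                    e_value=e_value, bit_score=bits,
                ))
    hits.sort(key=lambda h: (h.e_value, h.subject_id, h.s_start))
    return hits
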