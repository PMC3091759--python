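"""Paired-BES microsynteny classification.

The two end-reads of a BAC clone are separated by the insert (roughly
100-150 kb), so if both ends map close together, correctly oriented, on
one subject sequence of another genome, the region is a candidate for
conserved local order (microsynteny). The classifier applies three
criteria to each co-placement: (1) same subject sequence, (2) anchor
separation within an inclusive window (default 50-500 kb), (3) correct
relative orientation, meaning the two reads map on opposite strands and
face each other (each read's 3' end points toward the other anchor), as
the ends of a clone insert must. Criterion 3 can be relaxed to admit
regions that underwent localized inversions.

Because one end can hit a subject several times (duplications), each
end's hits are first merged into anchors — hits on the same subject and
strand within a merge window (default 10 kb) collapse to their best-E
representative — and every same-subject (anchor, anchor) combination is
one mapping locus. Loci per pair therefore estimate how many times the
region is present in the subject genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from beskit._util import round_half_up
from beskit.io_formats import BesPair, HitRecord, Strand

__all__ = [
    "PairLocus", "SyntenySummary", "Verdict", "SyntenyParams",
    "merge_anchors", "loci_for_pair", "classify_collinear", "synteny_summary",
]

DEFAULT_MIN_SEP = 50_000
DEFAULT_MAX_SEP = 500_000
DEFAULT_MERGE_WINDOW = 10_000


class Verdict(str, Enum):
    COLLINEAR = "COLLINEAR"
    FAIL_WINDOW = "FAIL_WINDOW"
    FAIL_ORIENTATION = "FAIL_ORIENTATION"


@dataclass(frozen=True)
class SyntenyParams:
    min_sep: int = DEFAULT_MIN_SEP
    max_sep: int = DEFAULT_MAX_SEP
    merge_window: int = DEFAULT_MERGE_WINDOW
    require_orientation: bool = True


@dataclass(frozen=True)
class PairLocus:
    pair_id: str
    subject_id: str
    end1_span: tuple[int, int]
    end2_span: tuple[int, int]
    end1_strand: Strand
    end2_strand: Strand
    separation: int  # distance between anchor midpoints, bp
    orientation_ok: bool


@dataclass
class SyntenySummary:
    n_pairs_total: int
    n_bes_with_hits: int
    n_pairs_with_both_ends_hit: int
    n_pairs_same_subject: int
    n_loci: int
    n_pairs_in_window: int
    n_pairs_correct_orientation: int
    multi_locus_pairs: int = 0
    multi_locus_pairs_on_different_subjects: int = 0

    @property
    def mean_loci_per_pair(self) -> float | None:
        """Loci per pair with a same-subject co-placement (one decimal)."""
        if self.n_pairs_same_subject == 0:
            return None
        return round_half_up(self.n_loci / self.n_pairs_same_subject, 1)

    @property
    def percent_of_pairs(self) -> float | None:
        """Collinear pairs as a percent of all input pairs (one decimal)."""
        if self.n_pairs_total == 0:
            return None
        return round_half_up(100.0 * self.n_pairs_correct_orientation / self.n_pairs_total, 1)

    @property
    def percent_same_subject_in_window(self) -> float | None:
        if self.n_pairs_same_subject == 0:
            return None
        return round_half_up(100.0 * self.n_pairs_in_window / self.n_pairs_same_subject, 1)

    @property
    def multi_locus_dispersal_fraction(self) -> float | None:
        """Of pairs with >1 locus, the fraction whose loci span >=2 subjects."""
        if self.multi_locus_pairs == 0:
            return None
        return round_half_up(
            self.multi_locus_pairs_on_different_subjects / self.multi_locus_pairs, 2)


def merge_anchors(hits: Sequence[HitRecord], merge_window: int = DEFAULT_MERGE_WINDOW) -> list[HitRecord]:
    """Collapse one end's hits into anchor representatives.

    Hits on the same subject and strand whose midpoints lie within
    `merge_window` of the running cluster's midpoint merge; the
    representative is the best hit (lowest E, then highest bit score,
    then leftmost).
    """
    groups: dict[tuple[str, Strand], list[HitRecord]] = {}
    for h in hits:
        groups.setdefault((h.subject_id, h.subject_strand), []).append(h)
    anchors: list[HitRecord] = []
    for key in sorted(groups, key=lambda k: (k[0], k[1].value)):
        ghits = sorted(groups[key], key=lambda h: (h.s_start + h.s_end) / 2)
        cluster: list[HitRecord] = []
        last_mid = None
        for h in ghits:
            mid = (h.s_start + h.s_end) / 2
            if last_mid is not None and mid - last_mid > merge_window:
                anchors.append(_best(cluster))
                cluster = []
            cluster.append(h)
            last_mid = mid
        if cluster:
            anchors.append(_best(cluster))
    return anchors


def _best(hits: Sequence[HitRecord]) -> HitRecord:
    return min(hits, key=lambda h: (h.e_value, -h.bit_score, h.s_start))


def _midpoint(h: HitRecord) -> float:
    return (h.s_start + h.s_end) / 2


def loci_for_pair(
    pair_id: str,
    hits_end1: Sequence[HitRecord],
    hits_end2: Sequence[HitRecord],
    merge_window: int = DEFAULT_MERGE_WINDOW,
) -> list[PairLocus]:
    """All same-subject co-placements of a pair's two ends.

    Each end's hits are merged into anchors first; every (anchor1,
    anchor2) combination on a shared subject is one locus.
    """
    a1 = merge_anchors(hits_end1, merge_window)
    a2 = merge_anchors(hits_end2, merge_window)
    loci: list[PairLocus] = []
    for h1 in a1:
        for h2 in a2:
            if h1.subject_id != h2.subject_id:
                continue
            m1, m2 = _midpoint(h1), _midpoint(h2)
            orientation_ok = False
            if h1.subject_strand != h2.subject_strand:
                plus_mid = m1 if h1.subject_strand is Strand.PLUS else m2
                minus_mid = m2 if h1.subject_strand is Strand.PLUS else m1
                orientation_ok = plus_mid <= minus_mid  # reads face inward
            loci.append(PairLocus(
                pair_id=pair_id, subject_id=h1.subject_id,
                end1_span=(h1.s_start, h1.s_end), end2_span=(h2.s_start, h2.s_end),
                end1_strand=h1.subject_strand, end2_strand=h2.subject_strand,
                separation=int(round(abs(m2 - m1))),
                orientation_ok=orientation_ok,
            ))
    return loci


def classify_collinear(
    locus: PairLocus,
    min_sep: int = DEFAULT_MIN_SEP,
    max_sep: int = DEFAULT_MAX_SEP,
    require_orientation: bool = True,
) -> Verdict:
    """Apply the separation-window and orientation criteria (bounds inclusive)."""
    if not min_sep <= locus.separation <= max_sep:
        return Verdict.FAIL_WINDOW
    if require_orientation and not locus.orientation_ok:
        return Verdict.FAIL_ORIENTATION
    return Verdict.COLLINEAR


def synteny_summary(
    pairs: Sequence[BesPair],
    hits: Mapping[str, Sequence[HitRecord]],
    params: SyntenyParams = SyntenyParams(),
) -> SyntenySummary:
    """The full mapping funnel for a set of pairs against one subject genome.

    `hits` is keyed by read (record) id. The funnel is monotone by
    construction: pairs on the same subject >= pairs within the window >=
    pairs correctly oriented.
    """
    n_bes_with_hits = 0
    n_both = 0
    n_same_subject = 0
    n_loci = 0
    n_window = 0
    n_orient = 0
    multi = 0
    multi_diff = 0
    for pair in pairs:
        h1 = hits.get(pair.forward.record.id, ())
        h2 = hits.get(pair.reverse.record.id, ())
        n_bes_with_hits += (1 if h1 else 0) + (1 if h2 else 0)
        if not (h1 and h2):
            continue
        n_both += 1
        loci = loci_for_pair(pair.clone_id, h1, h2, params.merge_window)
        if not loci:
            continue
        n_same_subject += 1
        n_loci += len(loci)
        verdicts = [classify_collinear(L, params.min_sep, params.max_sep, True) for L in loci]
        relaxed = [classify_collinear(L, params.min_sep, params.max_sep, False) for L in loci]
        if any(v is not Verdict.FAIL_WINDOW for v in verdicts):
            n_window += 1
        check = verdicts if params.require_orientation else relaxed
        if any(v is Verdict.COLLINEAR for v in check):
            n_orient += 1
        if len(loci) > 1:
            multi += 1
            if len({L.subject_id for L in loci}) > 1:
                multi_diff += 1
    return SyntenySummary(
        n_pairs_total=len(pairs),
        n_bes_with_hits=n_bes_with_hits,
        n_pairs_with_both_ends_hit=n_both,
        n_pairs_same_subject=n_same_subject,
        n_loci=n_loci,
        n_pairs_in_window=n_window,
        n_pairs_correct_orientation=n_orient,
        multi_locus_pairs=multi,
        multi_locus_pairs_on_different_subjects=multi_diff,
    )
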