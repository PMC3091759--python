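import numpy as np
import pytest

from beskit.io_formats import BesPair, BesRead, End, HitRecord, Library, SequenceRecord, Strand
from beskit.paired_bes_synteny import (
    SyntenyParams, Verdict, classify_collinear, loci_for_pair, merge_anchors,
    synteny_summary,
)


def _hit(query, subject, start, end, strand=Strand.PLUS, e=1e-40):
    return HitRecord(query_id=query, subject_id=subject, percent_identity=99.0,
                     aln_length=end - start, q_start=0, q_end=end - start,
                     s_start=start, s_end=end, subject_strand=strand,
                     e_value=e, bit_score=200.0)


def _pair(clone):
    mk = lambda suffix, end: BesRead(
        record=SequenceRecord(f"{clone}.{suffix}", "ACGT" * 50),
        library=Library.OTHER, clone_id=clone, end=end)
    return BesPair(clone_id=clone, forward=mk("f", End.FORWARD),
                   reverse=mk("r", End.REVERSE))


class TestLociForPair:
    def test_one_hit_per_end_one_locus(self):
        loci = loci_for_pair("p", [_hit("p.f", "chrA", 0, 500)],
                             [_hit("p.r", "chrA", 99_750, 100_250, Strand.MINUS)])
        assert len(loci) == 1
        assert loci[0].separation == 99_750

    def test_cartesian_within_subject(self):
        h1 = [_hit("p.f", "chrA", 0, 500), _hit("p.f", "chrA", 2_000_000, 2_000_500)]
        h2 = [_hit("p.r", "chrA", 100_000, 100_500, Strand.MINUS)]
        assert len(loci_for_pair("p", h1, h2)) == 2

    def test_disjoint_subjects_no_locus(self):
        assert loci_for_pair("p", [_hit("p.f", "chrA", 0, 500)],
                             [_hit("p.r", "chrB", 0, 500)]) == []

    def test_anchor_merging_collapses_nearby_hits(self):
        hits = [_hit("p.f", "chrA", 0, 500, e=1e-60),
                _hit("p.f", "chrA", 3_000, 3_500, e=1e-30),
                _hit("p.f", "chrA", 50_000, 50_500)]
        anchors = merge_anchors(hits, merge_window=10_000)
        assert len(anchors) == 2
        assert anchors[0].e_value == 1e-60  # best-E representative survives

    def test_opposite_strand_not_merged(self):
        hits = [_hit("p.f", "chrA", 0, 500, Strand.PLUS),
                _hit("p.f", "chrA", 1_000, 1_500, Strand.MINUS)]
        assert len(merge_anchors(hits, 10_000)) == 2


class TestClassifyCollinear:
    def _locus(self, sep, s1=Strand.PLUS, s2=Strand.MINUS):
        h1 = _hit("p.f", "chrA", 0, 500, s1)
        h2 = _hit("p.r", "chrA", sep, sep + 500, s2)
        (locus,) = loci_for_pair("p", [h1], [h2])
        assert locus.separation == sep
        return locus

    def test_convergent_in_window_collinear(self):
        assert classify_collinear(self._locus(200_000)) is Verdict.COLLINEAR

    @pytest.mark.parametrize("sep,verdict", [
        (49_999, Verdict.FAIL_WINDOW),
        (50_000, Verdict.COLLINEAR),
        (500_000, Verdict.COLLINEAR),
        (600_000, Verdict.FAIL_WINDOW),
    ])
    def test_window_bounds_inclusive(self, sep, verdict):
        assert classify_collinear(self._locus(sep)) is verdict

    def test_same_strand_fails_unless_orientation_relaxed(self):
        locus = self._locus(200_000, s2=Strand.PLUS)
        assert classify_collinear(locus) is Verdict.FAIL_ORIENTATION
        assert classify_collinear(locus, require_orientation=False) is Verdict.COLLINEAR

    def test_divergent_opposite_strands_fail(self):
        # minus-strand anchor left of the plus-strand anchor: reads face away
        h1 = _hit("p.f", "chrA", 200_000, 200_500, Strand.PLUS)
        h2 = _hit("p.r", "chrA", 0, 500, Strand.MINUS)
        (locus,) = loci_for_pair("p", [h1], [h2])
        assert not locus.orientation_ok
        assert classify_collinear(locus) is Verdict.FAIL_ORIENTATION


class TestSummary:
    def test_empty_inputs_all_zero(self):
        summary = synteny_summary([], {})
        assert summary.n_loci == 0 and summary.mean_loci_per_pair is None

    def test_funnel_counts_and_monotonicity_random(self, rng):
        pairs = [_pair(f"c{i}") for i in range(60)]
        hits: dict[str, list[HitRecord]] = {}
        for p in pairs:
            for read in (p.forward, p.reverse):
                if rng.random() < 0.85:
                    n = int(rng.integers(1, 3))
                    starts = rng.integers(0, 2_000_000, size=n)
                    hits[read.record.id] = [
                        _hit(read.record.id, f"chr{int(rng.integers(1, 4))}",
                             int(s), int(s) + 500,
                             Strand.PLUS if rng.random() < 0.5 else Strand.MINUS)
                        for s in starts
                    ]
        summary = synteny_summary(pairs, hits)
        assert summary.n_pairs_with_both_ends_hit >= summary.n_pairs_same_subject
        assert summary.n_pairs_same_subject >= summary.n_pairs_in_window
        assert summary.n_pairs_in_window >= summary.n_pairs_correct_orientation
        # relaxing orientation never loses pairs
        relaxed = synteny_summary(pairs, hits, SyntenyParams(require_orientation=False))
        assert relaxed.n_pairs_correct_orientation >= summary.n_pairs_correct_orientation
        assert relaxed.n_pairs_correct_orientation == summary.n_pairs_in_window

    def test_survey_derived_ratios(self):
        # loci-per-pair and window percentages recomputed from funnel counts
        from beskit.paired_bes_synteny import SyntenySummary
        cucumber = SyntenySummary(
            n_pairs_total=21_612, n_bes_with_hits=30_818,
            n_pairs_with_both_ends_hit=10_296, n_pairs_same_subject=6_475,
            n_loci=31_385, n_pairs_in_window=4_945,
            n_pairs_correct_orientation=4_138)
        assert cucumber.mean_loci_per_pair == 4.8
        assert cucumber.percent_of_pairs == 19.1
        poplar = SyntenySummary(
            n_pairs_total=21_612, n_bes_with_hits=4_676,
            n_pairs_with_both_ends_hit=315, n_pairs_same_subject=171,
            n_loci=276, n_pairs_in_window=95, n_pairs_correct_orientation=76)
        assert poplar.mean_loci_per_pair == 1.6
        assert poplar.percent_same_subject_in_window == 55.6
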