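import numpy as np
import pytest

from beskit._util import revcomp
from beskit.io_formats import SequenceRecord
from beskit.redundancy_assembly import (
    Orientation, cross_assemble, greedy_assemble, overlap_align, SINGLETON,
)

from _oracles import overlap_components
from conftest import fragment_template, random_seq


class TestOverlapAlign:
    def test_identical_sequences(self, rng):
        a = SequenceRecord("a", random_seq(rng, 200))
        res = overlap_align(a, SequenceRecord("b", a.sequence))
        assert res.accepted and res.overlap_length == 200 and res.identity == 100.0

    def test_exact_suffix_prefix_overlap(self, rng):
        template = random_seq(rng, 900)
        r1 = SequenceRecord("r1", template[:500])
        r2 = SequenceRecord("r2", template[400:])
        res = overlap_align(r1, r2)
        assert res.accepted and res.overlap_length == 100
        assert res.offset == 400  # merged span would be 900 bp

    def test_overlap_below_minimum_rejected(self, rng):
        template = random_seq(rng, 900)
        res = overlap_align(SequenceRecord("a", template[:500]),
                            SequenceRecord("b", template[421:]))
        assert not res.accepted and res.overlap_length < 80

    def test_identity_below_minimum_rejected(self, rng):
        template = random_seq(rng, 900)
        tail = list(template[400:])
        # 6 mismatches in the 100-bp overlap -> 94% identity
        for pos in (5, 20, 40, 60, 80, 95):
            tail[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[tail[pos]]
        res = overlap_align(SequenceRecord("a", template[:500]),
                            SequenceRecord("b", "".join(tail)))
        assert not res.accepted
        assert res.identity < 95.0

    def test_reverse_complement_orientation_detected(self, rng):
        template = random_seq(rng, 900)
        res = overlap_align(SequenceRecord("a", template[:500]),
                            SequenceRecord("b", revcomp(template[400:])))
        assert res.accepted and res.relative_orientation is Orientation.REVCOMP


class TestGreedyAssemble:
    def test_disjoint_reads_stay_singletons(self, rng):
        reads = [SequenceRecord(f"r{i}", random_seq(rng, 300)) for i in range(3)]
        asm = greedy_assemble(reads)
        assert asm.contigs == [] and len(asm.singletons) == 3
        assert set(asm.membership.values()) == {SINGLETON}

    def test_two_overlapping_reads_merge_to_forced_length(self, rng):
        template = random_seq(rng, 900)
        asm = greedy_assemble([SequenceRecord("r1", template[:500]),
                               SequenceRecord("r2", template[400:])])
        assert len(asm.contigs) == 1 and not asm.singletons
        consensus, members = asm.contigs[0]
        assert len(consensus.sequence) == 900
        assert consensus.sequence == template
        assert sorted(members) == ["r1", "r2"]

    def test_conservation_and_duplicate_ids(self, rng):
        reads = [SequenceRecord(f"r{i}", random_seq(rng, 200)) for i in range(6)]
        asm = greedy_assemble(reads)
        placed = sum(len(m) for _, m in asm.contigs) + len(asm.singletons)
        assert placed == len(reads) == len(asm.membership)
        with pytest.raises(ValueError, match="duplicate"):
            greedy_assemble(reads + [SequenceRecord("r0", "ACGT" * 30)])

    def test_membership_matches_component_oracle(self, rng):
        # random fragmentations of 2-kb templates; some fragments flipped
        for _ in range(12):
            template = random_seq(rng, 2000)
            frags = fragment_template(rng, template, 5, (400, 600), 120)
            frags = [
                SequenceRecord(f.id, revcomp(f.sequence)) if rng.random() < 0.4 else f
                for f in frags
            ]
            lone = SequenceRecord("lone", random_seq(rng, 450))
            seqs = frags + [lone]
            asm = greedy_assemble(seqs)
            got = {frozenset(m) for _, m in asm.contigs}
            got |= {frozenset([s.id]) for s in asm.singletons}
            assert got == overlap_components(seqs)

    def test_idempotent_on_own_output(self, rng):
        template = random_seq(rng, 1500)
        frags = fragment_template(rng, template, 4, (400, 600), 150)
        asm = greedy_assemble(frags)
        again = greedy_assemble(asm.sequences)
        assert len(again.sequences) == len(asm.sequences)
        assert again.contigs == []


class TestCrossAssemble:
    def test_disjoint_assemblies_no_merges(self, rng):
        asm1 = greedy_assemble([SequenceRecord(f"a{i}", random_seq(rng, 300)) for i in range(3)])
        asm2 = greedy_assemble([SequenceRecord(f"b{i}", random_seq(rng, 300)) for i in range(2)])
        merged, report = cross_assemble(asm1, asm2)
        assert len(merged.sequences) == 5
        assert report.sequences_removed == 0 and report.bp_removed == 0

    def test_self_cross_assembly_merges_every_copy(self, rng):
        seqs = [SequenceRecord(f"s{i}", random_seq(rng, 300)) for i in range(3)]
        asm1 = greedy_assemble(seqs)
        asm2 = greedy_assemble([SequenceRecord(r.id, r.sequence) for r in seqs])
        merged, report = cross_assemble(asm1, asm2)
        assert len(merged.contigs) == 3 and not merged.singletons
        assert report.sequences_removed == 3

    def test_id_collision_rejected(self, rng):
        seqs = [SequenceRecord("s0", random_seq(rng, 300))]
        asm = greedy_assemble(seqs)
        with pytest.raises(ValueError, match="collision"):
            cross_assemble(asm, asm, prefixes=("A", "A"))

    def test_partial_cross_redundancy_counts(self, rng):
        # one shared sequence between the two sets -> exactly one merge
        shared = random_seq(rng, 400)
        asm1 = greedy_assemble([SequenceRecord("a0", shared),
                                SequenceRecord("a1", random_seq(rng, 400))])
        asm2 = greedy_assemble([SequenceRecord("b0", shared),
                                SequenceRecord("b1", random_seq(rng, 400))])
        merged, report = cross_assemble(asm1, asm2)
        assert report.input_sequences == 4
        assert report.output_sequences == 3
        assert report.sequences_removed == 1
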