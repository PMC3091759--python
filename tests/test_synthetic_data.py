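import numpy as np
import pytest

from beskit import synthetic_data as synth
from beskit._util import revcomp
from beskit.io_formats import Library
from beskit.ssr_scanner import scan_many
from beskit.synthetic_data import (
    BlockOrientation, FeatureRequest, GenomeModel, LibrarySpec, SyntenySpec,
    simulate_genome, simulate_library, simulate_library_detailed,
    simulate_related_genome,
)


class TestSimulateGenome:
    def test_no_requested_features_scan_is_clean(self):
        g = simulate_genome(1, 30_000, FeatureRequest(), seed=1)
        assert g.ledger.ssrs == [] and g.ledger.repeats == []
        assert scan_many(g.sequences) == []

    def test_requested_ssr_count_planted(self):
        g = simulate_genome(2, 50_000, FeatureRequest(n_ssrs=100), seed=2)
        assert len(g.ledger.ssrs) == 100

    def test_determinism_same_seed(self):
        a = simulate_genome(2, 20_000, FeatureRequest(n_ssrs=10, n_repeats=5), seed=7)
        b = simulate_genome(2, 20_000, FeatureRequest(n_ssrs=10, n_repeats=5), seed=7)
        assert [s.sequence for s in a.sequences] == [s.sequence for s in b.sequences]
        c = simulate_genome(2, 20_000, FeatureRequest(n_ssrs=10, n_repeats=5), seed=8)
        assert [s.sequence for s in c.sequences] != [s.sequence for s in a.sequences]

    def test_gc_near_requested(self):
        g = simulate_genome(1, 200_000, FeatureRequest(), seed=3)
        from beskit.stats_report import gc_content
        assert gc_content(g.sequences) == pytest.approx(35.2, abs=0.8)

    def test_ledger_spans_inside_sequences(self):
        g = simulate_genome(2, 40_000, FeatureRequest(n_ssrs=30, n_repeats=10, n_genes=5), seed=4)
        lengths = {s.id: len(s.sequence) for s in g.sequences}
        for L in g.ledger.ssrs:
            assert 0 <= L.start < L.end <= lengths[L.seq_id]
        for r in g.ledger.repeats:
            assert 0 <= r.start < r.end <= lengths[r.seq_id]

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="packing|larger"):
            simulate_genome(1, 5_000, FeatureRequest(n_repeats=40,
                                                     repeat_len_range=(700, 800)), seed=5)


class TestSimulateLibrary:
    def _genome(self, seed=11):
        return simulate_genome(1, 60_000, FeatureRequest(n_restriction_sites=60), seed=seed)

    def test_single_clone_reads_are_genome_substrings(self):
        g = self._genome()
        spec = LibrarySpec(n_clones=1, mean_insert=5_000, insert_sd=300,
                           method=LibrarySpec.Method.RANDOM_SHEAR, seed=1)
        pairs = simulate_library(g, spec)
        assert len(pairs) == 1
        genome_seq = g.sequences[0].sequence
        assert pairs[0].forward.record.sequence in genome_seq
        assert revcomp(pairs[0].reverse.record.sequence) in genome_seq

    def test_empty_fraction_rounding(self):
        g = self._genome()
        spec = LibrarySpec(n_clones=100, mean_insert=5_000, insert_sd=300,
                           method=LibrarySpec.Method.RANDOM_SHEAR, seed=2,
                           empty_fraction=0.2, library=Library.RCM)
        pairs = simulate_library(g, spec)
        assert len(pairs) == 80
        assert all(p.forward.library is Library.RCM for p in pairs)

    def test_restriction_inserts_bounded_by_sites(self):
        g = self._genome()
        sites = set(g.ledger.restriction_sites["chr1"])
        spec = LibrarySpec(n_clones=30, mean_insert=5_000, insert_sd=500,
                           method=LibrarySpec.Method.RESTRICTION, seed=3)
        pairs, truths = simulate_library_detailed(g, spec)
        assert len(pairs) == 30
        for t in truths:
            assert t.insert_start in sites and t.insert_end in sites

    def test_restriction_bias_follows_site_distribution(self):
        # sites only in the left half -> all inserts in the left half
        g = self._genome()
        left = [s for s in g.ledger.restriction_sites["chr1"] if s < 30_000]
        biased = GenomeModel(sequences=g.sequences,
                             ledger=synth.FeatureLedger(restriction_sites={"chr1": left}))
        spec = LibrarySpec(n_clones=20, mean_insert=4_000, insert_sd=400,
                           method=LibrarySpec.Method.RESTRICTION, seed=4)
        _, truths = simulate_library_detailed(biased, spec)
        assert truths and all(t.insert_end <= 30_000 for t in truths)

    def test_restriction_without_sites_rejected(self):
        g = simulate_genome(1, 20_000, FeatureRequest(), seed=12)
        g.ledger.restriction_sites = {"chr1": []}
        spec = LibrarySpec(n_clones=1, mean_insert=2_000, insert_sd=100,
                           method=LibrarySpec.Method.RESTRICTION, seed=1)
        with pytest.raises(ValueError, match="restriction site"):
            simulate_library(g, spec)

    def test_mean_read_length_converges(self):
        g = simulate_genome(1, 120_000, FeatureRequest(), seed=13)
        spec = LibrarySpec(n_clones=3_000, mean_insert=5_000, insert_sd=300,
                           method=LibrarySpec.Method.RANDOM_SHEAR, seed=5)
        pairs = simulate_library(g, spec)
        lengths = [len(p.forward.record.sequence) for p in pairs]
        lengths += [len(p.reverse.record.sequence) for p in pairs]
        mean = float(np.mean(lengths))
        assert abs(mean - 543) / 543 < 0.02
        assert min(lengths) >= 50 and max(lengths) <= 879


class TestRelatedGenome:
    def _source(self):
        return simulate_genome(1, 80_000, FeatureRequest(), seed=21)

    def test_identity_copies_when_no_noise(self):
        src = self._source()
        tgt, ledger = simulate_related_genome(
            src, SyntenySpec(n_blocks=4, block_len=(5_000, 8_000), seed=1))
        src_seq = {s.id: s.sequence for s in src.sequences}
        tgt_seq = {s.id: s.sequence for s in tgt.sequences}
        assert len(ledger) == 4
        for b in ledger:
            assert b.orientation is BlockOrientation.SAME
            assert (tgt_seq[b.target_chrom][b.target_start:b.target_end]
                    == src_seq[b.source_chrom][b.source_start:b.source_end])

    def test_duplication_multiplicity_ledgered(self):
        src = self._source()
        tgt, ledger = simulate_related_genome(
            src, SyntenySpec(n_blocks=5, block_len=(3_000, 4_000), seed=2,
                             duplication_multiplicity=2))
        assert len(ledger) == 10
        per_block = {}
        for b in ledger:
            per_block.setdefault((b.source_chrom, b.source_start), set()).add(b.copy_index)
        assert all(copies == {0, 1} for copies in per_block.values())
        # copies of one block land on distinct target chromosomes
        chroms = {}
        for b in ledger:
            chroms.setdefault((b.source_chrom, b.source_start), set()).add(b.target_chrom)
        assert all(len(c) == 2 for c in chroms.values())

    def test_all_inverted_when_probability_one(self):
        src = self._source()
        _, ledger = simulate_related_genome(
            src, SyntenySpec(n_blocks=3, block_len=(2_000, 3_000), seed=3,
                             inversion_prob=1.0))
        assert all(b.orientation is BlockOrientation.INVERTED for b in ledger)

    def test_divergence_rate_applied(self):
        src = self._source()
        tgt, ledger = simulate_related_genome(
            src, SyntenySpec(n_blocks=2, block_len=(10_000, 10_000), seed=4,
                             divergence=0.05))
        src_seq = {s.id: s.sequence for s in src.sequences}
        tgt_seq = {s.id: s.sequence for s in tgt.sequences}
        for b in ledger:
            a = src_seq[b.source_chrom][b.source_start:b.source_end]
            c = tgt_seq[b.target_chrom][b.target_start:b.target_end]
            mism = sum(1 for x, y in zip(a, c) if x != y)
            assert 0.02 < mism / len(a) < 0.09
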