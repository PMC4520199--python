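"""The truth-labeled simulator: reference, contigs with injected errors, reads."""

import json

import numpy as np
import pytest

from contigrank.feature_extraction import compute_depth
from contigrank.formats_io import read_contigs, read_psl, read_read_alignments, read_table
from contigrank.reference_scoring import percent_identity, score_table
from contigrank.synthetic_fixtures import (
    SimulationParams,
    derive_contigs,
    make_fixture,
    simulate_reads,
    simulate_reference,
    write_sam,
)


def params(**kw):
    base = dict(seed=3, genome_length=30_000, n_contigs=20,
                contig_length_range=(500, 1500), min_chimera_distance=5_000)
    base.update(kw)
    return SimulationParams(**base)


class TestReference:
    def test_gc_content_within_binomial_bound(self):
        p = params(genome_length=1000, gc_fraction=0.5, min_chimera_distance=100)
        seq = simulate_reference(p)
        gc = sum(seq.count(b) for b in "GC")
        assert len(seq) == 1000
        assert abs(gc - 500) <= 50  # 3 sigma of Binomial(1000, 0.5)

    def test_deterministic_given_seed(self):
        assert simulate_reference(params()) == simulate_reference(params())
        assert simulate_reference(params()) != simulate_reference(params(seed=4))

    def test_extreme_gc(self):
        seq = simulate_reference(params(genome_length=500, gc_fraction=1.0,
                                        min_chimera_distance=100))
        assert set(seq) <= {"G", "C"}


class TestDeriveContigs:
    def zero_error(self, **kw):
        return params(substitution_rate=0.0, insertion_rate=0.0, deletion_rate=0.0,
                      p_chimera=0.0, p_hypermutated=0.0, **kw)

    def test_zero_error_rates_give_perfect_alignments(self):
        p = self.zero_error()
        ref = simulate_reference(p)
        contigs, psl, truth = derive_contigs(ref, p)
        assert len(psl) == len(contigs)
        for rec, c in zip(psl, contigs):
            assert rec.misMatches == 0
            assert (rec.qStart, rec.qEnd) == (0, rec.qSize)
            assert rec.qSize == c.length_padded
            # the contig really is the reference substring it claims to be
            assert c.bases == ref[rec.tStart:rec.tEnd]
        assert all(t.label == "good" for t in truth.per_contig.values())

    def test_substitution_counts_flow_into_psl_and_identity(self):
        p = params(substitution_rate=0.01, insertion_rate=0.0, deletion_rate=0.0,
                   p_chimera=0.0, p_hypermutated=0.0)
        ref = simulate_reference(p)
        contigs, psl, truth = derive_contigs(ref, p)
        for rec in psl:
            t = truth.per_contig[rec.qName]
            assert rec.misMatches == t.n_substitutions
            # the contig differs from its source in exactly those positions
            src = ref[rec.tStart:rec.tEnd]
            c = next(x for x in contigs if x.contig_id == rec.qName)
            diffs = [i for i, (a, b) in enumerate(zip(c.bases, src)) if a != b]
            assert diffs == t.substitution_positions

    def test_truth_pident_agrees_with_scorer_exactly(self):
        p = params(p_chimera=0.3)
        ref = simulate_reference(p)
        contigs, psl, truth = derive_contigs(ref, p)
        scores = score_table(contigs, psl)
        for _, row in scores.iterrows():
            t = truth.per_contig[row["contig_id"]]
            assert 100.0 - row["identity_dev"] == pytest.approx(t.true_pident, abs=1e-9)

    def test_chimeras_fragmented_and_bad(self):
        p = params(p_chimera=1.0)
        ref = simulate_reference(p)
        contigs, psl, truth = derive_contigs(ref, p)
        scores = score_table(contigs, psl)
        assert (scores["fragmentation"] >= 1).all()
        assert all(t.label == "bad" for t in truth.per_contig.values())
        # the two source loci are genuinely distant
        for t in truth.per_contig.values():
            (a0, _), (b0, _) = t.source_intervals
            assert abs(a0 - b0) >= p.min_chimera_distance

    def test_psl_invariants_hold_across_many_seeds(self):
        for seed in range(1, 101):
            p = params(seed=seed, n_contigs=3, genome_length=8000,
                       contig_length_range=(300, 600), min_chimera_distance=2000,
                       substitution_rate=0.02, insertion_rate=0.005,
                       deletion_rate=0.005, p_chimera=0.3)
            ref = simulate_reference(p)
            _, psl, _ = derive_contigs(ref, p)
            for rec in psl:
                rec.validate()  # raises on any violated invariant

    def test_contig_longer_than_genome_rejected(self):
        p = params(genome_length=30_000, contig_length_range=(40_000, 50_000))
        with pytest.raises(ValueError, match="genome length"):
            derive_contigs(simulate_reference(p), p)


class TestSimulateReads:
    def test_interior_depth_near_target(self):
        p = params(genome_length=15_000, n_contigs=1,
                   contig_length_range=(10_000, 10_000), read_length=100,
                   mean_depth=30.0, substitution_rate=0.0, p_chimera=0.0,
                   p_hypermutated=0.0, insertion_rate=0.0, deletion_rate=0.0)
        ref = simulate_reference(p)
        contigs, _, _ = derive_contigs(ref, p)
        reads = simulate_reads(contigs, p)
        depth = compute_depth(contigs[0].length_padded, [
            type("R", (), {"aligned_blocks": [(r.start, r.start + len(r.sequence))],
                           "read_id": r.read_id})() for r in reads])
        interior = depth[200:-200]
        assert abs(interior.mean() - 30.0) < 3.0

    def test_zero_depth_no_reads(self):
        p = params(mean_depth=0.0)
        contigs, _, _ = derive_contigs(simulate_reference(p), p)
        assert simulate_reads(contigs, p) == []

    def test_sam_round_trip(self, tmp_path):
        p = params(n_contigs=4, mean_depth=5.0)
        contigs, _, truth = derive_contigs(simulate_reference(p), p)
        reads = simulate_reads(contigs, p, truth)
        sam = tmp_path / "reads.sam"
        write_sam(reads, contigs, sam)
        parsed = list(read_read_alignments(sam))
        assert len(parsed) == len(reads)
        for got, want in zip(parsed, reads):
            assert got.read_id == want.read_id
            assert got.contig_id == want.contig_id
            assert got.start == want.start
            assert got.aligned_blocks == [(want.start, want.start + len(want.sequence))]
            assert got.mean_read_quality == pytest.approx(30.0)

    def test_chimera_junction_starves_spanning_coverage(self):
        p = params(n_contigs=10, p_chimera=1.0, mean_depth=40.0,
                   contig_length_range=(2000, 3000))
        contigs, _, truth = derive_contigs(simulate_reference(p), p)
        reads = simulate_reads(contigs, p, truth)
        for c in contigs:
            j = truth.per_contig[c.contig_id].junction
            assert not any(r.start < j < r.start + len(r.sequence)
                           for r in reads if r.contig_id == c.contig_id)


class TestMakeFixture:
    def test_files_written_and_mutually_consistent(self, tmp_path):
        p = params(n_contigs=8)
        manifest = make_fixture(p, tmp_path / "fx")
        d = tmp_path / "fx"
        for f in ("ref.fasta", "contigs.fasta", "reads.sam", "truth.psl",
                  "truth.tsv", "manifest.json"):
            assert (d / f).exists()
        contigs = read_contigs(d / "contigs.fasta")
        psl = read_psl(d / "truth.psl")
        truth = read_table(d / "truth.tsv")
        assert len(contigs) == 8
        assert {r.qName for r in psl} == {c.contig_id for c in contigs}
        assert truth["contig_id"].tolist() == [c.contig_id for c in contigs]
        assert json.loads((d / "manifest.json").read_text())["n_reads"] == manifest["n_reads"]
        # labels obey the declared rule: chimeric or substitution density > cutoff
        lengths = {c.contig_id: c.length_padded for c in contigs}
        for _, row in truth.iterrows():
            expect_bad = bool(row["is_chimera"]) or \
                row["n_substitutions"] / lengths[row["contig_id"]] > p.bad_rate_cutoff
            assert (row["label"] == "bad") == expect_bad

    def test_same_seed_byte_identical(self, tmp_path):
        p = params(n_contigs=5)
        make_fixture(p, tmp_path / "a")
        make_fixture(p, tmp_path / "b")
        for f in ("ref.fasta", "contigs.fasta", "reads.sam", "truth.psl", "truth.tsv"):
            assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()

    def test_single_contig_fixture(self, tmp_path):
        make_fixture(params(n_contigs=1), tmp_path / "fx")
        assert len(read_contigs(tmp_path / "fx" / "contigs.fasta")) == 1

    def test_refuses_overwrite_without_force(self, tmp_path):
        p = params(n_contigs=2)
        make_fixture(p, tmp_path / "fx")
        with pytest.raises(FileExistsError):
            make_fixture(p, tmp_path / "fx")
        make_fixture(p, tmp_path / "fx", force=True)  # no error
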