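"""Synthetic benchmark generation: references, implants, reads, alignment."""

import numpy as np
import pysam
import pytest

from svgraph.evaluation import read_truth
from svgraph.sim_forge import (
    Block,
    CsvSpec,
    HaplotypeMap,
    OpSpec,
    ReadPair,
    SimConfig,
    _realize,
    implant_csvs,
    make_reference,
    reported_catalog_spec,
    randomized_spec,
    revcomp,
    simulate_read_pairs,
    truth_guided_align,
    write_fastq,
    REPORTED_TYPES,
)


class TestReference:
    def test_seed_determinism(self, tmp_path):
        a = make_reference(str(tmp_path / "a.fa"), 120_000,
                           rng=np.random.default_rng(5))
        b = make_reference(str(tmp_path / "b.fa"), 120_000,
                           rng=np.random.default_rng(5))
        assert a == b
        assert (tmp_path / "a.fa.fai").exists()

    def test_gc_content(self, tmp_path):
        seq = make_reference(str(tmp_path / "gc.fa"), 1_000_000,
                             gc_fraction=0.5, rng=np.random.default_rng(1))
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.01

    def test_tiny_genome_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            make_reference(str(tmp_path / "t.fa"), 10)


class TestImplant:
    def ref(self, n=200_000, seed=3):
        rng = np.random.default_rng(seed)
        codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n)
        return codes.tobytes().decode()

    def test_homozygous_deletion_shortens_both_haplotypes(self):
        ref = self.ref()
        cfg = SimConfig(seed=1, n_events=1, zygosity="hom")
        spec = CsvSpec("Del", (OpSpec("Del", 500),), "hom")
        h1, h2, truths = implant_csvs(len(ref), cfg, np.random.default_rng(1),
                                      [spec])
        assert h1.length == len(ref) - 500
        assert h2.length == len(ref) - 500
        (t,) = truths
        assert t.components[0][0] == "Del"
        assert t.components[0][2] - t.components[0][1] == 500

    def test_del_spa_del_has_three_components(self):
        spec = reported_catalog_spec("DelSpaDel", np.random.default_rng(4))
        real = _realize(spec, 10_000)
        assert [c[0] for c in real.components] == ["Del", "spacer", "Del"]

    def test_tantrans_swaps_adjacent_segments(self):
        ref = self.ref()
        spec = CsvSpec("Tantrans", (OpSpec("Tantrans", 300, length2=400),))
        real = _realize(spec, 10_000)
        hm = HaplotypeMap([Block(0, 10_000)] + list(real.blocks)
                          + [Block(real.consumed[1], len(ref))])
        hap = hm.sequence(ref)
        assert hap[10_000:10_400] == ref[10_300:10_700]
        assert hap[10_400:10_700] == ref[10_000:10_300]
        assert hm.length == len(ref)

    def test_haplotype_length_matches_signed_length_changes(self):
        ref = self.ref()
        cfg = SimConfig(seed=9, n_events=12, zygosity="hom")
        rng = np.random.default_rng(9)
        h1, h2, truths = implant_csvs(len(ref), cfg, rng)
        # recompute expected length from the block lists themselves
        assert h1.length == sum(len(b) for b in h1.blocks)
        delta = h1.length - len(ref)
        assert abs(delta) < 12 * 3 * 5000  # bounded by op count x sizes

    def test_every_reported_type_realizes_with_valid_truth(self):
        rng = np.random.default_rng(7)
        for name in REPORTED_TYPES:
            spec = reported_catalog_spec(name, rng)
            real = _realize(spec, 50_000)
            assert real.consumed[0] == 50_000
            assert real.components
            for ty, s, e in real.components:
                assert s <= e

    def test_randomized_mode_composes_two_to_four_ops(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            spec = randomized_spec(rng)
            assert 2 <= len(spec.operations) <= 4

    def test_overflow_raises(self):
        ref = self.ref(120_000)
        cfg = SimConfig(seed=1, n_events=30)
        with pytest.raises(ValueError, match="events"):
            implant_csvs(len(ref), cfg, np.random.default_rng(1))


class TestReads:
    def test_pair_count_matches_coverage(self):
        seqs = ["A" * 500_000, "A" * 500_000]
        cfg = SimConfig(genome_length=500_000, coverage=30, seed=2,
                        base_error_rate=0.0)
        pairs = list(simulate_read_pairs(seqs, cfg, np.random.default_rng(2)))
        expected = 30 * 1_000_000 / (2 * 2 * 100)
        assert abs(len(pairs) - expected) / expected < 0.01

    def test_error_free_reads_are_exact_substrings(self):
        rng = np.random.default_rng(3)
        seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                         size=200_000).tobytes().decode()
        cfg = SimConfig(genome_length=200_000, coverage=2, seed=3,
                        base_error_rate=0.0)
        for p in simulate_read_pairs([seq, seq], cfg, np.random.default_rng(3)):
            assert p.seq1 in seq
            assert revcomp(p.seq2) in seq

    def test_same_seed_identical_fastq(self, tmp_path):
        seqs = ["ACGT" * 50_000] * 2
        cfg = SimConfig(genome_length=200_000, coverage=1, seed=5)
        for tag in ("x", "y"):
            pairs = simulate_read_pairs(seqs, cfg, np.random.default_rng(5))
            write_fastq(pairs, str(tmp_path / f"{tag}_1.fq"),
                        str(tmp_path / f"{tag}_2.fq"))
        assert (tmp_path / "x_1.fq").read_bytes() == (tmp_path / "y_1.fq").read_bytes()
        assert (tmp_path / "x_2.fq").read_bytes() == (tmp_path / "y_2.fq").read_bytes()

    def test_insert_shorter_than_reads_rejected(self):
        with pytest.raises(ValueError, match="insert_mean"):
            SimConfig(insert_mean=150.0, read_length=100)


class TestTruthGuidedAlignment:
    REF_LEN = 200_000

    def align_pairs(self, hapmap, pairs, tmp_path, name="t"):
        cfg = SimConfig(seed=1)
        bam = str(tmp_path / f"{name}.bam")
        truth_guided_align(pairs, [hapmap], cfg, self.REF_LEN, bam)
        return bam

    def hap_with(self, blocks):
        return HaplotypeMap([Block(0, 50_000)] + blocks)

    def make_pair(self, hap_seq, start, insert, name="p0"):
        rl = 100
        return ReadPair(name, 0, start, insert,
                        hap_seq[start:start + rl],
                        revcomp(hap_seq[start + insert - rl:start + insert]))

    def ref(self):
        rng = np.random.default_rng(11)
        return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                          size=self.REF_LEN).tobytes().decode()

    def test_pair_straddling_deletion_has_inflated_template(self, tmp_path):
        ref = self.ref()
        # 2 kb deletion at 50,000
        hm = HaplotypeMap([Block(0, 50_000), Block(52_000, self.REF_LEN)])
        hap = hm.sequence(ref)
        pair = self.make_pair(hap, 49_750, 500)
        bam = self.align_pairs(hm, [pair], tmp_path, "del")
        with pysam.AlignmentFile(bam) as fh:
            recs = [r for r in fh.fetch() if not r.is_supplementary]
        assert len(recs) == 2
        assert not recs[0].is_reverse and recs[1].is_reverse
        assert abs(recs[0].template_length) == 500 + 2000
        assert not recs[0].is_proper_pair

    def test_read_crossing_inversion_breakpoint_splits_at_junction(self, tmp_path):
        ref = self.ref()
        # 1 kb inversion at [50,000, 51,000)
        hm = HaplotypeMap([Block(0, 50_000), Block(50_000, 51_000, "-"),
                           Block(51_000, self.REF_LEN)])
        hap = hm.sequence(ref)
        # read1 covers hap [49,950, 50,050): 50 bp before + 50 bp inside
        pair = self.make_pair(hap, 49_950, 500)
        bam = self.align_pairs(hm, [pair], tmp_path, "inv")
        with pysam.AlignmentFile(bam) as fh:
            r1 = [r for r in fh.fetch() if not r.is_read2]
        assert len(r1) == 2  # primary + supplementary
        forward = [r for r in r1 if not r.is_reverse][0]
        inverted = [r for r in r1 if r.is_reverse][0]
        assert abs(forward.reference_end - 50_000) <= 1
        # the inverted piece maps to the far end of the inversion
        assert abs(inverted.reference_end - 51_000) <= 1
        assert all(r.has_tag("SA") for r in r1)

    def test_variant_free_pair_is_proper(self, tmp_path):
        ref = self.ref()
        hm = HaplotypeMap([Block(0, self.REF_LEN)])
        pair = self.make_pair(ref, 10_000, 480)
        bam = self.align_pairs(hm, [pair], tmp_path, "plain")
        with pysam.AlignmentFile(bam) as fh:
            recs = list(fh.fetch())
        assert len(recs) == 2
        assert all(r.is_proper_pair for r in recs)
        assert abs(recs[0].template_length) == 480
        assert recs[0].cigartuples == [(0, 100)]

    def test_bam_is_sorted_and_indexed(self, small_het_dataset):
        with pysam.AlignmentFile(small_het_dataset.bam) as fh:
            assert fh.header["HD"]["SO"] == "coordinate"
            assert fh.has_index()

    def test_truth_file_loads(self, small_het_dataset):
        truths = read_truth(small_het_dataset.truth_tsv)
        assert len(truths) == 8
        assert all(t.zygosity == "het" for t in truths)
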