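"""Preprocessing, the exact-match aligner, the partition, and SAM reading."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calchip import (
    AlignmentRecord,
    Bucket,
    Genome,
    Read,
    align_exact,
    filter_short,
    partition_from_alignments,
    partition_reads,
    read_sam,
    trim_reads,
)
from calchip.reads import SamParseError, reverse_complement


def mk_read(seq, rid="r"):
    return Read(rid, seq, "I" * len(seq))


def random_reads(rng, n, min_len=20, max_len=260):
    lengths = rng.integers(min_len, max_len + 1, size=n)
    bases = np.array(list("ACGT"))
    return [
        mk_read("".join(bases[rng.integers(0, 4, size=l)]), f"r{i}")
        for i, l in enumerate(lengths)
    ]


class TestTrim:
    @pytest.mark.parametrize(
        "length,expected",
        [(250, 190), (200, 190), (150, 140), (8, 0), (10, 0), (11, 1)],
    )
    def test_trimmed_length(self, length, expected):
        (out,) = trim_reads([mk_read("A" * length)])
        assert len(out) == expected
        assert len(out.sequence) == len(out.quality)

    def test_keeps_original_bases_11_to_200(self, rng):
        (read,) = random_reads(rng, 1, min_len=150, max_len=150)
        (out,) = trim_reads([read])
        assert out.sequence == read.sequence[10:150]

    def test_trim_is_slice_on_original_coordinates(self, rng):
        reads = random_reads(rng, 50)
        for original, trimmed in zip(reads, trim_reads(reads)):
            assert trimmed.sequence == original.sequence[10:200]

    def test_double_trim_equals_single(self, rng):
        reads = random_reads(rng, 30)
        once = trim_reads(reads, 10, 200)
        twice = trim_reads(trim_reads(reads, 10, 200), 0, 10**9)
        assert once == twice

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            trim_reads([], head_trim=-1)
        with pytest.raises(ValueError):
            trim_reads([], head_trim=10, max_end=10)


class TestFilterShort:
    def test_strict_boundary(self):
        reads = [mk_read("A" * n, f"len{n}") for n in (49, 50, 51)]
        kept = filter_short(reads, min_len=50)
        assert [r.id for r in kept] == ["len50", "len51"]

    def test_empty_input(self):
        assert filter_short([]) == []

    def test_idempotent_and_order_preserving(self, rng):
        reads = random_reads(rng, 200)
        once = filter_short(reads)
        assert filter_short(once) == once
        assert once == [r for r in reads if len(r) >= 50]

    def test_retained_count_matches_brute_force(self, rng):
        reads = random_reads(rng, 1_000)
        trimmed = trim_reads(reads)
        kept = filter_short(trimmed)
        expected = sum(
            1 for r in reads if len(r.sequence[10:200]) >= 50
        )
        assert len(kept) == expected

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 300), max_size=30), st.integers(0, 100))
    def test_every_survivor_meets_cutoff(self, lengths, min_len):
        reads = [mk_read("A" * n, f"r{i}") for i, n in enumerate(lengths)]
        kept = filter_short(reads, min_len=min_len)
        assert all(len(r) >= min_len for r in kept)
        assert filter_short(kept, min_len=min_len) == kept


@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    seqs = ["".join(bases[rng.integers(0, 4, 1000)]) for _ in range(2)]
    return Genome("exp", (("exp1", seqs[0]), ("exp2", seqs[1])))


class TestAlignExact:
    def test_forward_copy_maps_at_source(self, toy_genome):
        window = toy_genome.sequence("exp1")[100:140]
        (rec,) = align_exact([mk_read(window)], toy_genome)
        assert rec == AlignmentRecord("r", True, "exp1", 100, "+", 40)

    def test_reverse_complement_maps_minus(self, toy_genome):
        window = toy_genome.sequence("exp2")[300:340]
        (rec,) = align_exact([mk_read(reverse_complement(window))], toy_genome)
        assert (rec.chrom, rec.pos, rec.strand) == ("exp2", 300, "-")

    def test_absent_read_unmapped(self, toy_genome):
        absent = "A" * 40  # a 40-mer homopolymer is absent from 2 kb of random sequence
        assert absent not in toy_genome.sequence("exp1")
        assert absent not in toy_genome.sequence("exp2")
        (rec,) = align_exact([mk_read(absent)], toy_genome)
        assert rec == AlignmentRecord("r", False)

    def test_empty_read_unmapped(self, toy_genome):
        (rec,) = align_exact([mk_read("")], toy_genome)
        assert not rec.mapped

    def test_chromosome_order_breaks_ties(self):
        genome = Genome("g", (("c1", "TTTACGTACGTTTT"), ("c2", "ACGTACGTAAAA")))
        (rec,) = align_exact([mk_read("ACGTACGT")], genome)
        assert (rec.chrom, rec.pos) == ("c1", 3)

    def test_leftmost_and_plus_strand_preferred(self):
        # palindromic 8-mer: forward and reverse hits coincide -> "+" wins
        genome = Genome("g", (("c", "TTGAATTCGAATTCTT"),))
        (rec,) = align_exact([mk_read("GAATTC")], genome)
        assert (rec.pos, rec.strand) == (2, "+")

    def test_agrees_with_string_search_on_simulated_reads(
        self, small_genomes, small_experiment
    ):
        exp, cal = small_genomes
        ip, _, _ = small_experiment
        sample = ip[:300]
        for read, rec in zip(sample, align_exact(sample, exp)):
            fwd = any(read.sequence in s for _, s in exp.chromosomes)
            rev = any(reverse_complement(read.sequence) in s for _, s in exp.chromosomes)
            assert rec.mapped == (fwd or rev)


class TestPartition:
    def test_read_in_both_genomes_is_calibration(self, toy_genome):
        shared = toy_genome.sequence("exp1")[50:90]
        cal = Genome("cal", (("cal1", "T" * 30 + shared + "G" * 30),))
        part = partition_reads([mk_read(shared)], cal, toy_genome)
        assert part.assignment["r"] is Bucket.CALIBRATION

    def test_exclusive_and_unmapped_buckets(self, toy_genome):
        cal = Genome("cal", (("cal1", "TGCA" * 250),))
        reads = [
            mk_read(toy_genome.sequence("exp1")[10:50], "only_exp"),
            mk_read("TGCA" * 10, "only_cal"),
            mk_read("A" * 40, "nowhere"),
        ]
        part = partition_reads(reads, cal, toy_genome)
        assert part.assignment["only_exp"] is Bucket.EXPERIMENTAL
        assert part.assignment["only_cal"] is Bucket.CALIBRATION
        assert part.assignment["nowhere"] is Bucket.UNMAPPED
        assert sum(part.counts().values()) == len(reads)

    def test_buckets_disjoint_and_exhaustive(self, small_genomes, small_experiment):
        exp, cal = small_genomes
        ip, _, _ = small_experiment
        sample = ip[:400]
        part = partition_reads(sample, cal, exp)
        assert set(part.assignment) == {r.id for r in sample}
        counts = part.counts()
        assert sum(counts.values()) == len(sample)
        assert len(part.alignments_cal) == counts[Bucket.CALIBRATION]
        assert len(part.alignments_exp) == counts[Bucket.EXPERIMENTAL]

    def test_growing_calibration_genome_is_monotone(self, toy_genome, rng):
        """Adding calibration sequence can only pull reads into CALIBRATION."""
        reads = random_reads(rng, 60, min_len=40, max_len=40)
        reads += [mk_read(toy_genome.sequence("exp1")[i : i + 40], f"g{i}")
                  for i in range(0, 200, 20)]
        small_cal = Genome("cal", (("cal1", "TGCA" * 100),))
        big_cal = Genome(
            "cal", (("cal1", "TGCA" * 100), ("cal2", toy_genome.sequence("exp1")[:200]))
        )
        before = partition_reads(reads, small_cal, toy_genome).assignment
        after = partition_reads(reads, big_cal, toy_genome).assignment
        for rid, bucket in before.items():
            if bucket is Bucket.CALIBRATION:
                assert after[rid] is Bucket.CALIBRATION
            else:
                assert after[rid] in (bucket, Bucket.CALIBRATION)

    def test_duplicate_ids_rejected(self, toy_genome):
        cal = Genome("cal", (("cal1", "TGCA" * 50),))
        reads = [mk_read("ACGT" * 10, "dup"), mk_read("TTTT" * 10, "dup")]
        with pytest.raises(ValueError):
            partition_reads(reads, cal, toy_genome)

    def test_partition_from_alignments_prefers_calibration(self):
        cal_recs = [AlignmentRecord("a", True, "c1", 5, "+", 40),
                    AlignmentRecord("b", False)]
        exp_recs = [AlignmentRecord("a", True, "e1", 9, "+", 40),
                    AlignmentRecord("b", True, "e1", 70, "-", 40)]
        part = partition_from_alignments(cal_recs, exp_recs)
        assert part.assignment["a"] is Bucket.CALIBRATION
        assert part.assignment["b"] is Bucket.EXPERIMENTAL


SAM_FIXTURE = """\
@HD\tVN:1.6\tSO:unknown
@SQ\tSN:chrA\tLN:1000
r1\t0\tchrA\t101\t60\t40M\t*\t0\t0\t{seq}\t{qual}
r2\t16\tchrA\t201\t60\t40M\t*\t0\t0\t{seq}\t{qual}
r3\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual}
r4\t256\tchrA\t301\t60\t40M\t*\t0\t0\t*\t*
r5\t2048\tchrA\t401\t60\t40M\t*\t0\t0\t{seq}\t{qual}
""".format(seq="A" * 40, qual="I" * 40)


class TestReadSam:
    def test_five_record_fixture_round_trips_hand_parse(self, tmp_path):
        path = tmp_path / "mini.sam"
        path.write_text(SAM_FIXTURE)
        records = read_sam(path)
        # secondary (r4) and supplementary (r5) are dropped
        assert [r.read_id for r in records] == ["r1", "r2", "r3"]
        assert records[0] == AlignmentRecord("r1", True, "chrA", 100, "+", 40)
        assert records[1] == AlignmentRecord("r2", True, "chrA", 200, "-", 40)
        assert records[2] == AlignmentRecord("r3", False)

    def test_one_based_pos_becomes_zero_based(self, tmp_path):
        path = tmp_path / "one.sam"
        path.write_text(
            "@SQ\tSN:c\tLN:500\n"
            "x\t0\tc\t101\t60\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII\n"
        )
        (rec,) = read_sam(path)
        assert rec.pos == 100

    def test_genome_validation(self, tmp_path):
        path = tmp_path / "bad_chrom.sam"
        path.write_text(
            "@SQ\tSN:unknown\tLN:500\n"
            "x\t0\tunknown\t10\t60\t4M\t*\t0\t0\tACGT\tIIII\n"
        )
        genome = Genome("g", (("c", "ACGT" * 100),))
        with pytest.raises(SamParseError):
            read_sam(path, genome)

    def test_malformed_sam_raises_parse_error(self, tmp_path):
        path = tmp_path / "broken.sam"
        path.write_text("@SQ\tSN:c\tLN:500\nnot a sam record at all\n")
        with pytest.raises(SamParseError):
            read_sam(path)
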