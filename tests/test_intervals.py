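import numpy as np
import pytest

from g4shift.intervals import (
    BedParseError,
    GenomeDef,
    GenomicInterval,
    IntervalSet,
    ValidationError,
    consensus,
    distance_counts,
    merge_overlapping,
    read_bed,
    read_chrom_sizes,
    shuffle,
    subtract_within,
    window_overlap,
    write_bed,
)

import oracles


class TestBedIO:
    def test_reads_sorted(self, tmp_path, toy_genome):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t5\t10\nchr1\t2\t4\n")
        iset, skipped = read_bed(str(p), toy_genome)
        assert skipped == 0
        assert [(iv.start, iv.end) for iv in iset] == [(2, 4), (5, 10)]

    def test_zero_width_rejected(self, tmp_path, toy_genome):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t10\t10\n")
        with pytest.raises(BedParseError, match=r"bad\.bed:1.*zero"):
            read_bed(str(p), toy_genome)

    def test_unknown_chrom_lenient_vs_strict(self, tmp_path, toy_genome):
        p = tmp_path / "c.bed"
        p.write_text("chrUnknown\t1\t2\nchr1\t1\t2\n")
        iset, skipped = read_bed(str(p), toy_genome, strict=False)
        assert skipped == 1 and len(iset) == 1
        with pytest.raises(ValidationError):
            read_bed(str(p), toy_genome, strict=True)

    def test_roundtrip(self, tmp_path, toy_genome, make_set):
        s = make_set(("chr1", 2, 4, "+"), ("chr2", 5, 10, "-"))
        out = tmp_path / "o.bed"
        write_bed(s, str(out), header_lines=["test"])
        back, _ = read_bed(str(out), toy_genome)
        assert [(i.chrom, i.start, i.end, i.strand) for i in back] == [
            ("chr1", 2, 4, "+"),
            ("chr2", 5, 10, "-"),
        ]

    def test_chrom_sizes(self, tmp_path):
        p = tmp_path / "g.sizes"
        p.write_text("chr1\t1000\nchr2\t500\n")
        g = read_chrom_sizes(str(p))
        assert g.lengths == {"chr1": 1000, "chr2": 500}


class TestWindowOverlap:
    def test_boundary_inclusion(self, make_set):
        q = make_set(("chr1", 100, 101))
        hit = make_set(("chr1", 105, 110), role="features")
        miss = make_set(("chr1", 106, 110), role="features")
        assert len(window_overlap(q, hit, 5)) == 1  # [95,106) touches base 105
        assert len(window_overlap(q, miss, 5)) == 0  # [95,106) disjoint from [106,...)

    def test_w0_identity(self, make_set):
        q = make_set(("chr1", 10, 20))
        assert len(window_overlap(q, q.with_role("features"), 0)) == 1

    def test_partition_with_subtract(self, make_set):
        q = make_set(*[("chr1", i * 10, i * 10 + 1) for i in range(10)])
        f = make_set(("chr1", 25, 40), role="features")
        for w in (0, 3, 10):
            inside = window_overlap(q, f, w)
            outside = subtract_within(q, f, w)
            assert len(inside) + len(outside) == len(q)
            merged = sorted(
                [(i.chrom, i.start) for i in inside] + [(i.chrom, i.start) for i in outside]
            )
            assert merged == sorted((i.chrom, i.start) for i in q)

    def test_empty_features_identity(self, make_set, toy_genome):
        q = make_set(("chr1", 10, 11))
        empty = IntervalSet((), toy_genome, "features")
        assert len(window_overlap(q, empty, 5)) == 0
        assert list(subtract_within(q, empty, 5)) == list(q)

    def test_duplicates_counted_individually(self, make_set):
        q = make_set(("chr1", 10, 11), ("chr1", 10, 11))
        f = make_set(("chr1", 10, 11), role="features")
        assert len(window_overlap(q, f, 0)) == 2

    def test_monotone_in_w(self, toy_genome):
        rng = np.random.default_rng(0)
        q = oracles.random_interval_set(rng, toy_genome, n_max=50)
        f = oracles.random_interval_set(rng, toy_genome, n_max=20, role="features")
        counts = [len(window_overlap(q, f, w)) for w in (0, 1, 2, 5, 10, 50)]
        assert counts == sorted(counts)


class TestMergeConsensus:
    @pytest.mark.parametrize(
        "triples,gap,expected",
        [
            ([("chr1", 2, 5), ("chr1", 4, 8)], 0, [(2, 8)]),
            ([("chr1", 2, 5), ("chr1", 5, 8)], 0, [(2, 8)]),  # book-ended fuse
            ([("chr1", 2, 5), ("chr1", 6, 8)], 1, [(2, 8)]),  # distance 1 <= gap
            ([("chr1", 2, 5), ("chr1", 7, 8)], 1, [(2, 5), (7, 8)]),  # distance 2 > gap
            ([("chr1", 2, 5), ("chr1", 7, 8)], 0, [(2, 5), (7, 8)]),
        ],
    )
    def test_merge_examples(self, make_set, triples, gap, expected):
        merged = merge_overlapping(make_set(*triples), gap=gap)
        assert [(i.start, i.end) for i in merged] == expected

    def test_consensus_example(self, make_set):
        sets = [make_set(("chr1", 0, 10)), make_set(("chr1", 5, 15)), make_set(("chr1", 20, 30))]
        cons = consensus(sets, 2)
        assert [(i.start, i.end) for i in cons] == [(5, 10)]

    def test_consensus_degenerate_cases(self, make_set):
        sets = [make_set(("chr1", 0, 10), ("chr1", 9, 15)), make_set(("chr1", 30, 40))]
        k1 = consensus(sets, 1)
        union = merge_overlapping(
            IntervalSet([iv for s in sets for iv in s], sets[0].genome), gap=-1
        )
        assert list(k1) == list(union)
        same = [make_set(("chr1", 3, 7)), make_set(("chr1", 3, 7))]
        assert [(i.start, i.end) for i in consensus(same, 2)] == [(3, 7)]

    def test_consensus_k_out_of_range(self, make_set):
        with pytest.raises(ValidationError):
            consensus([make_set(("chr1", 0, 5))], 2)


class TestShuffle:
    def test_conservation_and_determinism(self, toy_genome):
        rng = np.random.default_rng(1)
        s = oracles.random_interval_set(rng, toy_genome, n_max=100)
        a = shuffle(s, toy_genome, seed=42)
        b = shuffle(s, toy_genome, seed=42)
        c = shuffle(s, toy_genome, seed=43)
        assert len(a) == len(s)
        assert sorted(a.widths().tolist()) == sorted(s.widths().tolist())
        assert list(a) == list(b)
        assert list(a) != list(c)

    def test_exclusion_avoided(self, toy_genome, make_set):
        s = make_set(*[("chr1", i, i + 1) for i in range(50)])
        exclude = make_set(("chr1", 0, 900), ("chr2", 0, 400), role="exclusion")
        out = shuffle(s, toy_genome, exclude, seed=5)
        assert len(window_overlap(out, exclude, 0)) == 0

    def test_infeasible_placement_errors(self, make_set):
        genome = GenomeDef.from_pairs([("chr1", 1000)])
        s = IntervalSet([GenomicInterval("chr1", 5, 6)], genome)
        exclude = IntervalSet([GenomicInterval("chr1", 0, 1000)], genome, "exclusion")
        with pytest.raises(ValidationError, match="placement"):
            shuffle(s, genome, exclude, seed=1, preserve_chrom=True, max_tries=50)

    def test_uniform_mean_position(self):
        genome = GenomeDef.from_pairs([("chrU", 1000)])
        s = IntervalSet([GenomicInterval("chrU", 0, 1)], genome)
        positions = [list(shuffle(s, genome, seed=k))[0].start for k in range(200)]
        se = 1000 / np.sqrt(12 * 200)  # SE of the mean of U(0,1000)
        assert abs(np.mean(positions) - 499.5) < 3 * se

    def test_chromosome_choice_proportional_to_length(self, toy_genome):
        s = IntervalSet([GenomicInterval("chr1", 0, 1)], toy_genome)
        chroms = [list(shuffle(s, toy_genome, seed=k))[0].chrom for k in range(300)]
        frac_chr1 = np.mean([c == "chr1" for c in chroms])
        se = np.sqrt((2 / 3) * (1 / 3) / 300)
        assert abs(frac_chr1 - 2 / 3) < 3 * se


class TestDistanceCounts:
    def test_planted_inside(self, make_set):
        f = make_set(("chr1", 100, 200), role="features")
        q = make_set(*[("chr1", 100 + i, 101 + i) for i in range(10)])
        counts = distance_counts(q, f, list(range(0, 51, 5)))
        assert counts[0] == 10 and counts[1:].sum() == 0

    def test_event_at_known_distance(self, make_set):
        f = make_set(("chr1", 200, 210), role="features")
        q = make_set(("chr1", 192, 193))  # nearest distance 7 bp
        counts = distance_counts(q, f, [0, 5, 10])
        assert counts.tolist() == [0, 0, 1]

    def test_empty_features(self, make_set, toy_genome):
        q = make_set(("chr1", 10, 11))
        counts = distance_counts(q, IntervalSet((), toy_genome, "features"), [0, 5])
        assert counts.sum() == 0

    def test_non_ascending_edges_rejected(self, make_set):
        q = make_set(("chr1", 10, 11))
        with pytest.raises(ValidationError):
            distance_counts(q, q, [5, 5, 10])

    def test_bins_sum_to_outermost_window(self, toy_genome):
        rng = np.random.default_rng(3)
        q = oracles.random_interval_set(rng, toy_genome, n_max=80)
        f = oracles.random_interval_set(rng, toy_genome, n_max=20, role="features")
        edges = [0, 3, 9, 20]
        counts = distance_counts(q, f, edges)
        assert counts.sum() == len(window_overlap(q, f, edges[-1]))


def test_interval_invariants():
    with pytest.raises(ValidationError):
        GenomicInterval("chr1", 10, 10)
    with pytest.raises(ValidationError):
        GenomicInterval("chr1", -1, 5)
    genome = GenomeDef.from_pairs([("chr1", 100)])
    with pytest.raises(ValidationError):
        IntervalSet([GenomicInterval("chr1", 90, 120)], genome)
    with pytest.raises(ValidationError):
        GenomeDef.from_pairs([("chr1", 100), ("chr1", 200)])
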