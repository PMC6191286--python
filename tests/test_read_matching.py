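"""Exact placement, cluster merging, and length-distribution behaviour."""

import random

import numpy as np
import pytest

from riscfrag.read_matching import (
    AlignmentRecord,
    cluster_alignments,
    compare_fractions,
    length_distribution,
    match_reads_to_orf,
)

from conftest import make_read


def brute_force_placements(read, orf):
    """Independent all-offsets scan for exact sense-strand matches."""
    return [
        i
        for i in range(len(orf) - len(read) + 1)
        if orf[i : i + len(read)] == read
    ]


def brute_force_merge(intervals, gap):
    """Transitive-closure interval merging, O(n^2)."""
    groups = [[iv] for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if any(
                    a[0] <= b[1] + gap and b[0] <= a[1] + gap
                    for a in groups[i]
                    for b in groups[j]
                ):
                    groups[i] += groups.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted(
        (min(s for s, _ in g), max(e for _, e in g)) for g in groups
    )


class TestMatchReadsToOrf:
    ORF = "ATGGCTAAACGGTTTCCCAAGGGTTTACCCGATCGATCGTAGCTAGCTAACGTT"

    def test_prefix_read_placed_at_origin(self):
        aln = match_reads_to_orf([make_read(self.ORF[:20])], self.ORF, min_len=19)
        assert len(aln) == 1
        assert (aln[0].start, aln[0].end) == (0, 20)

    def test_single_mismatch_yields_no_record(self):
        read = self.ORF[5:25]
        mutated = read[:10] + ("A" if read[10] != "A" else "C") + read[11:]
        assert match_reads_to_orf([make_read(mutated)], self.ORF) == []

    def test_short_perfect_match_excluded_by_min_len(self):
        read = make_read(self.ORF[3:20])  # 17 nt, perfect match
        assert match_reads_to_orf([read], self.ORF, min_len=19) == []
        assert len(match_reads_to_orf([read], self.ORF, min_len=15)) == 1

    def test_reads_with_n_excluded(self):
        read = make_read(self.ORF[:19] + "N")
        assert match_reads_to_orf([read], self.ORF + "N", min_len=15) == []

    def test_empty_orf_rejected(self):
        with pytest.raises(ValueError):
            match_reads_to_orf([make_read("ACGTACGTACGTACGTACGT")], "")

    def test_multi_placement_read_reported_per_placement(self):
        unit = "ACGTTGCAACGTGGCCTTAA"
        orf = unit + "T" * 5 + unit
        aln = match_reads_to_orf([make_read(unit)], orf, min_len=19)
        assert len(aln) == 2
        assert all(a.n_placements_on_target == 2 for a in aln)
        assert [a.start for a in aln] == [0, 25]

    def test_matches_brute_force_oracle(self):
        rng = random.Random(17)
        for _ in range(120):
            orf = "".join(rng.choices("ACGT", k=rng.randint(30, 80)))
            reads = []
            for _ in range(rng.randint(1, 8)):
                if rng.random() < 0.6 and len(orf) > 22:
                    i = rng.randrange(len(orf) - 20)
                    reads.append(make_read(orf[i : i + rng.randint(15, 20)]))
                else:
                    reads.append(
                        make_read("".join(rng.choices("ACGT", k=rng.randint(15, 22))))
                    )
            min_len = rng.choice([15, 17, 19])
            got = match_reads_to_orf(reads, orf, min_len=min_len)
            expected = []
            for read in reads:
                if len(read) < min_len or "N" in read.sequence:
                    continue
                expected += [
                    (read.sequence, i, i + len(read))
                    for i in brute_force_placements(read.sequence, orf)
                ]
            assert [(a.read.sequence, a.start, a.end) for a in got] == expected

    def test_substring_invariant(self, small_transcriptome, small_config,
                                 viability_table):
        from riscfrag.synthetic_data import simulate_reads

        reads, _ = simulate_reads(
            small_config, small_transcriptome, "ago", viability_table
        )
        t1 = small_transcriptome["t1"]
        for aln in match_reads_to_orf(reads, t1, min_len=15):
            assert t1.sequence[aln.start : aln.end] == aln.read.sequence


def _alignments_from_intervals(intervals):
    return [
        AlignmentRecord(make_read("A" * (e - s)), "t1", s, e)
        for s, e in intervals
    ]


class TestClusterAlignments:
    def test_overlap_merges(self):
        regions = cluster_alignments(_alignments_from_intervals([(0, 20), (10, 30)]))
        assert [(r.start, r.end) for r in regions] == [(0, 30)]
        assert regions[0].n_reads == 2

    def test_disjoint_stay_separate(self):
        regions = cluster_alignments(_alignments_from_intervals([(0, 20), (25, 45)]))
        assert [(r.start, r.end) for r in regions] == [(0, 20), (25, 45)]

    def test_abutment_merges_at_gap_zero(self):
        regions = cluster_alignments(_alignments_from_intervals([(0, 20), (20, 40)]))
        assert [(r.start, r.end) for r in regions] == [(0, 40)]

    def test_gap_parameter_bridges_short_gaps(self):
        intervals = [(0, 20), (25, 45)]
        assert len(cluster_alignments(_alignments_from_intervals(intervals), gap=5)) == 1
        assert len(cluster_alignments(_alignments_from_intervals(intervals), gap=4)) == 2

    def test_matches_transitive_closure_oracle(self):
        rng = random.Random(3)
        for _ in range(120):
            intervals = [
                (s, s + rng.randint(15, 30))
                for s in (rng.randrange(0, 200) for _ in range(rng.randint(1, 12)))
            ]
            gap = rng.choice([0, 0, 3, 10])
            got = cluster_alignments(_alignments_from_intervals(intervals), gap=gap)
            assert [(r.start, r.end) for r in got] == brute_force_merge(intervals, gap)
            assert sum(r.n_reads for r in got) == len(intervals)

    def test_independent_of_input_order(self):
        intervals = [(0, 20), (18, 40), (60, 80), (75, 95), (200, 220)]
        rng = random.Random(5)
        reference = cluster_alignments(_alignments_from_intervals(intervals))
        for _ in range(10):
            shuffled = intervals[:]
            rng.shuffle(shuffled)
            got = cluster_alignments(_alignments_from_intervals(shuffled))
            assert [(r.start, r.end, r.n_reads) for r in got] == [
                (r.start, r.end, r.n_reads) for r in reference
            ]

    def test_idempotent_on_region_boundaries(self):
        intervals = [(0, 20), (18, 40), (60, 80), (75, 95)]
        regions = cluster_alignments(_alignments_from_intervals(intervals))
        again = cluster_alignments(
            _alignments_from_intervals([(r.start, r.end) for r in regions])
        )
        assert [(r.start, r.end) for r in again] == [
            (r.start, r.end) for r in regions
        ]


class TestLengthDistribution:
    def test_uniform_lengths(self):
        reads = [make_read("A" * 20) for _ in range(3)]
        dist = length_distribution(reads)
        assert dist.peak_length == 20
        assert dist.mean_length == 20.0

    def test_peak_tie_breaks_shorter(self):
        reads = [make_read("A" * 20, count=5), make_read("C" * 23, count=5)]
        assert length_distribution(reads).peak_length == 20

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            length_distribution([])

    def test_rpm_weights_sum_to_million(self):
        reads = [make_read("A" * 20, count=3), make_read("C" * 22, count=7)]
        dist = length_distribution(reads, weight_mode="rpm")
        assert sum(dist.histogram.values()) == pytest.approx(1e6)

    def test_count_weighted_mean(self):
        reads = [make_read("A" * 20, count=1), make_read("C" * 30, count=3)]
        assert length_distribution(reads).mean_length == pytest.approx(27.5)

    def test_per_replicate_weighting(self):
        from riscfrag.io_formats import SmallRead

        reads = [
            SmallRead("A" * 20, {"rep1": 10, "rep2": 0}),
            SmallRead("C" * 30, {"rep1": 0, "rep2": 10}),
        ]
        assert length_distribution(reads, replicate="rep1").peak_length == 20
        assert length_distribution(reads, replicate="rep2").peak_length == 30


class TestCompareFractions:
    def test_identical_distributions_are_null(self):
        reads = [make_read("A" * 20, count=5), make_read("C" * 23, count=3)]
        dist = length_distribution(reads)
        report = compare_fractions(dist, dist)
        assert report.mean_difference == 0.0
        assert report.peak_difference == 0
        assert report.ks_statistic == 0.0

    def test_simulated_shift_is_negative(self, viability_table):
        from riscfrag.synthetic_data import SimulationConfig, generate_transcriptome, simulate_reads

        cfg = SimulationConfig(seed=2, n_transcripts=2,
                               transcript_length_range=(400, 600),
                               reads_per_cluster=200, mirna_fraction=0.1)
        ts = generate_transcriptome(cfg)
        ago, _ = simulate_reads(cfg, ts, "ago", viability_table)
        total, _ = simulate_reads(cfg, ts, "total", viability_table)
        report = compare_fractions(
            length_distribution(ago), length_distribution(total)
        )
        assert report.mean_difference < 0

    def test_ks_matches_ecdf_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            h1 = {int(k): float(v) for k, v in
                  zip(rng.integers(15, 35, 6), rng.integers(1, 50, 6))}
            h2 = {int(k): float(v) for k, v in
                  zip(rng.integers(15, 35, 6), rng.integers(1, 50, 6))}
            d1 = length_distribution(
                [make_read("A" * k, count=int(v)) for k, v in h1.items()]
            )
            d2 = length_distribution(
                [make_read("A" * k, count=int(v)) for k, v in h2.items()]
            )
            got = compare_fractions(d1, d2).ks_statistic

            # brute-force sup-difference of the two weighted ECDFs
            support = sorted(set(d1.histogram) | set(d2.histogram))
            t1 = sum(d1.histogram.values())
            t2 = sum(d2.histogram.values())
            sup = max(
                abs(
                    sum(w for k, w in d1.histogram.items() if k <= x) / t1
                    - sum(w for k, w in d2.histogram.items() if k <= x) / t2
                )
                for x in support
            )
            assert got == pytest.approx(sup)
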