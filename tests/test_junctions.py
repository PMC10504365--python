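import random

import pytest
from hypothesis import given, settings, strategies as st

from circbact.junctions import (
    cluster_junctions,
    filter_candidates,
    junction_fractions,
    tabulate_timecourse,
)
from circbact.splitread import PermutedReadEvidence


def ev(read_id, acceptor, donor, strand="+", unique=True, sample=None):
    return PermutedReadEvidence(
        read_id=read_id,
        acceptor_5p=acceptor,
        donor_3p=donor,
        strand=strand,
        left_anchor=20,
        right_anchor=20,
        mismatches_total=0,
        unique_placement=unique,
        sample=sample,
    )


def _shifted_set():
    """7 observations: 5x (1000,1199), 1x (1001,1199), 1x (1000,1201)."""
    records = [ev(f"a{i}", 1000, 1199) for i in range(5)]
    records.append(ev("b0", 1001, 1199))
    records.append(ev("c0", 1000, 1201))
    return records


class TestClusterJunctions:
    def test_members_within_shift_collapse_to_one(self):
        clusters = cluster_junctions(_shifted_set(), shift=3)
        assert len(clusters) == 1
        (c,) = clusters
        assert c.read_count == 7
        assert (c.rep_acceptor_5p, c.rep_donor_3p) == (1000, 1199)

    def test_ten_nt_apart_stays_separate(self):
        records = [ev("a", 1000, 1199), ev("b", 1010, 1199)]
        assert len(cluster_junctions(records, shift=3)) == 2

    def test_empty_evidence(self):
        assert cluster_junctions([]) == []

    def test_strands_never_merge(self):
        records = [ev("a", 1000, 1199, "+"), ev("b", 1000, 1199, "-")]
        assert len(cluster_junctions(records)) == 2

    def test_conserves_evidence_and_order_invariant(self):
        records = _shifted_set() + [ev("d", 5000, 5400), ev("e", 5002, 5401)]
        expected = cluster_junctions(records)
        rnd = random.Random(42)
        for _ in range(10):
            shuffled = records[:]
            rnd.shuffle(shuffled)
            got = cluster_junctions(shuffled)
            assert sum(c.read_count for c in got) == len(records)
            assert [
                (c.rep_acceptor_5p, c.rep_donor_3p, c.read_count) for c in got
            ] == [
                (c.rep_acceptor_5p, c.rep_donor_3p, c.read_count) for c in expected
            ]

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(100, 400), st.integers(0, 500)),
            min_size=0, max_size=30,
        )
    )
    def test_count_conservation_property(self, pairs):
        records = [
            ev(f"r{i}", a, a + 60 + d) for i, (a, d) in enumerate(pairs)
        ]
        clusters = cluster_junctions(records)
        assert sum(c.read_count for c in clusters) == len(records)
        for c in clusters:
            assert sum(c.samples.values()) == c.read_count


class TestFilterCandidates:
    def test_five_reads_retained(self):
        clusters = cluster_junctions([ev(f"r{i}", 1000, 1199) for i in range(5)])
        kept, rejected = filter_candidates(clusters, min_reads=5)
        assert len(kept) == 1 and rejected == []
        assert kept[0].total_reads == 5 and kept[0].span == 200

    def test_four_reads_rejected_with_reason(self):
        clusters = cluster_junctions([ev(f"r{i}", 1000, 1199) for i in range(4)])
        kept, rejected = filter_candidates(clusters, min_reads=5)
        assert kept == []
        assert rejected[0].reason == "min_reads"

    def test_wide_span_rejected(self):
        clusters = cluster_junctions([ev(f"r{i}", 1000, 2199) for i in range(6)])
        kept, rejected = filter_candidates(clusters, max_span=1000)
        assert kept == []
        assert rejected[0].reason == "max_span"

    def test_non_unique_rejected_only_when_required(self):
        clusters = cluster_junctions(
            [ev(f"r{i}", 1000, 1199, unique=False) for i in range(6)]
        )
        kept, rejected = filter_candidates(clusters, require_unique=True)
        assert kept == [] and rejected[0].reason == "non_unique"
        kept, _ = filter_candidates(clusters, require_unique=False)
        assert len(kept) == 1

    def test_isoforms_grouped_into_one_locus(self):
        records = [ev(f"r{i}", 1000, 1199) for i in range(5)]
        records += [ev(f"s{i}", 1035, 1199) for i in range(3)]
        kept, _ = filter_candidates(cluster_junctions(records))
        assert len(kept) == 1
        assert len(kept[0].isoforms) == 2
        assert kept[0].total_reads == 8

    def test_monotone_in_min_reads(self):
        records = []
        rnd = random.Random(1)
        for locus in range(6):
            base = 1000 + locus * 2000
            for i in range(rnd.randint(1, 12)):
                records.append(ev(f"l{locus}_{i}", base, base + 300))
        clusters = cluster_junctions(records)
        previous = None
        for threshold in range(1, 15):
            kept, _ = filter_candidates(clusters, min_reads=threshold)
            ids = {c.locus_id for c in kept}
            if previous is not None:
                assert ids <= previous
            previous = ids


class TestJunctionFractions:
    def test_ten_percent(self):
        clusters = cluster_junctions([ev(f"r{i}", 1000, 1199) for i in range(10)])
        fractions = junction_fractions(clusters, total_permuted=10,
                                       total_locus_reads=100)
        assert fractions["1000-1199"] == pytest.approx(10.0)

    def test_no_permuted_reads_all_zero(self):
        fractions = junction_fractions([], total_permuted=0, total_locus_reads=50)
        assert fractions["other_junctions"] == 0.0
        assert fractions["colinear"] == pytest.approx(100.0)

    def test_zero_total_reported_missing(self):
        assert junction_fractions([], 0, 0) is None

    def test_fractions_sum_to_hundred(self):
        clusters = cluster_junctions(
            [ev(f"r{i}", 1000, 1199) for i in range(7)]
            + [ev(f"s{i}", 1035, 1199) for i in range(2)]
        )
        fractions = junction_fractions(clusters, total_permuted=12,
                                       total_locus_reads=80)
        assert fractions.sum() == pytest.approx(100.0)


class TestTabulateTimecourse:
    def test_single_sample_single_row(self):
        records = [ev(f"r{i}", 1000, 1199, sample="s1") for i in range(6)]
        table = tabulate_timecourse(records, ["s1"])
        assert list(table.index) == ["s1"]
        assert table.loc["s1", "n_candidates"] == 1

    def test_empty_evidence_row_of_zeros(self):
        table = tabulate_timecourse([], ["s1", "s2"])
        assert list(table["n_candidates"]) == [0, 0]

    def test_unknown_sample_rejected(self):
        records = [ev("r", 1000, 1199, sample="sX")]
        with pytest.raises(ValueError):
            tabulate_timecourse(records, ["s1"])

    def test_per_locus_counts_split_by_sample(self):
        records = [ev(f"r{i}", 1000, 1199, sample="s1") for i in range(2)]
        records += [ev(f"q{i}", 1000, 1199, sample="s2") for i in range(8)]
        table = tabulate_timecourse(records, ["s1", "s2"])
        assert table.loc["s1", "locus_1000_1199"] == 2
        assert table.loc["s2", "locus_1000_1199"] == 8
        assert table.loc["s1", "n_candidates"] == 0  # below threshold in s1
        assert table.loc["s2", "n_candidates"] == 1
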