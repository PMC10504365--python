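import numpy as np
import pytest

from circbact.genome_io import ReferenceSequence, SequenceRead, reverse_complement
from circbact.simulate import SimConfig, simulate
from circbact.splitread import (
    GenomeIndex,
    align_full,
    call_backsplice,
    canonicalize_evidence,
    canonicalize_junction,
    detect_backsplices,
    enumerate_backsplices,
    seed_segments,
)

import oracles


def _genome(rng, n=2000, name="g"):
    return ReferenceSequence(name, "".join(rng.choice(list("ACGT"), size=n)))


class TestAlignFull:
    def test_exact_copy_recovers_placement(self, rng):
        genome = _genome(rng)
        read = SequenceRead("r", genome.bases[500:580])
        hit = align_full(read, genome, budget=2)
        assert (hit.genome_start, hit.genome_end, hit.strand, hit.mismatches) == (
            501, 580, "+", 0
        )

    def test_reverse_strand_copy(self, rng):
        genome = _genome(rng)
        read = SequenceRead("r", reverse_complement(genome.bases[500:580]))
        hit = align_full(read, genome, budget=2)
        assert (hit.genome_start, hit.strand) == (501, "-")

    def test_junction_read_is_unplaceable(self, rng):
        genome = _genome(rng)
        circle = genome.bases[1000:1200]
        read = SequenceRead("r", circle[-40:] + circle[:40])
        assert align_full(read, genome, budget=4) is None

    def test_matches_exhaustive_search_with_mismatches(self, rng):
        genome = _genome(rng, 3000)
        for trial in range(30):
            start = int(rng.integers(0, 2900))
            seq = list(genome.bases[start : start + 70])
            for p in rng.choice(70, size=int(rng.integers(0, 4)), replace=False):
                seq[p] = "ACGT"[int(rng.integers(4))]
            if rng.random() < 0.5:
                seq = list(reverse_complement("".join(seq)))
            read = SequenceRead(f"t{trial}", "".join(seq))
            got = align_full(read, genome, budget=2)
            expected = oracles.best_colinear(read.bases, genome.bases, budget=2)
            if expected is None:
                assert got is None
            else:
                mm, strand_i, off = expected
                assert got is not None
                assert (got.mismatches, got.strand, got.genome_start) == (
                    mm, "+-"[strand_i], off + 1
                )


class TestSeedSegments:
    def test_colinear_read_single_covering_segment(self, rng):
        genome = _genome(rng)
        index = GenomeIndex(genome, k=15)
        read = SequenceRead("r", genome.bases[300:380])
        segs = [s for s in seed_segments(read, index, 0) if s.strand == "+"]
        assert any(s.read_start == 0 and s.read_end == 80 for s in segs)

    def test_junction_read_two_segments(self, rng):
        genome = _genome(rng)
        index = GenomeIndex(genome, k=15)
        circle = genome.bases[1000:1200]
        read = SequenceRead("r", circle[-40:] + circle[:40])
        segs = [s for s in seed_segments(read, index, 0) if s.strand == "+"]
        assert any(s.read_start == 0 and s.read_end >= 40 for s in segs)
        assert any(s.read_end == 80 and s.read_start <= 40 for s in segs)

    def test_foreign_read_no_segments(self, rng):
        genome = ReferenceSequence("g", "AC" * 1000)
        index = GenomeIndex(genome, k=15)
        read = SequenceRead("r", "G" * 60)
        assert seed_segments(read, index, 2) == []


class TestCallBacksplice:
    def test_junction_geometry(self, rng):
        # read = circle tail + circle head => acceptor at start, donor at end
        genome = _genome(rng)
        index = GenomeIndex(genome, k=15)
        circle = genome.bases[999:1199]  # 1-based [1000, 1199]
        read = SequenceRead("r", circle[-20:] + circle[:20])
        segs = seed_segments(read, index, 0)
        ev = call_backsplice(read, segs, genome, max_span=1000, min_anchor=15)
        assert ev is not None
        ca, cd = canonicalize_junction(1000, 1199, genome.bases)
        assert (ev.acceptor_5p, ev.donor_3p, ev.strand) == (ca, cd, "+")
        assert ev.left_anchor + ev.right_anchor == 40

    def test_colinear_read_yields_nothing(self, rng):
        genome = _genome(rng)
        index = GenomeIndex(genome, k=15)
        read = SequenceRead("r", genome.bases[100:180])
        segs = seed_segments(read, index, 0)
        assert call_backsplice(read, segs, genome) is None

    def test_span_bound_excludes_distant_chimeras(self, rng):
        genome = _genome(rng, 4000)
        index = GenomeIndex(genome, k=15)
        read = SequenceRead("r", genome.bases[3000:3040] + genome.bases[100:140])
        segs = seed_segments(read, index, 0)
        assert call_backsplice(read, segs, genome, max_span=1000) is None
        ev = call_backsplice(read, segs, genome, max_span=4000)
        assert ev is not None and ev.span > 1000


class TestCanonicalize:
    def test_no_homology_unchanged(self):
        bases = "AAAATTTTCCCCGGGGAAAATTTTCCCCGGGG"
        # donor base G (pos 16), base before acceptor (pos 19) is A: no slide
        a, d = canonicalize_junction(20, 16 + 0, bases)  # arbitrary valid pair
        assert (a, d) == (20, 16)

    def test_homology_shifts_left_and_preserves_length(self, rng):
        bases = list(_genome(rng, 400).bases)
        # make 2 nt of flanking homology around junction (101, 250):
        bases[98] = bases[248]  # pos 99  == donor-1 base (pos 249)
        bases[99] = bases[249]  # pos 100 == donor base (pos 250)
        bases[97] = "A" if bases[247] != "A" else "C"  # stop at 2
        bases = "".join(bases)
        a, d = canonicalize_junction(101, 250, bases)
        assert (a, d) == (99, 248)
        assert d - a + 1 == 150

    def test_idempotent(self, rng):
        bases = _genome(rng, 500).bases
        for _ in range(20):
            a0 = int(rng.integers(5, 200))
            d0 = int(rng.integers(a0 + 50, 450))
            a1, d1 = canonicalize_junction(a0, d0, bases)
            assert canonicalize_junction(a1, d1, bases) == (a1, d1)


class TestOracleEquivalence:
    """Seeded detection (exact-anchor mode) vs exhaustive enumeration."""

    def test_seeded_equals_bruteforce_on_simulated_instances(self):
        mismatched = []
        for seed in range(12):
            config = SimConfig(
                genome_length=2_000,
                n_linear_loci=1,
                n_circ_loci=1,
                linear_size_range=(150, 250),
                circ_size_range=(120, 200),
                n_samples=1,
                read_length=80,
                fragment_length_mean=120.0,
                fragment_length_sd=15.0,
                coverage_per_sample=8,
                substitution_error_rate=0.0,
                min_gap=100,
                seed=1000 + seed,
            )
            sim_genome, truth, reads = simulate(config)
            genome = sim_genome.reference
            index = GenomeIndex(genome, k=15)
            for read in reads["s1"]:
                expected_colinear = oracles.best_colinear(
                    read.bases, genome.bases, budget=2
                )
                got_colinear = align_full(read, genome, budget=2)
                assert (got_colinear is None) == (expected_colinear is None)
                if got_colinear is not None:
                    continue
                segs = seed_segments(read, index, max_mismatch_per_segment=0)
                cands = enumerate_backsplices(
                    read, segs, genome, max_span=1000, min_anchor=15,
                    max_mismatch_per_segment=0,
                )
                got = {(e.strand, e.acceptor_5p, e.donor_3p) for e in cands}
                expected = oracles.brute_force_backsplices(
                    read.bases, genome.bases, max_span=1000, min_anchor=15,
                    per_side_budget=0,
                )
                if got != expected:
                    mismatched.append((seed, read.read_id, got, expected))
        assert mismatched == []


class TestDetectBacksplices:
    def test_no_evidence_from_colinear_reads(self, small_sim):
        config, sim_genome, truth, reads = small_sim
        result = detect_backsplices(sim_genome.reference, reads["s1"])
        colinear_ids = {c.read_id for c in result.colinear}
        evidence_ids = {e.read_id for e in result.evidence}
        assert not (colinear_ids & evidence_ids)
        for e in result.evidence:
            assert 2 * 15 <= e.span <= 1000

    def test_no_off_truth_junctions_error_free(self, small_sim):
        config, sim_genome, truth, reads = small_sim
        genome = sim_genome.reference
        result = detect_backsplices(genome, reads["s1"])
        truth_keys = {
            (j.strand,) + canonicalize_junction(j.acceptor_5p, j.donor_3p, genome.bases)
            for j in truth.junctions
        }
        got_keys = {(e.strand, e.acceptor_5p, e.donor_3p) for e in result.evidence}
        assert got_keys <= truth_keys

    def test_paired_mates_contribute_single_evidence(self, rng):
        genome = _genome(rng)
        circle = genome.bases[999:1199]
        junction_read = circle[-30:] + circle[:30]
        mate1 = SequenceRead("frag", junction_read, mate=1)
        mate2 = SequenceRead("frag", reverse_complement(junction_read), mate=2)
        result = detect_backsplices(genome, [mate1, mate2])
        assert len(result.evidence) == 1

    def test_strand_symmetry_of_evidence(self, rng):
        genome = _genome(rng)
        circle = genome.bases[999:1199]
        read_fwd = SequenceRead("a", circle[-25:] + circle[:25])
        read_rev = SequenceRead("b", reverse_complement(read_fwd.bases))
        result = detect_backsplices(genome, [read_fwd, read_rev])
        keys = {(e.acceptor_5p, e.donor_3p) for e in result.evidence}
        strands = {e.strand for e in result.evidence}
        assert len(keys) == 1 and strands == {"+", "-"}
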