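"""Guide enumeration, truncation and off-target search."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crispec.guides import (
    Guide,
    count_by_mismatch,
    enumerate_guides,
    find_offtargets,
    overlap_across_lengths,
    truncate_guide,
)
from crispec.sequence import hamming, revcomp
from crispec.simulate import make_genome, plant_site

from oracles import brute_force_offtargets

SPACER20 = "GTCACCTCCAATGACTAGGG"

dna = st.text(alphabet="ACGT", min_size=60, max_size=200)


def _guide(spacer=SPACER20, contig="seq"):
    return Guide(
        id="g", spacer=spacer, contig=contig, start=0, end=len(spacer) + 3, strand="+"
    )


class TestEnumerateGuides:
    def test_sequence_too_short_yields_nothing(self):
        assert enumerate_guides("ACGTACGTACGTACGTACGTGG", 20) == []  # 22 < 23

    def test_single_forward_guide_on_minimal_sequence(self):
        gs = enumerate_guides("ACGTACGTACGTACGTACGTAGG", 20)
        fwd = [g for g in gs if g.strand == "+"]
        assert len(fwd) == 1
        assert fwd[0].spacer == "ACGTACGTACGTACGTACGT"
        assert (fwd[0].start, fwd[0].end) == (0, 23)

    def test_shorter_spacers_fit_at_least_as_many_positions(self):
        seq = make_genome(2000, 0.5, seed=8)
        n20 = len(enumerate_guides(seq, 20))
        n17 = len(enumerate_guides(seq, 17))
        assert n17 >= n20

    def test_minus_strand_guides_match_revcomp_scan(self):
        seq = make_genome(300, 0.5, seed=4)
        minus = {(g.start, g.end) for g in enumerate_guides(seq, 20) if g.strand == "-"}
        # oracle: forward guides on the reverse complement, coordinates mapped
        n = len(seq)
        expected = {
            (n - g.end, n - g.start)
            for g in enumerate_guides(revcomp(seq), 20)
            if g.strand == "+"
        }
        assert minus == expected


class TestTruncateGuide:
    def test_trims_pam_distal_end(self):
        g = _guide("AAAAACCCCCGGGGGTTTTT")
        assert truncate_guide(g, 17).spacer == "AACCCCCGGGGGTTTTT"

    def test_preserves_seed_and_cut_site(self):
        g = _guide()
        t = truncate_guide(g, 17)
        assert t.spacer == g.spacer[-17:]
        assert t.spacer[-12:] == g.spacer[-12:]
        assert t.cut_site == g.cut_site

    def test_minus_strand_cut_site_preserved(self):
        g = Guide(id="g", spacer=SPACER20, contig="c", start=40, end=63, strand="-")
        assert truncate_guide(g, 18).cut_site == g.cut_site

    def test_rejects_non_truncation(self):
        g = _guide()
        with pytest.raises(ValueError):
            truncate_guide(g, 20)
        with pytest.raises(ValueError):
            truncate_guide(g, 16)


class TestFindOfftargets:
    def test_single_planted_perfect_copy(self):
        genome = make_genome(2000, 0.45, seed=6)
        genome, _ = plant_site(genome, SPACER20, "AGG", 0, 700)
        sites = find_offtargets(_guide(), genome, max_mm=0)
        assert len(sites) == 1
        assert sites[0].start == 700 and sites[0].n_mismatch == 0

    def test_mismatch_cutoff_and_bruteforce_agreement(self):
        genome = make_genome(5000, 0.45, seed=16)
        occupied = []
        rng = np.random.default_rng(1)
        for mm, pos in [(0, 500), (1, 1500), (2, 2500), (3, 3500)]:
            genome, _ = plant_site(genome, SPACER20, "TAG", mm, pos, rng=rng, occupied=occupied)
        sites = find_offtargets(_guide(), genome, max_mm=2)
        got = {(s.start, s.strand, s.n_mismatch) for s in sites}
        assert got == brute_force_offtargets(genome, SPACER20, 2)
        assert {s.start for s in sites} >= {500, 1500, 2500}
        assert 3500 not in {s.start for s in sites}

    def test_nrg_pam_accepts_nag_rejects_ncg(self):
        base = "T" * 30
        genome = base + SPACER20 + "TAG" + "T" * 30
        assert len(find_offtargets(_guide(), genome, max_mm=0)) == 1
        genome = base + SPACER20 + "TCG" + "T" * 30
        assert find_offtargets(_guide(), genome, max_mm=0) == []

    def test_mismatch_positions_numbered_from_pam(self):
        # mismatch in the leftmost (PAM-distal) spacer base -> position 20
        proto = "C" + SPACER20[1:]
        genome = "T" * 30 + proto + "AGG" + "T" * 30
        (site,) = find_offtargets(_guide(), genome, max_mm=1)
        assert site.mismatch_positions == (20,)
        assert site.seed_mismatches == 0
        # mismatch adjacent to the PAM -> position 1, inside the seed
        proto = SPACER20[:-1] + ("A" if SPACER20[-1] != "A" else "C")
        genome = "T" * 30 + proto + "AGG" + "T" * 30
        (site,) = find_offtargets(_guide(), genome, max_mm=1)
        assert site.mismatch_positions == (1,)
        assert site.seed_mismatches == 1

    def test_rejects_ambiguous_spacer(self):
        g = Guide(id="g", spacer="N" + SPACER20[1:], contig="c", start=0, end=23, strand="+")
        with pytest.raises(ValueError):
            find_offtargets(g, "ACGT" * 100)

    @given(dna)
    def test_strand_symmetry(self, seq):
        """Reverse-complementing the genome swaps strands, keeps mismatches."""
        sites = find_offtargets(_guide(), seq, max_mm=3)
        mirrored = find_offtargets(_guide(), revcomp(seq), max_mm=3)
        n = len(seq)
        remapped = {
            (n - s.end, "-" if s.strand == "+" else "+", s.n_mismatch) for s in mirrored
        }
        assert {(s.start, s.strand, s.n_mismatch) for s in sites} == remapped

    @given(dna)
    def test_truncation_never_increases_mismatches(self, seq):
        """At any locus the 17-nt suffix has <= the 20-nt spacer's mismatches."""
        full = find_offtargets(_guide(), seq, max_mm=5)
        for site in full:
            assert hamming(site.protospacer[-17:], SPACER20[-17:]) <= site.n_mismatch


class TestCountByMismatch:
    def test_empty_input_gives_zero_map(self):
        assert count_by_mismatch([]) == {m: 0 for m in range(6)}

    def test_recounts_planted_mismatch_classes(self):
        genome = make_genome(6000, 0.45, seed=21)
        rng = np.random.default_rng(2)
        occupied = []
        plan = [(0, 500)] + [(1, 1500), (1, 2200)] + [(2, 3000), (2, 3700), (2, 4400)]
        for mm, pos in plan:
            genome, _ = plant_site(genome, SPACER20, "AGG", mm, pos, rng=rng, occupied=occupied)
        counts = count_by_mismatch(find_offtargets(_guide(), genome, max_mm=2))
        assert counts[0] == 1 and counts[1] == 2 and counts[2] == 3

    def test_counts_sum_to_total(self):
        genome = make_genome(3000, 0.45, seed=23)
        sites = find_offtargets(_guide(), genome, max_mm=5)
        assert sum(count_by_mismatch(sites).values()) == len(sites)


class TestOverlapAcrossLengths:
    def test_identical_sets_fall_in_full_intersection(self):
        genome = make_genome(2000, 0.45, seed=31)
        genome, _ = plant_site(genome, SPACER20, "AGG", 0, 800)
        g = _guide()
        sites = find_offtargets(g, genome, max_mm=1)
        table = overlap_across_lengths({20: sites, 19: sites, 18: sites})
        assert table.region_counts == {(18, 19, 20): len(sites)}
        assert table.n_shared == len(sites)

    def test_full_guide_hits_are_subset_of_truncated_hits(self):
        genome = make_genome(20_000, 0.45, seed=32)
        rng = np.random.default_rng(3)
        occupied = []
        for i, mm in enumerate([0, 1, 2, 3, 2, 1]):
            genome, _ = plant_site(genome, SPACER20, "TGG", mm, 1000 + 600 * i, rng=rng, occupied=occupied)
        g20 = _guide()
        sets = {
            length: find_offtargets(
                g20 if length == 20 else truncate_guide(g20, length), genome, max_mm=3
            )
            for length in (20, 17)
        }
        keys = {
            length: {(s.contig, s.cut_site, s.strand) for s in sites}
            for length, sites in sets.items()
        }
        assert keys[20] <= keys[17]
        table = overlap_across_lengths(sets)
        assert table.n_shared == len(keys[20] & keys[17])

    def test_disjoint_sets_have_empty_intersection(self):
        g = _guide()
        a = find_offtargets(g, "T" * 30 + SPACER20 + "AGG" + "T" * 30, max_mm=0)
        b = find_offtargets(g, "C" * 60 + SPACER20 + "TGG" + "C" * 60, max_mm=0)
        table = overlap_across_lengths({20: a, 19: b})
        assert table.n_shared == 0
        assert table.union_size() == len(a) + len(b)

    def test_requires_two_lengths(self):
        with pytest.raises(ValueError):
            overlap_across_lengths({20: []})
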