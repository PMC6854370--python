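"""Read QC, alignment, indel calling and per-site quantification."""

import math

import pytest
from crispec.amplicon import (
    AmpliconRef,
    align_to_amplicon,
    call_read,
    extract_target_regions,
    make_aligner,
    qc_filter,
    quantify_site,
)
from crispec.guides import Guide, find_offtargets
from crispec.io import FastqRecord
from crispec.sequence import revcomp
from crispec.simulate import SimulationConfig, make_genome, plant_site, simulate_reads

from oracles import affine_semiglobal_score

AMP_SEQ = make_genome(200, 0.5, seed=99)
REF = AmpliconRef(id="amp", sequence=AMP_SEQ, guide_id="g", cut_pos=100)
ALIGNER = make_aligner()


def fq(seq, rid="r1"):
    return FastqRecord(rid, seq, "?" * len(seq))


class TestQcFilter:
    def test_read_with_n_discarded(self):
        assert qc_filter([fq("ACGTN" + "A" * 40)]) == []

    def test_clean_read_passes_unchanged(self):
        rec = fq("ACGT" * 25)
        assert qc_filter([rec]) == [rec]

    def test_adapter_trim_below_min_length_discards(self):
        adapter = "AGATCGGAAGAGCACACGTC"
        read = "ACGT" * 10  # 40 bases
        read = read[:30] + adapter[:10]  # 10-base adapter prefix at the 3' end
        assert qc_filter([fq(read)], min_len=35, adapters=[adapter]) == []
        # same read passes a smaller threshold, trimmed to 30
        kept = qc_filter([fq(read)], min_len=20, adapters=[adapter])
        assert [r.seq for r in kept] == [read[:30]]

    def test_short_adapter_overlap_not_trimmed(self):
        adapter = "AGATCGGAAGAGC"
        read = "C" * 60 + adapter[:5]  # 5 < 8 minimum overlap
        kept = qc_filter([fq(read)], adapters=[adapter])
        assert kept[0].seq == read

    def test_order_preserved(self):
        recs = [fq("ACGT" * 20, f"r{i}") for i in range(5)]
        assert [r.id for r in qc_filter(recs)] == [f"r{i}" for i in range(5)]

    def test_malformed_record_reports_index(self):
        bad = FastqRecord("r7", "ACGT", "??")
        with pytest.raises(ValueError, match="index 1"):
            qc_filter([fq("ACGT" * 20), bad])


class TestAlignToAmplicon:
    def test_exact_substring_has_no_mismatch_or_gap(self):
        aln = align_to_amplicon(AMP_SEQ[40:160], REF, aligner=ALIGNER)
        assert aln.strand == "+"
        assert aln.indels == ()
        assert aln.n_match == 120

    def test_deletion_at_cut_site_recovered(self):
        read = AMP_SEQ[:100] + AMP_SEQ[103:]
        aln = align_to_amplicon(read, REF, aligner=ALIGNER)
        (ind,) = aln.indels
        assert ind.kind == "del" and ind.length == 3
        call = call_read(aln, REF)
        assert call.status == "indel" and call.indel_size == -3

    def test_reverse_complement_read_same_call(self):
        read = AMP_SEQ[:100] + AMP_SEQ[103:]
        fwd = call_read(align_to_amplicon(read, REF, aligner=ALIGNER), REF)
        rev_aln = align_to_amplicon(revcomp(read), REF, aligner=ALIGNER)
        assert rev_aln.strand == "-"
        rev = call_read(rev_aln, REF)
        assert (rev.status, rev.indel_size, rev.indel_start) == (
            fwd.status, fwd.indel_size, fwd.indel_start,
        )

    def test_garbage_read_discarded_unaligned(self):
        call = call_read(align_to_amplicon("TTTTGGGG" * 10, REF, aligner=ALIGNER), REF)
        assert call.status == "discarded_unaligned"

    def test_score_matches_dp_oracle_on_toy_pairs(self):
        ref60 = make_genome(60, 0.5, seed=101)
        cases = [
            ref60,  # exact
            ref60[:25] + ref60[28:],  # 3-bp deletion
            ref60[:30] + "ACGT" + ref60[30:],  # 4-bp insertion
            ref60[:20] + "T" + ref60[21:],  # substitution
            ref60[10:50],  # internal fragment (end gaps free)
        ]
        ref = AmpliconRef(id="t", sequence=ref60, guide_id="g", cut_pos=30)
        for read in cases:
            aln = align_to_amplicon(read, ref, aligner=ALIGNER)
            assert aln.score == pytest.approx(affine_semiglobal_score(ref60, read))


class TestCallRead:
    def test_perfect_read_is_wt(self):
        call = call_read(align_to_amplicon(AMP_SEQ, REF, aligner=ALIGNER), REF)
        assert call.status == "WT" and call.indel_size == 0

    def test_out_of_window_insertion_is_wt_with_flag(self):
        read = AMP_SEQ[:150] + "GT" + AMP_SEQ[150:]  # 50 bases from the cut
        call = call_read(align_to_amplicon(read, REF, aligner=ALIGNER), REF)
        assert call.status == "WT"
        assert call.in_window is False
        assert call.indel_start is not None

    def test_window_widening_captures_distant_indel(self):
        read = AMP_SEQ[:150] + AMP_SEQ[152:]  # deletion 50 bases from the cut
        wide = AmpliconRef(id="amp", sequence=AMP_SEQ, guide_id="g", cut_pos=100, quant_window=50)
        assert call_read(align_to_amplicon(read, REF, aligner=ALIGNER), REF).status == "WT"
        assert call_read(align_to_amplicon(read, wide, aligner=ALIGNER), wide).status == "indel"

    def test_substitutions_never_become_indels(self):
        read = list(AMP_SEQ)
        read[100] = "A" if AMP_SEQ[100] != "A" else "C"
        read[101] = "A" if AMP_SEQ[101] != "A" else "C"
        call = call_read(align_to_amplicon("".join(read), REF, aligner=ALIGNER), REF)
        assert call.status == "WT"


class TestQuantifySite:
    def test_unedited_reads_give_zero_efficiency(self):
        cfg = SimulationConfig(edit_rate=0, n_reads=300, seed=1)
        reads, _ = simulate_reads(AMP_SEQ, 100, cfg)
        q = quantify_site(reads, REF, aligner=ALIGNER)
        assert q.efficiency == 0.0
        assert q.n_aligned == 300

    def test_efficiency_recovers_simulated_rate(self):
        cfg = SimulationConfig(edit_rate=0.15, n_reads=2000, seed=2)
        reads, truth = simulate_reads(AMP_SEQ, 100, cfg)
        q = quantify_site(reads, REF, aligner=ALIGNER)
        bound = 3 * math.sqrt(0.15 * 0.85 / 2000) * 100
        assert abs(q.efficiency - 15.0) < bound
        # calls agree with the simulator's own labels exactly
        assert q.n_indel == int(truth["edited"].sum())

    def test_concatenated_read_sets_add(self):
        cfg1 = SimulationConfig(edit_rate=0.2, n_reads=200, seed=3)
        cfg2 = SimulationConfig(edit_rate=0.4, n_reads=150, seed=4)
        r1, _ = simulate_reads(AMP_SEQ, 100, cfg1)
        r2, _ = simulate_reads(AMP_SEQ, 100, cfg2, id_prefix="s")
        qa = quantify_site(r1, REF, aligner=ALIGNER)
        qb = quantify_site(r2, REF, aligner=ALIGNER)
        qc = quantify_site(r1 + r2, REF, aligner=ALIGNER)
        assert qc.n_total == qa.n_total + qb.n_total
        assert qc.n_indel == qa.n_indel + qb.n_indel
        for key in set(qa.allele_spectrum) | set(qb.allele_spectrum):
            assert qc.allele_spectrum[key] == qa.allele_spectrum.get(key, 0) + qb.allele_spectrum.get(key, 0)

    def test_substitution_errors_do_not_shift_efficiency(self):
        clean = SimulationConfig(edit_rate=0, subst_error_rate=0, n_reads=400, seed=5)
        noisy = SimulationConfig(edit_rate=0, subst_error_rate=0.005, n_reads=400, seed=5)
        r_clean, _ = simulate_reads(AMP_SEQ, 100, clean)
        r_noisy, _ = simulate_reads(AMP_SEQ, 100, noisy)
        e_clean = quantify_site(r_clean, REF, aligner=ALIGNER).efficiency
        e_noisy = quantify_site(r_noisy, REF, aligner=ALIGNER).efficiency
        assert abs(e_noisy - e_clean) < 0.5

    def test_empty_read_set_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            q = quantify_site([], REF, aligner=ALIGNER)
        assert (q.n_total, q.n_aligned, q.n_indel) == (0, 0, 0)
        assert q.efficiency == 0.0


class TestExtractTargetRegions:
    SPACER = "GTCACCTCCAATGACTAGGG"

    def _planted(self):
        genome = make_genome(3000, 0.5, seed=71)
        genome, _ = plant_site(genome, self.SPACER, "AGG", 0, 1500)
        g = Guide(id="g", spacer=self.SPACER, contig="seq", start=1500, end=1523, strand="+")
        (site,) = find_offtargets(g, genome, max_mm=0)
        return {"seq": genome}, g, site

    def test_mid_contig_amplicon_is_200bp_centred(self):
        genome, _, site = self._planted()
        (ref,) = extract_target_regions(genome, [site], flank=100)
        assert len(ref.sequence) == 200
        assert ref.cut_pos == 100
        assert ref.cut_near_end

    def test_clamped_near_contig_start(self):
        genome, _, site = self._planted()
        seq = genome["seq"]
        # shift the site to 30 bases from the contig start
        near = {"seq": seq[site.cut_site - 30 :]}
        import dataclasses

        shifted = dataclasses.replace(site, start=site.start - (site.cut_site - 30),
                                      end=site.end - (site.cut_site - 30))
        (ref,) = extract_target_regions(near, [shifted], flank=100)
        assert len(ref.sequence) == 130
        assert ref.cut_pos == 30

    def test_roundtrip_search_recovers_site(self):
        genome, g, site = self._planted()
        (ref,) = extract_target_regions(genome, [site], flank=100)
        sub = find_offtargets(g, {"seq": ref.sequence}, max_mm=0)
        assert len(sub) == 1
        assert sub[0].n_mismatch == site.n_mismatch

    def test_missing_contig_named_in_error(self):
        genome, _, site = self._planted()
        import dataclasses

        orphan = dataclasses.replace(site, contig="chrZ")
        with pytest.raises(KeyError, match="chrZ"):
            extract_target_regions(genome, [orphan])
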