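"""Paired-end stage: discordant selection, PEFS, prioritization, spanning
reads, isoforms and in-frame determination."""

import pytest
from Bio.Seq import Seq, reverse_complement
from hypothesis import given, settings
from hypothesis import strategies as st

from fusionscout import (AlignmentRecord, FusionCandidate, GeneModel, InputError,
                         PipelineConfig, ReadRecord, assign_pairs_to_genes,
                         build_candidates, compute_pefs, determine_in_frame,
                         find_spanning_reads, prioritize_candidates,
                         select_discordant_pairs)
from fusionscout.pe import (INTERCHROMOSOMAL, LONG_INTRACHROMOSOMAL,
                            DiscordantPair, MatePlacement, PairSupport)

from conftest import fusion_transcript, make_pair, random_dna


def _aln(read_id, mate, chrom, start, unique=True, fully=True, mm=0):
    return AlignmentRecord(read_id=read_id, target_kind="genome", target_id=chrom,
                           target_start=start, read_start=0, read_end=50, strand="+",
                           mismatches=mm, unique=unique, mapped_fully=fully, mate=mate)


class TestSelectDiscordant:
    def test_different_chromosomes_interchromosomal(self):
        (pair,) = select_discordant_pairs(
            [_aln("p", 1, "chr1", 100), _aln("p", 2, "chr11", 900)])
        assert pair.category == INTERCHROMOSOMAL

    def test_same_chromosome_below_1mb_excluded(self):
        assert select_discordant_pairs(
            [_aln("p", 1, "chr1", 100), _aln("p", 2, "chr1", 500_100)]) == []

    def test_same_chromosome_1_5mb_long_intrachromosomal(self):
        (pair,) = select_discordant_pairs(
            [_aln("p", 1, "chr1", 100), _aln("p", 2, "chr1", 1_500_100)])
        assert pair.category == LONG_INTRACHROMOSOMAL

    def test_non_unique_or_partial_mate_disqualifies_pair(self):
        assert select_discordant_pairs(
            [_aln("p", 1, "chr1", 100, unique=False), _aln("p", 2, "chr2", 900)]) == []
        assert select_discordant_pairs(
            [_aln("p", 1, "chr1", 100, fully=False), _aln("p", 2, "chr2", 900)]) == []

    def test_orphan_mate_skipped(self):
        assert select_discordant_pairs([_aln("p", 1, "chr1", 100)]) == []


def _support(pair_id, start1, start2, mm1=0, mm2=0, gene5="GA", gene3="GB",
             chrom1="chr1", chrom2="chr2"):
    pair = DiscordantPair(
        pair_id=pair_id,
        mate1=MatePlacement(pair_id, 1, chrom1, start1, "+", mm1, 50),
        mate2=MatePlacement(pair_id, 2, chrom2, start2, "-", mm2, 50),
        category=INTERCHROMOSOMAL)
    return PairSupport(pair=pair, gene5=gene5, gene3=gene3,
                       mate_transcript={1: (gene5, f"{gene5}.t1", start1, "+", mm1, 1),
                                        2: (gene3, f"{gene3}.t1", start2, "-", mm2, 1)})


def _candidate(supports):
    (cand,) = build_candidates({("GA", "GB"): supports})
    return cand


class TestPEFS:
    def test_three_unique_pairs_score_six(self):
        cand = _candidate([_support(f"p{i}", 100 + 10 * i, 900 + 10 * i)
                           for i in range(3)])
        assert (cand.P, cand.D, cand.M, cand.pefs) == (3, 0, 0, 6.0)

    def test_five_pairs_one_mismatch_score_9_5(self):
        supports = [_support(f"p{i}", 100 + 10 * i, 900 + 10 * i) for i in range(5)]
        supports[2].pair.mate1.mismatches = 1
        cand = _candidate(supports)
        assert (cand.P, cand.D, cand.M, cand.pefs) == (5, 0, 1, 9.5)

    def test_five_unique_clean_pairs_score_ten(self):
        cand = _candidate([_support(f"p{i}", 100 + 10 * i, 900 + 10 * i)
                           for i in range(5)])
        assert cand.pefs == 10.0

    def test_three_pairs_one_duplicate_read_score_five(self):
        # one supporting read shares its start coordinate with another; its
        # mate does not
        supports = [_support("p0", 100, 900), _support("p1", 100, 930),
                    _support("p2", 140, 960)]
        cand = _candidate(supports)
        assert (cand.P, cand.D, cand.pefs) == (3, 1, 5.0)

    def test_fully_duplicated_pair_costs_two(self):
        supports = [_support(f"p{i}", 100 + 10 * i, 900 + 10 * i) for i in range(3)]
        before = _candidate(list(supports)).pefs
        dup = _support("pdup", 100, 900)  # both mates duplicate p0's starts
        after = _candidate(supports + [dup]).pefs
        assert after == before  # +2 for the pair, -2 for two duplicate reads
        assert after is not None and after <= before + 2

    def test_unique_clean_pair_adds_exactly_two(self):
        supports = [_support(f"p{i}", 100 + 10 * i, 900 + 10 * i) for i in range(3)]
        before = _candidate(list(supports)).pefs
        after = _candidate(supports + [_support("p9", 777, 1777)]).pefs
        assert after == before + 2.0

    def test_empty_candidate_rejected(self):
        cand = FusionCandidate(gene5="GA", gene3="GB", support_pairs=[], P=0)
        with pytest.raises(InputError):
            compute_pefs(cand)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 30), st.integers(0, 30), st.integers(0, 2),
                              st.integers(0, 2)), min_size=1, max_size=12))
    def test_pefs_identity_holds(self, raw):
        """PEFS always equals 2P - D - 0.5M with D and M recomputed independently."""
        supports = [_support(f"p{i}", 100 + a, 900 + b, mm1, mm2)
                    for i, (a, b, mm1, mm2) in enumerate(raw)]
        cand = _candidate(supports)
        from collections import Counter
        starts = Counter()
        for a, b, _, _ in raw:
            starts[("chr1", 100 + a)] += 1
            starts[("chr2", 900 + b)] += 1
        expected_d = sum(n - 1 for n in starts.values())
        expected_m = sum(mm1 + mm2 for _, _, mm1, mm2 in raw)
        assert cand.D == expected_d and cand.M == expected_m
        assert cand.pefs == round(2 * len(raw) - expected_d - 0.5 * expected_m, 1)


class TestPrioritize:
    def _cand(self, p, pefs):
        cand = FusionCandidate(gene5="GA", gene3="GB", support_pairs=[], P=p)
        cand.pefs = pefs
        return cand

    def test_thresholds_are_conjunctive(self):
        assert len(prioritize_candidates([self._cand(3, 6.0)])) == 1
        assert prioritize_candidates([self._cand(2, 4.0)]) == []
        # enough pairs but heavy penalties push the score below 5
        assert prioritize_candidates([self._cand(4, 4.5)]) == []

    def test_sorted_by_score_then_pairs_then_name(self):
        a = FusionCandidate(gene5="AA", gene3="ZZ", support_pairs=[], P=3)
        a.pefs = 6.0
        b = FusionCandidate(gene5="BB", gene3="YY", support_pairs=[], P=4)
        b.pefs = 8.0
        c = FusionCandidate(gene5="AB", gene3="CD", support_pairs=[], P=4)
        c.pefs = 6.0
        out = prioritize_candidates([a, b, c])
        assert [(x.gene5, x.gene3) for x in out] == [("BB", "YY"), ("AB", "CD"),
                                                     ("AA", "ZZ")]


class TestAssignPairs:
    def _run(self, reads, toy_genome, toy_genes, starts=((100, 100),)):
        pairs = []
        reads_by_id = {}
        for i in range(0, len(reads), 2):
            rid = reads[i].read_id
            pairs.append(DiscordantPair(
                pair_id=rid,
                mate1=MatePlacement(rid, 1, "chr1", starts[i // 2][0], "+", 0, 50),
                mate2=MatePlacement(rid, 2, "chr2", starts[i // 2][1], "-", 0, 50),
                category=INTERCHROMOSOMAL))
            reads_by_id[(rid, 1)] = reads[i]
            reads_by_id[(rid, 2)] = reads[i + 1]
        return assign_pairs_to_genes(pairs, toy_genes, toy_genome, reads_by_id)

    def test_mate_strand_orients_five_prime_partner(self, toy_genome, toy_genes,
                                                    genes_by_id):
        tx, _ = fusion_transcript(genes_by_id["NFIA"], 2, genes_by_id["EHF"], 3,
                                  toy_genome)
        reads = make_pair("f1", tx, 5, 200)
        groups = self._run(reads, toy_genome, toy_genes)
        assert set(groups) == {("NFIA", "EHF")}

    def test_swapped_mate_roles_keep_orientation(self, toy_genome, toy_genes,
                                                 genes_by_id):
        # read 1 sequenced from the 3' end of the fragment: gene5 is still NFIA
        tx, _ = fusion_transcript(genes_by_id["NFIA"], 2, genes_by_id["EHF"], 3,
                                  toy_genome)
        m1, m2 = make_pair("f2", tx, 5, 200)
        swapped = [ReadRecord("f2", m2.sequence, 1), ReadRecord("f2", m1.sequence, 2)]
        groups = self._run(swapped, toy_genome, toy_genes)
        assert set(groups) == {("NFIA", "EHF")}

    def test_reciprocal_fusion_is_a_separate_group(self, toy_genome, toy_genes,
                                                   genes_by_id):
        tx_f, _ = fusion_transcript(genes_by_id["NFIA"], 2, genes_by_id["EHF"], 3,
                                    toy_genome)
        tx_r, _ = fusion_transcript(genes_by_id["EHF"], 2, genes_by_id["NFIA"], 3,
                                    toy_genome)
        reads = make_pair("f", tx_f, 5, 200) + make_pair("r", tx_r, 5, 230)
        groups = self._run(reads, toy_genome, toy_genes, starts=((100, 100), (110, 110)))
        assert set(groups) == {("NFIA", "EHF"), ("EHF", "NFIA")}

    def test_both_mates_in_one_gene_dropped(self, toy_genome, toy_genes, genes_by_id):
        ehf_tx = genes_by_id["EHF"].transcript_sequence(toy_genome)
        reads = make_pair("w1", ehf_tx, 5, 200)
        assert self._run(reads, toy_genome, toy_genes) == {}


class TestSpanningReads:
    def _candidate(self):
        return FusionCandidate(gene5="NFIA", gene3="EHF", support_pairs=[], P=3)

    def test_true_junction_and_alternate_isoform(self, toy_genome, genes_by_id):
        tx2, j2 = fusion_transcript(genes_by_id["NFIA"], 2, genes_by_id["EHF"], 3,
                                    toy_genome)
        tx1, j1 = fusion_transcript(genes_by_id["NFIA"], 1, genes_by_id["EHF"], 3,
                                    toy_genome)
        unmapped = [ReadRecord(f"s{k}", tx2[j2 - 25 - k:j2 + 25 - k]) for k in range(3)]
        unmapped.append(ReadRecord("iso", tx1[j1 - 25:j1 + 25]))
        cand = find_spanning_reads(self._candidate(), unmapped, genes_by_id,
                                   toy_genome, x=50)
        assert cand.confirmed
        assert cand.predicted_junction == (2, 3)
        assert cand.isoforms == [(1, 3), (2, 3)]
        assert len(cand.spanning_reads) == 4

    def test_zero_spanning_reads_leaves_unconfirmed(self, toy_genome, genes_by_id):
        cand = self._candidate()
        cand.support_pairs = [_support("p0", 100, 900, gene5="NFIA", gene3="EHF")]
        cand = find_spanning_reads(cand, [], genes_by_id, toy_genome, x=50)
        assert not cand.confirmed
        assert "unconfirmed" in cand.flags
        # fallback junction from the innermost exons touched by flanking pairs
        assert cand.predicted_junction == (1, 1)


def _cds_gene(gene_id, chrom, offset, cds_t):
    """Two 60 bp exons on the plus strand with a CDS given in transcript coords."""
    exons = [(offset, offset + 60), (offset + 120, offset + 180)]
    gene = GeneModel(gene_id, f"{gene_id}.t1", chrom, "+", exons)
    t0, t1 = cds_t

    def to_genomic(t):
        return offset + t if t < 60 else offset + 120 + (t - 60)

    gene.cds_span = (to_genomic(t0), to_genomic(t1 - 1) + 1)
    gene.__post_init__()
    return gene


class TestInFrame:
    @pytest.fixture()
    def frame_genome(self):
        import numpy as np
        rng = np.random.default_rng(99)
        return {"chrA": random_dna(rng, 400), "chrB": random_dna(rng, 400)}

    def _call(self, g5, g3, junction=(1, 2)):
        cand = FusionCandidate(gene5=g5.gene_id, gene3=g3.gene_id, support_pairs=[],
                               P=3, predicted_junction=junction)
        return determine_in_frame(cand, {g5.gene_id: g5, g3.gene_id: g3})

    def test_matched_phases_in_frame_verified_by_translation(self, frame_genome):
        # donor phase (60-12)%3 == acceptor phase (60-9)%3 == 0
        g5 = _cds_gene("F5", "chrA", 20, (12, 102))
        g3 = _cds_gene("F3", "chrB", 20, (9, 99))
        assert self._call(g5, g3) == "Y"
        # oracle: translating the fused CDS preserves the 3' partner's peptide
        tx5 = g5.transcript_sequence(frame_genome)
        tx3 = g3.transcript_sequence(frame_genome)
        fused_cds = tx5[12:60] + tx3[60:99]
        fusion_pep = str(Seq(fused_cds).translate())
        native_pep = str(Seq(tx3[9:99]).translate())
        downstream = (99 - 60) // 3
        assert fusion_pep[-downstream:] == native_pep[-downstream:]

    def test_off_by_one_phase_out_of_frame(self, frame_genome):
        g5 = _cds_gene("F5", "chrA", 20, (12, 102))
        g3 = _cds_gene("F3", "chrB", 20, (10, 100))  # acceptor phase shifts by 1
        assert self._call(g5, g3) == "N"
        tx5 = g5.transcript_sequence(frame_genome)
        tx3 = g3.transcript_sequence(frame_genome)
        fused = tx5[12:60] + tx3[60:100]
        fusion_pep = str(Seq(fused[:len(fused) // 3 * 3]).translate())
        native_pep = str(Seq(tx3[10:100]).translate())
        assert fusion_pep[-5:] != native_pep[-5:]

    def test_breakpoint_in_5utr_is_utr_truncation(self):
        # CDS of the 5' partner starts in exon 2; the junction after exon 1
        # lies in the 5' UTR, so the 3' partner's ORF survives intact
        g5 = _cds_gene("U5", "chrA", 20, (70, 118))
        g3 = _cds_gene("U3", "chrB", 20, (9, 99))
        assert self._call(g5, g3) == "UTR-truncation"

    def test_missing_cds_is_unknown(self, frame_genome):
        g5 = _cds_gene("F5", "chrA", 20, (12, 102))
        g3 = GeneModel("NC", "NC.t1", "chrB", "+", [(20, 80), (140, 200)])
        assert self._call(g5, g3) == "unknown"
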