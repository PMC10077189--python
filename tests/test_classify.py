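"""GSSP extraction, genome mapping, and staged novelty classification."""

from __future__ import annotations

import numpy as np
import pytest

import gsspipe as g
from gsspipe.classify import GSSP, _map_transcript_span, detect_saavs
from gsspipe.psms import PeptideIdentification
from gsspipe.seqdb import GenomeSequence, Transcript, TranslatedORF


def pid(seq: str) -> PeptideIdentification:
    return PeptideIdentification(
        seq, g.collapse_il(seq), frozenset({f"s_{seq}"}), frozenset({"msgf"}), 1.0, 0.0
    )


def make_gssp(seq: str, orf_id: str, offset: int) -> GSSP:
    return GSSP(pid(seq), ((orf_id, offset),))


class TestExtractGssps:
    def test_predicted_peptide_is_not_gssp(self):
        db = g.build_search_database(
            [("prot1", "WWWPEPTIDEKWWW")],
            genome_orfs=[TranslatedORF("o1", "genome_6frame", "c", 0, "PEPTIDEK",
                                       "c", 0, 24, "+")],
        )
        gssps, orphans = g.extract_gssps([pid("PEPTIDEK")], db)
        assert gssps == [] and orphans == []

    def test_il_variant_of_predicted_is_not_gssp(self):
        db = g.build_search_database(
            [("prot1", "WWWPEPTIDEKWWW")],
            genome_orfs=[TranslatedORF("o1", "genome_6frame", "c", 0, "PEPTLDEK",
                                       "c", 0, 24, "+")],
        )
        gssps, _ = g.extract_gssps([pid("PEPTLDEK")], db)
        assert gssps == []

    def test_orf_only_peptide_is_gssp(self):
        db = g.build_search_database(
            [("prot1", "WWWWWWWW")],
            genome_orfs=[TranslatedORF("o1", "genome_6frame", "c", 0, "AAPEPTIDEK",
                                       "c", 30, 60, "+")],
        )
        (gssp,), _ = g.extract_gssps([pid("PEPTIDEK")], db)
        assert gssp.occurrences == (("o1", 2),)

    def test_unmatched_peptide_is_orphan(self):
        db = g.build_search_database([("prot1", "WWWWWWWW")])
        gssps, orphans = g.extract_gssps([pid("PEPTIDEK")], db)
        assert gssps == [] and orphans == ["PEPTIDEK"]

    def test_planted_intergenic_peptides_are_gssps(self, small_truth, small_gssps):
        _, gssps, orphans = small_gssps
        assert orphans == []
        novel = next(f for f in small_truth.planted if f.kind == "novel_gene")
        planted_peps = {
            p.seq for p in g.digest_tryptic(novel.detail["protein"], 0)
        }
        found = {x.key for x in gssps}
        assert planted_peps <= found


class TestMapping:
    def test_forward_offset_arithmetic(self):
        orf = TranslatedORF("o1", "genome_6frame", "c", 0, "W" * 5 + "PEPTIDEK" + "W" * 5,
                            "c", 100, 154, "+")
        gssp = g.map_gssp_to_genome(make_gssp("PEPTIDEK", "o1", 5), {"o1": orf})
        (m,) = gssp.mappings
        assert m.blocks == ((115, 139),) and m.strand == "+"

    def test_minus_strand_mirrored(self):
        orf = TranslatedORF("o1", "genome_6frame", "c", 3, "W" * 5 + "PEPTIDEK" + "W" * 5,
                            "c", 100, 154, "-")
        gssp = g.map_gssp_to_genome(make_gssp("PEPTIDEK", "o1", 5), {"o1": orf})
        (m,) = gssp.mappings
        assert m.blocks == ((154 - 39, 154 - 15),) and m.strand == "-"

    def test_transcript_chain_split(self):
        # 30-nt exon1 + 30-nt exon2, peptide crosses the junction
        orf = TranslatedORF("t|t0|0-60", "transcript_3frame", "t", 0,
                            "AAAAAAAAPEPTIDEKAAAA", "c", None, None, "+",
                            t_start=0, t_end=60, chain=((100, 130), (200, 230)))
        gssp = g.map_gssp_to_genome(make_gssp("PEPTIDEK", orf.orf_id, 8), {orf.orf_id: orf})
        (m,) = gssp.mappings
        assert m.blocks == ((124, 130), (200, 218))
        assert m.junctions == ((130, 200),)

    def test_mappings_retranslate_on_synthetic_genome(self, small_truth, small_gssps, small_dbs):
        # genome-ORF mappings must re-translate from the genome; transcript
        # mappings may legitimately differ (planted variant transcripts)
        _, gssps, _ = small_gssps
        _, genome_orfs, _ = small_dbs
        genome_ids = {o.orf_id for o in genome_orfs}
        res = small_truth.residues()
        n = 0
        for gssp in gssps:
            for m in gssp.mappings:
                if m.orf_id in genome_ids:
                    nt = res[m.seq_id][m.blocks[0][0] : m.blocks[0][1]]
                    if m.strand == "-":
                        nt = g.reverse_complement(nt)
                    assert g.collapse_il(g.translate_dna(nt)) == m.peptide
                    n += 1
        assert n > 0

    def test_chain_walk_minus_strand(self):
        blocks, junctions = _map_transcript_span(0, 9, [(10, 16), (20, 26)], "-")
        # transcript 5' end sits at the top genomic block
        assert blocks == ((13, 16), (20, 26))
        assert junctions == ((16, 20),)


class TestClassifyOrfs:
    def _orf_with(self, gssps_and_offsets, orf_id="c|g0|0-3000", span=(0, 3000), strand="+"):
        aa = "W" * (span[1] - span[0]) // 3
        return None

    def test_intergenic_two_gssps_is_novel(self, small_truth, small_gssps):
        _, gssps, _ = small_gssps
        deferred = g.find_novel_junction_deferrals(gssps, small_truth.annotation)
        calls, _ = g.classify_orfs(gssps, small_truth.annotation, 2, deferred)
        novel = [c for c in calls if c.call_class == "novel_gene"]
        planted = [
            f for f in small_truth.planted
            if f.kind in ("novel_gene", "pseudogene_expressed")
        ]
        assert len(novel) == len(planted)
        # every planted novel locus is hit by exactly one call
        for f in planted:
            hits = [
                c for c in novel
                if c.seq_id == f.seq_id
                and c.intervals[0][0] >= f.intervals[0][0] - 1
                and c.intervals[-1][1] <= f.intervals[-1][1] + 1
            ]
            assert len(hits) == 1
            assert hits[0].pseudogene_flag == (f.kind == "pseudogene_expressed")

    def test_single_gssp_orf_yields_no_call(self):
        orf = TranslatedORF("c|g0|0-60", "genome_6frame", "c", 0, "AAPEPTIDEKAA",
                            "c", 0, 36, "+")
        gssp = g.map_gssp_to_genome(make_gssp("PEPTIDEK", orf.orf_id, 2), {orf.orf_id: orf})
        calls, remaining = g.classify_orfs([gssp], [])
        assert calls == [] and len(remaining) == 1

    def test_revised_targets_and_sub_evidence(self, small_truth, small_gssps):
        _, gssps, _ = small_gssps
        deferred = g.find_novel_junction_deferrals(gssps, small_truth.annotation)
        calls, _ = g.classify_orfs(gssps, small_truth.annotation, 2, deferred)
        revised = {c.target_gene: c for c in calls if c.call_class == "revised_gene"}
        for f in small_truth.planted:
            if not f.kind.startswith("revised"):
                continue
            call = revised[f.detail["target_gene"]]
            if f.kind == "revised_intron":
                assert call.sub_evidence == {"intron_peptide"}
            elif f.kind == "revised_merge":
                assert {"exon_merge", "intron_peptide"} <= call.sub_evidence
            else:
                assert "exon_extension" in call.sub_evidence

    def test_no_gssp_in_two_call_classes(self, small_truth, small_gssps, small_dbs):
        _, gssps, _ = small_gssps
        _, _, t_orfs = small_dbs
        deferred = g.find_novel_junction_deferrals(gssps, small_truth.annotation)
        calls, remaining = g.classify_orfs(gssps, small_truth.annotation, 2, deferred)
        sp, remaining = g.detect_splice_variants(remaining, t_orfs, small_truth.annotation, calls)
        sv, _ = detect_saavs(remaining, [(x.gene_id, x.protein) for x in small_truth.annotation if x.protein])
        seen: dict[str, str] = {}
        for call in calls + sp + sv:
            for pep in call.gssp_peptides:
                assert pep not in seen, f"{pep} in {seen[pep]} and {call.call_class}"
                seen[pep] = call.call_class

    def test_novel_calls_avoid_coding_exons(self, small_truth, small_gssps):
        _, gssps, _ = small_gssps
        deferred = g.find_novel_junction_deferrals(gssps, small_truth.annotation)
        calls, _ = g.classify_orfs(gssps, small_truth.annotation, 2, deferred)
        for c in calls:
            if c.call_class != "novel_gene":
                continue
            for gene in small_truth.annotation:
                if gene.biotype != "protein_coding" or gene.seq_id != c.seq_id or gene.strand != c.strand:
                    continue
                for a, b in c.intervals:
                    for ea, eb in gene.exons:
                        assert min(b, eb) - max(a, ea) <= 0


class TestSpliceVariants:
    def test_planted_junctions_recovered(self, small_truth, small_gssps, small_dbs):
        _, gssps, _ = small_gssps
        _, _, t_orfs = small_dbs
        deferred = g.find_novel_junction_deferrals(gssps, small_truth.annotation)
        calls, remaining = g.classify_orfs(gssps, small_truth.annotation, 2, deferred)
        sp, _ = g.detect_splice_variants(remaining, t_orfs, small_truth.annotation, calls)
        by_class = {c.call_class: c for c in sp}
        novel_truth = next(f for f in small_truth.planted if f.kind == "splice_novel")
        revised_truth = next(f for f in small_truth.planted if f.kind == "splice_revised")
        assert by_class["novel_splice"].junction == tuple(novel_truth.detail["junction"])
        assert by_class["revised_splice"].junction == tuple(revised_truth.detail["junction"])
        assert by_class["revised_splice"].target_gene == revised_truth.detail["target_gene"]

    def test_annotated_junction_not_called(self):
        # transcript reproduces an annotated intron: junction is known
        gene = g.GeneModel("g1", "c", "+", ((100, 130), (200, 230)), "protein_coding", "X")
        orf = TranslatedORF("t|t0|0-60", "transcript_3frame", "t", 0,
                            "AAAAAAAAPEPTIDEKAAAA", "c", None, None, "+",
                            t_start=0, t_end=60, chain=((100, 130), (200, 230)))
        gssp = g.map_gssp_to_genome(make_gssp("PEPTIDEK", orf.orf_id, 8), {orf.orf_id: orf})
        other = g.map_gssp_to_genome(make_gssp("AAAAAAAA", orf.orf_id, 0), {orf.orf_id: orf})
        calls, _ = g.detect_splice_variants([gssp, other], [orf], [gene], [])
        assert calls == []

    def test_junction_needs_supporting_gssp(self):
        orf = TranslatedORF("t|t0|0-60", "transcript_3frame", "t", 0,
                            "AAAAAAAAPEPTIDEKAAAA", "c", None, None, "+",
                            t_start=0, t_end=60, chain=((100, 130), (200, 230)))
        gssp = g.map_gssp_to_genome(make_gssp("PEPTIDEK", orf.orf_id, 8), {orf.orf_id: orf})
        calls, _ = g.detect_splice_variants([gssp], [orf], [], [])
        assert calls == []


class TestSaavs:
    def test_pro_ser_worked_vector(self):
        """A CCC->TCC codon change reads as a Pro->Ser single-residue variant."""
        ref_cds = "GCTGAAGTTATGGATCCCACCGGTAAG"  # AEVMDPTGK
        protein = g.translate_dna(ref_cds)
        assert protein[5] == "P"
        var_cds = ref_cds[:15] + "TCC" + ref_cds[18:]
        variant_pep = g.translate_dna(var_cds)
        assert variant_pep[5] == "S"
        calls, amb = detect_saavs(
            [make_gssp(variant_pep, "o1", 0)], [("prot1", protein)]
        )
        (call,) = calls
        assert call.call_class == "saav"
        assert call.variant_detail == ((6, "P", "S"),)
        assert amb == []

    def test_phe_leu_worked_vector(self):
        """A TTT->CTT codon change reads as a Phe->Leu variant, here against a
        pseudogene-derived novel product."""
        ref_cds = "GCTGAAGTTATGGATTTTACCGGTAAG"  # AEVMDFTGK
        protein = g.translate_dna(ref_cds)
        assert protein[5] == "F"
        var_cds = ref_cds[:15] + "CTT" + ref_cds[18:]
        variant_pep = g.translate_dna(var_cds)
        assert variant_pep[5] == "L"
        calls, _ = detect_saavs(
            [make_gssp(variant_pep, "o1", 0)],
            [("NG0001", protein)],
            novel_ids={"NG0001"},
        )
        (call,) = calls
        assert call.variant_detail == ((6, "F", "L"),)
        assert "on_novel_product" in call.sub_evidence

    def test_two_substitutions_allowed(self):
        calls, _ = detect_saavs([make_gssp("PEPTADEA", "o1", 0)], [("p1", "WWPEPTIDEKWW")])
        (call,) = calls
        assert {(r, a) for _, r, a in call.variant_detail} == {("I", "A"), ("K", "A")} or len(call.variant_detail) == 2

    def test_hamming_three_not_called(self):
        calls, _ = detect_saavs([make_gssp("PEPAAAEK", "o1", 0)], [("p1", "WWPEPTIDEKWW")])
        assert calls == []

    def test_ambiguous_across_proteins_flagged(self):
        calls, amb = detect_saavs(
            [make_gssp("PEPTADEK", "o1", 0)],
            [("p1", "PEPTIDEK"), ("p2", "PEPTIDEK")],
        )
        assert calls == [] and amb == ["PEPTADEK"]

    def test_distances_equal_brute_force(self):
        rng = np.random.default_rng(47)
        alphabet = list("ACDEFGHKMNQSTVWY")
        proteins = [
            (f"p{i}", "".join(rng.choice(alphabet, size=50))) for i in range(10)
        ]
        for _ in range(30):
            pep = "".join(rng.choice(alphabet, size=9))
            calls, amb = detect_saavs([make_gssp(pep, "o1", 0)], proteins)
            # brute force best distance over all windows of all proteins
            best = 99
            holders = set()
            for pid_, seq in proteins:
                for a in range(len(seq) - len(pep) + 1):
                    d = sum(x != y for x, y in zip(pep, seq[a : a + len(pep)]))
                    if d < best:
                        best, holders = d, {pid_}
                    elif d == best:
                        holders.add(pid_)
            if best == 0 or best > 2:
                assert calls == [] and (best > 2 or amb == [])
            elif len(holders) > 1:
                assert amb == [pep]
            else:
                (call,) = calls
                assert call.target_gene in holders
                assert len(call.variant_detail) == best

    def test_planted_saavs_recovered(self, small_truth, small_gssps, small_dbs):
        _, gssps, _ = small_gssps
        _, _, t_orfs = small_dbs
        deferred = g.find_novel_junction_deferrals(gssps, small_truth.annotation)
        calls, remaining = g.classify_orfs(gssps, small_truth.annotation, 2, deferred)
        _, remaining = g.detect_splice_variants(remaining, t_orfs, small_truth.annotation, calls)
        sv, amb = detect_saavs(
            remaining, [(x.gene_id, x.protein) for x in small_truth.annotation if x.protein]
        )
        planted = {
            f.detail["target_gene"]: f for f in small_truth.planted if f.kind == "saav"
        }
        assert {c.target_gene for c in sv} == set(planted)
        for c in sv:
            truth = planted[c.target_gene]
            assert list(c.variant_detail) == [tuple(v) for v in truth.detail["variants"]]
        # hamming-3 decoys never become calls
        decoy_peps = {
            f.detail["variant_peptide"]
            for f in small_truth.planted
            if f.kind == "saav_decoy"
        }
        assert decoy_peps.isdisjoint({p for c in sv for p in c.gssp_peptides})
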