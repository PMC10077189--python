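"""Sequence, translation, digestion and search-database tests.

The translation oracle here is deliberately independent of the package: a
hard-coded 64-codon standard-code dictionary and a per-frame loop.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

import gsspipe as g
from gsspipe.seqdb import DbEntry, GenomeSequence, SearchDatabase, Transcript

# --- independent standard genetic code (oracle) -----------------------------

_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
ORACLE_CODE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def oracle_translate(seq: str) -> str:
    return "".join(
        ORACLE_CODE.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3)
    )


def oracle_orf_set(residues: str, min_orf_aa: int):
    """Brute-force six-frame stop-to-stop ORFs as (frame, start, end, aa)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[c] for c in reversed(residues))
    length = len(residues)
    out = set()
    for strand, s in (("+", residues), ("-", rc)):
        for f in range(3):
            prot = oracle_translate(s[f:])
            run_start = 0
            for i, aa in enumerate(prot + "*"):
                if aa == "*":
                    if i - run_start >= min_orf_aa:
                        nt_a, nt_b = f + 3 * run_start, f + 3 * i
                        if strand == "+":
                            span = (nt_a, nt_b)
                        else:
                            span = (length - nt_b, length - nt_a)
                        frame = f if strand == "+" else f + 3
                        out.add((frame, span[0], span[1], prot[run_start:i]))
                    run_start = i + 1
    return out


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# --- FASTA / GFF3 round trips -----------------------------------------------


class TestGenomeIO:
    def test_two_record_fasta_roundtrip(self, tmp_path):
        seqs = [
            GenomeSequence("s1", "ACGTACGTNN"),
            GenomeSequence("s2", "TTTTACGT", "chloroplast"),
        ]
        path = g.write_genome(seqs, tmp_path / "g.fasta")
        back = g.read_genome(path, compartment_map={"s2": "chloroplast"})
        assert [(s.seq_id, s.residues, s.compartment) for s in back] == [
            (s.seq_id, s.residues, s.compartment) for s in seqs
        ]

    def test_invalid_residue_names_record(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">recA\nACGu\n")
        with pytest.raises(ValueError, match="recA"):
            g.read_genome(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ValueError):
            g.read_genome(path)

    def test_synthetic_genome_residue_roundtrip(self, small_truth, tmp_path):
        path = g.write_genome(small_truth.genome, tmp_path / "syn.fasta")
        back = g.read_genome(path)
        assert {s.seq_id: s.residues for s in back} == small_truth.residues()


class TestAnnotationIO:
    def test_gff3_coordinate_convention(self, tmp_path):
        genome = [GenomeSequence("c", "A" * 6 + "ATGAAATAG" + "A" * 10)]
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c\tx\tgene\t7\t15\t.\t+\t.\tID=g1;biotype=protein_coding\n"
            "c\tx\tCDS\t7\t15\t.\t+\t0\tParent=g1\n"
        )
        (model,) = g.read_annotation(gff, genome)
        assert model.exons == ((6, 15),)
        assert model.protein == "MK"

    def test_minus_strand_two_exon_translation(self, tmp_path):
        # protein MK: CDS=ATGAAATAG split 4|5, reverse-complemented on genome
        cds = "ATGAAATAG"
        part1, part2 = cds[:4], cds[4:]
        genomic = (
            "CC" + g.reverse_complement(part2) + "GGGG" + g.reverse_complement(part1) + "CC"
        )
        genome = [GenomeSequence("c", genomic)]
        # exon coordinates ascending: part2 at [2,7), part1 at [11,15)
        gff = tmp_path / "m.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c\tx\tgene\t3\t15\t.\t-\t.\tID=g1\n"
            "c\tx\tCDS\t3\t7\t.\t-\t0\tParent=g1\n"
            "c\tx\tCDS\t12\t15\t.\t-\t0\tParent=g1\n"
        )
        (model,) = g.read_annotation(gff, genome)
        spliced = model.spliced_cds(genomic)
        assert spliced == cds
        assert model.protein == "MK"

    def test_synthetic_annotation_roundtrip(self, small_truth, tmp_path):
        path = g.write_annotation(small_truth.annotation, tmp_path / "ann.gff3")
        back = g.read_annotation(path, small_truth.genome)
        orig = {m.gene_id: m for m in small_truth.annotation}
        assert set(orig) == {m.gene_id for m in back}
        for m in back:
            o = orig[m.gene_id]
            assert m.exons == o.exons
            assert m.strand == o.strand
            assert m.biotype == o.biotype
            assert m.protein == o.protein

    def test_cds_not_multiple_of_three_flagged(self, tmp_path, caplog):
        genome = [GenomeSequence("c", "ATGAAATAGAA")]
        gff = tmp_path / "bad.gff3"
        gff.write_text("c\tx\tgene\t1\t8\t.\t+\t.\tID=g1\nc\tx\tCDS\t1\t8\t.\t+\t0\tParent=g1\n")
        (model,) = g.read_annotation(gff, genome)
        assert model.untranslatable and model.protein == ""

    def test_out_of_bounds_feature_rejected(self, tmp_path):
        genome = [GenomeSequence("c", "ATGAAATAG")]
        gff = tmp_path / "oob.gff3"
        gff.write_text("c\tx\tgene\t1\t50\t.\t+\t.\tID=g1\nc\tx\tCDS\t1\t50\t.\t+\t0\tParent=g1\n")
        with pytest.raises(ValueError, match="bounds"):
            g.read_annotation(gff, genome)


# --- six- and three-frame translation ----------------------------------------


class TestSixFrame:
    def test_minimal_orf(self):
        seq = GenomeSequence("s", "ATGAAATAG")
        orfs = [o for o in g.six_frame_translate(seq, min_orf_aa=1) if o.frame == 0]
        assert [(o.aa_seq, o.start, o.end, o.strand) for o in orfs] == [("MK", 0, 6, "+")]

    def test_n_codons_become_x(self):
        seq = GenomeSequence("s", "ATGANATAG")
        (orf,) = [o for o in g.six_frame_translate(seq, min_orf_aa=2) if o.frame == 0]
        assert orf.aa_seq == "MX"

    def test_revcomp_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            s = random_dna(rng, 120)
            a = g.six_frame_translate(GenomeSequence("s", s), 5)
            b = g.six_frame_translate(GenomeSequence("s", g.reverse_complement(s)), 5)
            length = len(s)
            fwd = {(o.start, o.end, o.aa_seq, o.strand) for o in a}
            mirrored = {
                (length - o.end, length - o.start, o.aa_seq, "+-"[o.strand == "+"])
                for o in b
            }
            assert fwd == mirrored

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            s = random_dna(rng, 300)
            got = {
                (o.frame, o.start, o.end, o.aa_seq)
                for o in g.six_frame_translate(GenomeSequence("s", s), 5)
            }
            assert got == oracle_orf_set(s, 5)

    def test_orf_spans_retranslate(self, small_truth):
        res = small_truth.residues()
        for seq in small_truth.genome:
            for orf in g.six_frame_translate(seq, 10)[:200]:
                nt = res[orf.seq_id][orf.start : orf.end]
                if orf.strand == "-":
                    nt = g.reverse_complement(nt)
                assert g.translate_dna(nt) == orf.aa_seq


class TestThreeFrame:
    def test_short_transcript_removed(self):
        assert g.three_frame_translate([("t1", "A" * 49)], min_orf_aa=1) == []

    def test_51nt_transcript_orf_length(self):
        seq = "ATG" + "GCT" * 16  # 51 nt, no stops in frame 0
        orfs = [
            o for o in g.three_frame_translate([("t1", seq)], min_orf_aa=1)
            if o.frame == 0
        ]
        assert orfs[0].aa_seq == "M" + "A" * 16
        assert len(orfs[0].aa_seq) == 17

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            s = random_dna(rng, int(rng.integers(50, 400)))
            got = {
                (o.frame, o.t_start, o.t_end, o.aa_seq)
                for o in g.three_frame_translate([("t", s)], min_orf_aa=4)
            }
            expected = set()
            for f in range(3):
                prot = oracle_translate(s[f:])
                run = 0
                for i, aa in enumerate(prot + "*"):
                    if aa == "*":
                        if i - run >= 4:
                            expected.add((f, f + 3 * run, f + 3 * i, prot[run:i]))
                        run = i + 1
            assert got == expected

    def test_anchored_transcripts_carry_chain(self):
        t = Transcript("t1", "ATG" + "GCT" * 20, "chr1", "+", ((100, 163),))
        orfs = g.three_frame_translate([t], min_orf_aa=5)
        assert all(o.chain == ((100, 163),) for o in orfs)


# --- tryptic digestion -------------------------------------------------------


def oracle_digest(protein: str, max_missed: int, len_range):
    """Independent brute force: every substring whose ends are valid cleavage
    boundaries and whose internal uncut-site count is within budget."""
    lo, hi = len_range
    n = len(protein)

    def boundary(i):
        return i == 0 or i == n or (protein[i - 1] in "KR" and protein[i] != "P")

    out = set()
    for a in range(n):
        for b in range(a + 1, n + 1):
            if not (boundary(a) and boundary(b)):
                continue
            internal = sum(
                1
                for i in range(a + 1, b)
                if protein[i - 1] in "KR" and protein[i] != "P"
            )
            if internal <= max_missed and lo <= b - a <= hi:
                out.add((protein[a:b], a))
    return out


class TestDigestion:
    def test_cleaves_after_k_and_r(self):
        peps = g.digest_tryptic("MKRAST", max_missed=0, len_range=(1, 45))
        assert [p.seq for p in peps] == ["MK", "R", "AST"]

    def test_no_cleavage_before_proline(self):
        peps = g.digest_tryptic("AKPR", max_missed=0, len_range=(1, 45))
        assert [p.seq for p in peps] == ["AKPR"]

    def test_missed_cleavages_enumerated(self):
        peps = g.digest_tryptic("AKBKCK", max_missed=2, len_range=(1, 45))
        assert {(p.seq, p.missed) for p in peps} == {
            ("AK", 0), ("BK", 0), ("CK", 0),
            ("AKBK", 1), ("BKCK", 1), ("AKBKCK", 2),
        }

    def test_empty_protein(self):
        assert g.digest_tryptic("") == []

    @pytest.mark.parametrize("max_missed", [0, 1, 2])
    def test_brute_force_oracle(self, max_missed):
        rng = np.random.default_rng(17)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(60):
            protein = "".join(rng.choice(alphabet, size=int(rng.integers(5, 80))))
            got = {(p.seq, p.start) for p in g.digest_tryptic(protein, max_missed, (1, 45))}
            assert got == oracle_digest(protein, max_missed, (1, 45))

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60))
    def test_zero_missed_peptides_concatenate(self, protein):
        peps = g.digest_tryptic(protein, max_missed=0, len_range=(1, len(protein)))
        assert "".join(p.seq for p in peps) == protein

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60))
    def test_il_swap_invariance(self, protein):
        """Digestion boundaries ignore I<->L swaps (neither is a cut site)."""
        swapped = protein.translate(str.maketrans("IL", "LI"))
        a = [(p.start, len(p.seq), p.missed) for p in g.digest_tryptic(protein)]
        b = [(p.start, len(p.seq), p.missed) for p in g.digest_tryptic(swapped)]
        assert a == b


# --- search database ---------------------------------------------------------


class TestSearchDatabase:
    def test_decoys_one_per_target(self):
        targets = [(f"p{i}", "PEPTIDEK") for i in range(10)]
        db = g.build_search_database(targets)
        assert len(db) == 20
        assert len(db.decoys) == 10

    def test_decoy_is_reversal(self):
        db = g.build_search_database([("p1", "PEPTIDEK")])
        assert db.by_id["DECOY_p1"].aa_seq == "KEDITPEP"

    def test_duplicate_entry_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SearchDatabase([DbEntry("a", "PEP", "predicted"), DbEntry("a", "TID", "predicted")])

    def test_il_collapsed_lookup(self):
        db = g.build_search_database([("p1", "PEPTIDEK")])
        assert db.lookup("PEPTLDEK", origins=("predicted",)) == [("p1", 0)]

    def test_x_never_matches(self):
        db = g.build_search_database([("p1", "PEPXTIDEK")])
        assert db.lookup("PEPXTIDEK", origins=("predicted",)) == []

    def test_index_equals_naive_scan(self):
        rng = np.random.default_rng(23)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        entries = [
            (f"p{i}", "".join(rng.choice(alphabet, size=int(rng.integers(20, 60)))))
            for i in range(30)
        ]
        db = g.build_search_database(entries)
        collapsed = [(eid, g.collapse_il(seq)) for eid, seq in entries]
        for _ in range(100):
            eid, seq = entries[int(rng.integers(len(entries)))]
            a = int(rng.integers(len(seq) - 5))
            query = g.collapse_il(seq[a : a + 6])
            naive = set()
            for eid2, cseq in collapsed:
                pos = cseq.find(query)
                while pos != -1:
                    naive.add((eid2, pos))
                    pos = cseq.find(query, pos + 1)
            assert set(db.lookup(query, origins=("predicted",))) == naive

    def test_database_fasta_export(self, tmp_path):
        db = g.build_search_database([("p1", "PEPTIDEK")])
        path = g.write_database_fasta(db, tmp_path / "db.fasta")
        text = path.read_text()
        assert ">p1|origin=predicted\n" in text
        assert ">DECOY_p1|origin=decoy\n" in text
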