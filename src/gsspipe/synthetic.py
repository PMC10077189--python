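"""Synthetic proteogenomic study generator with known ground truth.

Builds desk-scale genomes, annotations, transcriptomes, PSM tables, RNA-seq
alignments and reporter-ion tables that exercise every pipeline stage, with
every novelty planted on purpose and recorded:

* random GC~47% background with multi-exon protein-coding genes and a small
  fraction of (unexpressed) pseudogenes;
* planted novelties of every class the classifier calls: intergenic novel
  genes, expressed pseudogenes, revised gene models (spurious annotated
  introns, multi-intron merges, truncated exons), splice variants with
  unannotated junctions, and single-amino-acid variants carried on
  variant transcripts;
* tryptic peptide evidence scored from a two-Gaussian model (target vs
  null/decoy), with optional cross-engine disagreement injection;
* spliced RNA-seq reads tiled over expressed loci with a uniform per-base
  mismatch process;
* multi-channel reporter intensities with replicate structure and planted
  fold changes.

Synthetic proteins are built as tryptic segments of 7-13 residues (17-letter
alphabet without K/R/P) terminated by K or R, so every fully cleaved peptide
falls deterministically inside the 7-45 aa detection window; evidence is
generated fully cleaved.  All outputs are byte-deterministic under a fixed
seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import _map_transcript_span
from .psms import PSM, write_psm_table
from .seqdb import (
    GeneModel,
    GenomeSequence,
    Transcript,
    digest_tryptic,
    reverse_complement,
    translate_dna,
    write_annotation,
    write_genome,
    write_transcripts,
)
from .validate import QuantRecord

#: residue pool for synthetic proteins: no K/R (cleavage), no P (suppression),
#: no I (so I/L collapse is the identity on synthetic sequences)
SEGMENT_ALPHABET = "ACDEFGHLMNQSTVWY"
#: residues usable as SAAV substitutions
SUBSTITUTION_ALPHABET = "ACDEFGHMNQSTVWY"

PLANT_KINDS = (
    "novel_gene",
    "pseudogene_expressed",
    "revised_intron",
    "revised_merge",
    "revised_extension",
    "splice_novel",
    "splice_revised",
    "saav",
    "saav_decoy",
    "de_protein",
)

_CODONS_BY_AA: dict[str, tuple[str, ...]] = {}


def _codons_by_aa() -> dict[str, tuple[str, ...]]:
    if not _CODONS_BY_AA:
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[1]
        by_aa: dict[str, list[str]] = {}
        for codon, aa in table.forward_table.items():
            by_aa.setdefault(aa, []).append(codon)
        for aa, codons in by_aa.items():
            _CODONS_BY_AA[aa] = tuple(sorted(codons))
        _CODONS_BY_AA["*"] = tuple(sorted(table.stop_codons))
    return _CODONS_BY_AA


@dataclass(frozen=True)
class PlantedFeature:
    """One planted novelty with its genomic locus and kind-specific payload."""

    kind: str
    name: str
    seq_id: str
    strand: str
    intervals: tuple[tuple[int, int], ...]
    detail: dict


@dataclass
class SyntheticTruth:
    """A synthetic study: genome + annotation + planted features + the true
    expressed products and transcripts the evidence will be drawn from."""

    genome: list[GenomeSequence]
    annotation: list[GeneModel]
    planted: list[PlantedFeature]
    seed: int
    products: dict[str, str] = field(default_factory=dict)
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def coding_genes(self) -> list[GeneModel]:
        return [g for g in self.annotation if g.biotype == "protein_coding"]

    def residues(self) -> dict[str, str]:
        return {s.seq_id: s.residues for s in self.genome}


# ---------------------------------------------------------------------------
# Sequence construction helpers
# ---------------------------------------------------------------------------


def _random_dna(rng: np.random.Generator, n: int, gc: float = 0.47) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    letters = np.frombuffer(b"ACGT", dtype="S1")
    return rng.choice(letters, size=n, p=p).tobytes().decode()


def _make_protein(
    rng: np.random.Generator, n_peptides: int, seg_len: tuple[int, int] = (7, 13)
) -> tuple[str, list[int]]:
    """A protein of ``n_peptides`` tryptic segments; returns the sequence and
    the cleavage boundaries [0, b1, ..., len]."""
    parts: list[str] = []
    boundaries = [0]
    letters = list(SEGMENT_ALPHABET)
    for _ in range(n_peptides):
        length = int(rng.integers(seg_len[0], seg_len[1] + 1))
        seg = "".join(rng.choice(letters, size=length))
        seg += "K" if rng.random() < 0.5 else "R"
        parts.append(seg)
        boundaries.append(boundaries[-1] + len(seg))
    return "".join(parts), boundaries


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    by_aa = _codons_by_aa()
    return "".join(
        by_aa[aa][int(rng.integers(len(by_aa[aa])))] for aa in protein
    )


def _aa_to_genomic(
    cds_g: tuple[int, int], strand: str, aa_a: int, aa_b: int
) -> tuple[int, int]:
    gs, ge = cds_g
    if strand == "+":
        return (gs + 3 * aa_a, gs + 3 * aa_b)
    return (ge - 3 * aa_b, ge - 3 * aa_a)


class _Placer:
    """Tracks occupied intervals per chromosome and hands out intergenic
    slots with a safety margin."""

    def __init__(self, truth: SyntheticTruth, margin: int = 300):
        self.margin = margin
        self.lengths = {s.seq_id: len(s) for s in truth.genome}
        self.occupied: dict[str, list[tuple[int, int]]] = {
            s.seq_id: [] for s in truth.genome
        }
        for g in truth.annotation:
            self.occupied[g.seq_id].append((g.start, g.end))
        for f in truth.planted:
            self.occupied[f.seq_id].append((f.intervals[0][0], f.intervals[-1][1]))

    def take(self, rng: np.random.Generator, length: int) -> tuple[str, int]:
        need = length + 2 * self.margin
        candidates: list[tuple[str, int, int]] = []
        for seq_id in sorted(self.occupied):
            ivs = sorted(self.occupied[seq_id])
            prev = 0
            for a, b in ivs + [(self.lengths[seq_id], self.lengths[seq_id])]:
                if a - prev >= need:
                    candidates.append((seq_id, prev, a))
                prev = max(prev, b)
        if not candidates:
            raise ValueError("no intergenic room left for planting")
        seq_id, lo, hi = candidates[int(rng.integers(len(candidates)))]
        pos = lo + self.margin + int(rng.integers(hi - lo - need + 1))
        self.occupied[seq_id].append((pos, pos + length))
        return seq_id, pos


def _write_region(truth: SyntheticTruth, seq_id: str, pos: int, seq: str) -> None:
    for i, gs in enumerate(truth.genome):
        if gs.seq_id == seq_id:
            res = gs.residues
            truth.genome[i] = replace(gs, residues=res[:pos] + seq + res[pos + len(seq) :])
            return
    raise KeyError(seq_id)


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------


def generate_genome(
    seed: int,
    n_chromosomes: int = 2,
    n_genes: int = 50,
    gene_len_range: tuple[int, int] = (100, 240),
    intron_prob: float = 0.5,
    genome_length: int = 1_000_000,
    pseudogene_frac: float = 0.05,
) -> SyntheticTruth:
    """A random annotated genome: GC~47% background, ``n_genes`` genes of
    1-6 exons with valid ORFs, ~``pseudogene_frac`` of them emitted as
    single-exon pseudogenes (annotated non-coding, sequence still
    ORF-bearing).  Deterministic under ``seed``."""
    rng = np.random.default_rng(seed)
    if n_genes < n_chromosomes:
        raise ValueError("need at least one gene per chromosome")
    by_aa = _codons_by_aa()
    chrom_len = genome_length // n_chromosomes
    counts = [n_genes // n_chromosomes] * n_chromosomes
    for i in range(n_genes % n_chromosomes):
        counts[i] += 1
    n_pseudo = int(round(pseudogene_frac * n_genes))
    pseudo_idx = set(rng.choice(n_genes, size=n_pseudo, replace=False).tolist())

    genome: list[GenomeSequence] = []
    annotation: list[GeneModel] = []
    gene_no = 0
    for ci in range(n_chromosomes):
        seq_id = f"chr{ci + 1}"
        background = _random_dna(rng, chrom_len)
        # build this chromosome's genes
        built: list[tuple[str, str, tuple[tuple[int, int], ...], str, str]] = []
        for _ in range(counts[ci]):
            is_pseudo = gene_no in pseudo_idx
            n_aa = int(rng.integers(gene_len_range[0], gene_len_range[1] + 1))
            protein, _bounds = _make_protein(rng, max(5, n_aa // 11))
            cds = _back_translate(rng, protein)
            stop = by_aa["*"][int(rng.integers(3))]
            strand = "+" if rng.random() < 0.5 else "-"
            if not is_pseudo and rng.random() < intron_prob:
                n_introns = int(rng.integers(1, 6))
            else:
                n_introns = 0
            cuts = sorted(
                int(x)
                for x in rng.choice(
                    np.arange(30, len(cds) - 30), size=n_introns, replace=False
                )
            ) if n_introns else []
            # enforce minimum exon size between cuts
            cuts = [c for k, c in enumerate(cuts) if k == 0 or c - cuts[k - 1] >= 30]
            pieces: list[str] = []
            exons_rel: list[tuple[int, int]] = []
            prev = 0
            offset = 0
            for cut in cuts + [len(cds)]:
                exon_seq = cds[prev:cut]
                exons_rel.append((offset, offset + len(exon_seq)))
                pieces.append(exon_seq)
                offset += len(exon_seq)
                if cut != len(cds):
                    intron = _random_dna(rng, int(rng.integers(60, 301)))
                    pieces.append(intron)
                    offset += len(intron)
                prev = cut
            sense = "".join(pieces) + stop
            if strand == "-":
                glen = len(sense)
                genomic = reverse_complement(sense)
                exons_rel = sorted((glen - b, glen - a) for a, b in exons_rel)
            else:
                genomic = sense
            gene_no += 1
            built.append(
                (
                    f"gene{gene_no:04d}",
                    genomic,
                    tuple(exons_rel),
                    strand,
                    "" if is_pseudo else protein,
                )
            )
        # place the genes with random intergenic gaps
        total_gene = sum(len(g[1]) for g in built)
        min_gap = 1000
        leftover = chrom_len - total_gene - (len(built) + 1) * min_gap
        if leftover < 0:
            raise ValueError(
                f"infeasible packing: {counts[ci]} genes do not fit in {chrom_len} bp"
            )
        weights = rng.random(len(built) + 1)
        extra = np.floor(weights / weights.sum() * leftover).astype(int)
        cursor = 0
        residues = background
        for k, (gene_id, genomic, exons_rel, strand, protein) in enumerate(built):
            cursor += min_gap + int(extra[k])
            residues = residues[:cursor] + genomic + residues[cursor + len(genomic) :]
            exons = tuple((cursor + a, cursor + b) for a, b in exons_rel)
            annotation.append(
                GeneModel(
                    gene_id=gene_id,
                    seq_id=seq_id,
                    strand=strand,
                    exons=exons,
                    biotype="pseudogene" if not protein else "protein_coding",
                    protein=protein,
                )
            )
            cursor += len(genomic)
        genome.append(GenomeSequence(seq_id, residues))

    return SyntheticTruth(genome=genome, annotation=annotation, planted=[], seed=seed)


# ---------------------------------------------------------------------------
# Novelty planting
# ---------------------------------------------------------------------------


def _plant_single_exon(
    truth: SyntheticTruth,
    placer: _Placer,
    rng: np.random.Generator,
    protein: str,
) -> tuple[str, str, tuple[int, int]]:
    """Write a contiguous CDS into intergenic space, bracketed by in-frame
    stop codons so the surrounding stop-to-stop ORF is exactly the planted
    protein; returns (seq_id, strand, coding genomic interval)."""
    cds = _back_translate(rng, protein)
    stops = _codons_by_aa()["*"]
    sense = stops[int(rng.integers(3))] + cds + stops[int(rng.integers(3))]
    strand = "+" if rng.random() < 0.5 else "-"
    genomic = sense if strand == "+" else reverse_complement(sense)
    seq_id, pos = placer.take(rng, len(genomic))
    _write_region(truth, seq_id, pos, genomic)
    # the CDS sits between the stop brackets in either orientation
    cds_g = (pos + 3, pos + 3 + len(cds))
    return seq_id, strand, cds_g


def _gene_counter(truth: SyntheticTruth) -> int:
    return len(truth.annotation)


def plant_novelties(
    truth: SyntheticTruth,
    counts: Mapping[str, int],
    seed: int,
) -> SyntheticTruth:
    """Plant novelties of the requested kinds into the truth (in place and
    returned).  Kinds and what they emulate:

    - ``novel_gene``: intergenic single-exon gene withheld from the annotation;
    - ``pseudogene_expressed``: as above, but annotated as a pseudogene whose
      product is nonetheless expressed;
    - ``revised_intron`` / ``revised_merge``: a contiguous real CDS annotated
      with one / two spurious introns (the merge case emulates several
      annotated exons that should be merged into one);
    - ``revised_extension``: annotation truncates the real CDS mid-peptide;
    - ``splice_novel`` / ``splice_revised``: a genuinely spliced gene with an
      unannotated junction, intergenic or overlapping an annotated exon stub;
    - ``saav`` / ``saav_decoy``: a variant transcript of an annotated gene
      carrying 1-2 (decoy: 3) residue substitutions inside one tryptic
      peptide — the genome is left untouched, as variants can only enter the
      search space through the transcriptome;
    - ``de_protein``: a planted fold change on a novel product's reporter
      intensities.
    """
    unknown = set(counts) - set(PLANT_KINDS)
    if unknown:
        raise ValueError(f"unknown planted kinds: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    placer = _Placer(truth)
    gene_no = _gene_counter(truth)

    def next_gene_id() -> str:
        nonlocal gene_no
        gene_no += 1
        return f"gene{gene_no:04d}"

    # --- novel genes and expressed pseudogenes -----------------------------
    for i in range(counts.get("novel_gene", 0)):
        protein, _ = _make_protein(rng, int(rng.integers(5, 9)))
        seq_id, strand, cds_g = _plant_single_exon(truth, placer, rng, protein)
        name = f"novel{i + 1:03d}"
        truth.products[name] = protein
        truth.transcripts.append(
            Transcript(f"t_{name}", _coding_seq(truth, seq_id, strand, (cds_g,)),
                       seq_id, strand, (cds_g,))
        )
        truth.planted.append(
            PlantedFeature("novel_gene", name, seq_id, strand, (cds_g,),
                           {"protein": protein})
        )

    for i in range(counts.get("pseudogene_expressed", 0)):
        protein, _ = _make_protein(rng, int(rng.integers(5, 9)))
        seq_id, strand, cds_g = _plant_single_exon(truth, placer, rng, protein)
        gid = next_gene_id()
        truth.annotation.append(
            GeneModel(gid, seq_id, strand, (cds_g,), biotype="pseudogene")
        )
        name = f"pseudo_expr{i + 1:03d}"
        truth.products[name] = protein
        truth.transcripts.append(
            Transcript(f"t_{name}", _coding_seq(truth, seq_id, strand, (cds_g,)),
                       seq_id, strand, (cds_g,))
        )
        truth.planted.append(
            PlantedFeature("pseudogene_expressed", name, seq_id, strand, (cds_g,),
                           {"protein": protein, "target_gene": gid})
        )

    # --- revised gene models ------------------------------------------------
    def plant_revised(kind: str, i: int) -> None:
        n_pep = int(rng.integers(12, 17))
        protein, bounds = _make_protein(rng, n_pep)
        seq_id, strand, cds_g = _plant_single_exon(truth, placer, rng, protein)
        if kind == "revised_intron":
            j = int(rng.integers(2, n_pep - 5))
            removed = [(bounds[j], bounds[j + 3])]
        elif kind == "revised_merge":
            j = int(rng.integers(2, n_pep - 9))
            k = int(rng.integers(j + 4, n_pep - 4))
            removed = [(bounds[j], bounds[j + 2]), (bounds[k], bounds[k + 2])]
        else:  # revised_extension: truncate mid-peptide near the C-terminus
            cut = bounds[n_pep - 3] + 4
            removed = [(cut, len(protein))]
        kept: list[tuple[int, int]] = []
        prev = 0
        for a, b in removed:
            if a > prev:
                kept.append((prev, a))
            prev = b
        if prev < len(protein):
            kept.append((prev, len(protein)))
        exons = tuple(sorted(_aa_to_genomic(cds_g, strand, a, b) for a, b in kept))
        annotated_protein = "".join(protein[a:b] for a, b in kept)
        gid = next_gene_id()
        truth.annotation.append(
            GeneModel(gid, seq_id, strand, exons, "protein_coding", annotated_protein)
        )
        name = f"true_{gid}"
        truth.products[name] = protein
        truth.transcripts.append(
            Transcript(f"t_{name}", _coding_seq(truth, seq_id, strand, (cds_g,)),
                       seq_id, strand, (cds_g,))
        )
        truth.planted.append(
            PlantedFeature(
                kind, name, seq_id, strand, (cds_g,),
                {
                    "protein": protein,
                    "target_gene": gid,
                    "removed_aa": removed,
                    "removed_genomic": [
                        _aa_to_genomic(cds_g, strand, a, b) for a, b in removed
                    ],
                },
            )
        )

    for kind in ("revised_intron", "revised_merge", "revised_extension"):
        for i in range(counts.get(kind, 0)):
            plant_revised(kind, i)

    # --- splice variants ----------------------------------------------------
    def plant_splice(mode: str, i: int) -> None:
        n_pep = int(rng.integers(10, 15))
        protein, bounds = _make_protein(rng, n_pep)
        j = int(rng.integers(2, n_pep - 2))
        seg_len = bounds[j + 1] - bounds[j]
        t = int(rng.integers(3, seg_len - 2))
        junction_aa = bounds[j] + t
        cds = _back_translate(rng, protein)
        stops = _codons_by_aa()["*"]
        intron = _random_dna(rng, int(rng.integers(150, 301)))
        e1_nt = 3 * junction_aa
        sense = (
            stops[int(rng.integers(3))] + cds[:e1_nt] + intron + cds[e1_nt:]
            + stops[int(rng.integers(3))]
        )
        strand = "+" if rng.random() < 0.5 else "-"
        genomic = sense if strand == "+" else reverse_complement(sense)
        seq_id, pos = placer.take(rng, len(genomic))
        _write_region(truth, seq_id, pos, genomic)
        glen = len(sense)
        blocks_sense = [
            (3, 3 + e1_nt),
            (3 + e1_nt + len(intron), 3 + e1_nt + len(intron) + len(cds) - e1_nt),
        ]
        if strand == "+":
            blocks = tuple((pos + a, pos + b) for a, b in blocks_sense)
        else:
            blocks = tuple(sorted((pos + glen - b, pos + glen - a) for a, b in blocks_sense))
        junction = (blocks[0][1], blocks[1][0])
        name = f"splice_{mode}{i + 1:03d}"
        target = None
        if mode == "revised":
            # annotate the first-exon portion (transcript 5' side) as a stub gene
            stub_aa = (0, junction_aa)
            exon1_g = _aa_to_genomic(
                (blocks[0][0], blocks[0][1]) if strand == "+" else (blocks[1][0], blocks[1][1]),
                strand, 0, junction_aa,
            )
            target = next_gene_id()
            truth.annotation.append(
                GeneModel(target, seq_id, strand, (exon1_g,), "protein_coding",
                          protein[:junction_aa])
            )
        truth.products[name] = protein
        truth.transcripts.append(
            Transcript(f"t_{name}", cds, seq_id, strand, blocks)
        )
        truth.planted.append(
            PlantedFeature(
                f"splice_{mode}", name, seq_id, strand, blocks,
                {
                    "protein": protein,
                    "junction": junction,
                    "target_gene": target,
                    "junction_peptide": protein[bounds[j] : bounds[j + 1]],
                },
            )
        )

    for mode in ("novel", "revised"):
        for i in range(counts.get(f"splice_{mode}", 0)):
            plant_splice(mode, i)

    # --- single amino acid variants ----------------------------------------
    targeted: set[str] = set()

    def _collision_free(variant_pep: str, target: tuple[str, int]) -> bool:
        """True iff no window of any protein other than the target window is
        within Hamming distance 2 of the variant peptide — guarantees the
        planted variant resolves to its intended source uniquely (and that a
        distance-3 decoy resolves nowhere)."""
        m = len(variant_pep)
        space = [(g.gene_id, g.protein) for g in truth.annotation if g.protein]
        space += list(truth.products.items())
        for name, protein in space:
            cseq = protein.replace("I", "L")
            for a in range(len(cseq) - m + 1):
                if (name, a) == target:
                    continue
                d = 0
                for x, y in zip(variant_pep, cseq[a : a + m]):
                    if x != y:
                        d += 1
                        if d > 2:
                            break
                else:
                    return False
        return True

    def plant_saav(n_subs: int, i: int, decoy: bool) -> None:
        candidates = [
            g for g in truth.annotation
            if g.biotype == "protein_coding"
            and len(g.exons) == 1
            and g.protein
            and g.gene_id not in targeted
            and not any(f.detail.get("target_gene") == g.gene_id for f in truth.planted)
        ]
        if not candidates:
            raise ValueError("no untargeted single-exon genes left for SAAV planting")
        gene = candidates[int(rng.integers(len(candidates)))]
        targeted.add(gene.gene_id)
        peptides = [
            p for p in digest_tryptic(gene.protein, max_missed=0)
            if len(p.seq) >= max(9, n_subs + 4)
            and p.start > 0
            and p.start + len(p.seq) < len(gene.protein)
        ]
        for _attempt in range(60):
            pep = peptides[int(rng.integers(len(peptides)))]
            offsets = sorted(
                int(x)
                for x in rng.choice(
                    np.arange(1, len(pep.seq) - 1), size=n_subs, replace=False
                )
            )
            variants: list[tuple[int, str, str]] = []
            variant_protein = list(gene.protein)
            for off in offsets:
                pos = pep.start + off
                ref = gene.protein[pos]
                choices = [c for c in SUBSTITUTION_ALPHABET if c != ref]
                alt = choices[int(rng.integers(len(choices)))]
                variant_protein[pos] = alt
                variants.append((pos + 1, ref, alt))
            candidate_pep = "".join(variant_protein)[pep.start : pep.start + len(pep.seq)]
            if _collision_free(
                candidate_pep.replace("I", "L"), (gene.gene_id, pep.start)
            ):
                break
        else:
            raise ValueError("could not plant a proteome-unique SAAV peptide")
        variant_protein = "".join(variant_protein)
        # variant transcript: genomic CDS with only the variant codons changed
        res = truth.residues()[gene.seq_id]
        a, b = gene.exons[0]
        cds = res[a:b] if gene.strand == "+" else reverse_complement(res[a:b])
        cds_list = list(cds)
        by_aa = _codons_by_aa()
        for pos1, _ref, alt in variants:
            codon = by_aa[alt][int(rng.integers(len(by_aa[alt])))]
            cds_list[3 * (pos1 - 1) : 3 * pos1] = list(codon)
        name = ("saav_decoy" if decoy else "saav") + f"{i + 1:03d}"
        truth.products[name] = variant_protein
        truth.transcripts.append(
            Transcript(f"t_{name}", "".join(cds_list), gene.seq_id, gene.strand,
                       (gene.exons[0],))
        )
        variant_peptide = variant_protein[pep.start : pep.start + len(pep.seq)]
        truth.planted.append(
            PlantedFeature(
                "saav_decoy" if decoy else "saav", name, gene.seq_id, gene.strand,
                (_aa_to_genomic((a, b) if gene.strand == "+" else (a, b), gene.strand,
                                pep.start, pep.start + len(pep.seq)),),
                {
                    "target_gene": gene.gene_id,
                    "variants": variants,
                    "variant_peptide": variant_peptide,
                    "n_subs": n_subs,
                },
            )
        )

    for i in range(counts.get("saav", 0)):
        plant_saav(int(rng.integers(1, 3)), i, decoy=False)
    for i in range(counts.get("saav_decoy", 0)):
        plant_saav(3, i, decoy=True)

    # --- planted differential expression ------------------------------------
    novel_names = [
        f.name for f in truth.planted if f.kind in ("novel_gene", "pseudogene_expressed")
    ]
    n_de = counts.get("de_protein", 0)
    if n_de > len(novel_names):
        raise ValueError("more de_protein features requested than novel products")
    chosen = rng.choice(len(novel_names), size=n_de, replace=False)
    conditions = ("N_def", "P_def", "Si_def")
    for i, idx in enumerate(sorted(int(x) for x in chosen)):
        name = novel_names[idx]
        cond = conditions[int(rng.integers(len(conditions)))]
        feature = next(f for f in truth.planted if f.name == name)
        truth.planted.append(
            PlantedFeature(
                "de_protein", f"de{i + 1:03d}", feature.seq_id, feature.strand,
                feature.intervals,
                {"protein_name": name, "condition": cond, "fold_change": 8.0},
            )
        )
    return truth


def _coding_seq(
    truth: SyntheticTruth, seq_id: str, strand: str, blocks: Sequence[tuple[int, int]]
) -> str:
    res = truth.residues()[seq_id]
    spliced = "".join(res[a:b] for a, b in blocks)
    return reverse_complement(spliced) if strand == "-" else spliced


# ---------------------------------------------------------------------------
# Evidence simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SamRead:
    qname: str
    seq_id: str
    pos: int  # 0-based
    cigar: str
    seq: str
    nm: int
    reverse: bool


@dataclass
class Evidence:
    psm_tables: dict[str, list[PSM]]
    transcripts: list[Transcript]
    alignments: dict[str, list[SamRead]]
    quant_records: list[QuantRecord]
    expressed: dict[str, str]


def _expressed_products(truth: SyntheticTruth) -> dict[str, str]:
    skip = {
        f.detail.get("target_gene")
        for f in truth.planted
        if f.kind.startswith(("revised", "splice"))
    }
    expressed = {
        g.gene_id: g.protein
        for g in truth.coding_genes
        if g.protein and g.gene_id not in skip
    }
    expressed.update(truth.products)
    return expressed


def simulate_evidence(
    truth: SyntheticTruth,
    seed: int,
    peptide_detect_prob: float = 1.0,
    n_engines: int = 3,
    mu_target: float = 6.0,
    mu_null: float = 0.0,
    score_sd: float = 1.0,
    disagreement_rate: float = 0.0,
    decoy_frac: float = 0.3,
    spectra_mean: float = 1.0,
    len_range: tuple[int, int] = (7, 45),
    rnaseq_samples: int = 2,
    read_len: int = 100,
    tile_step: int = 30,
    mismatch_rate: float = 0.0,
    quant_reps: int = 2,
    quant_sigma: float = 0.05,
    quant_n_background: int = 10,
) -> Evidence:
    """Simulate the full evidence bundle for a planted truth.

    Expressed proteins (annotated plus planted products) are digested fully
    tryptically; peptides are detected with ``peptide_detect_prob`` and give
    1+Poisson(``spectra_mean``) spectra each.  Every engine scores every
    spectrum from N(``mu_target``, ``score_sd``); decoy PSMs are drawn from
    N(``mu_null``, ``score_sd``) at ``decoy_frac`` of the target spectrum
    count.  Cross-engine disagreement replaces one engine's peptide at rate
    ``disagreement_rate``.  RNA-seq reads are tiled over every expressed
    transcript with a uniform per-base mismatch process (NM computed against
    the genome, so planted variants surface as mismatches).  Reporter
    intensities are log-normal around planted fold changes.
    """
    rng = np.random.default_rng(seed)
    engines = ["msgf", "xtandem", "mascot"][:n_engines]
    expressed = _expressed_products(truth)
    residues = truth.residues()

    # ---- peptide evidence ----
    detected: list[tuple[str, str]] = []  # (protein name, peptide)
    for name in sorted(expressed):
        for pep in digest_tryptic(expressed[name], max_missed=0, len_range=len_range):
            if rng.random() <= peptide_detect_prob:
                detected.append((name, pep.seq))
    peptide_pool = sorted({p for _, p in detected})

    psm_tables: dict[str, list[PSM]] = {e: [] for e in engines}
    spec_no = 0
    for name, peptide in detected:
        n_spectra = 1 + int(rng.poisson(spectra_mean))
        for _ in range(n_spectra):
            spec_no += 1
            sid = f"sp{spec_no:07d}"
            wrong_engine = None
            if disagreement_rate > 0 and rng.random() < disagreement_rate:
                wrong_engine = engines[int(rng.integers(len(engines)))]
            for engine in engines:
                pep = peptide
                if engine == wrong_engine and len(peptide_pool) > 1:
                    while True:
                        alt = peptide_pool[int(rng.integers(len(peptide_pool)))]
                        if alt != peptide:
                            pep = alt
                            break
                psm_tables[engine].append(
                    PSM(sid, pep, engine, float(rng.normal(mu_target, score_sd)), False)
                )
    n_decoys = int(decoy_frac * spec_no)
    for engine in engines:
        for d in range(n_decoys):
            pep = peptide_pool[int(rng.integers(len(peptide_pool)))][::-1]
            psm_tables[engine].append(
                PSM(
                    f"d{engine}{d + 1:07d}", pep, engine,
                    float(rng.normal(mu_null, score_sd)), True,
                )
            )

    # ---- transcripts ----
    transcripts: list[Transcript] = list(truth.transcripts)
    revised_targets = {
        f.detail.get("target_gene")
        for f in truth.planted
        if f.kind.startswith(("revised", "splice"))
    }
    for g in truth.coding_genes:
        if g.protein and g.gene_id not in revised_targets:
            transcripts.append(
                Transcript(
                    f"t_{g.gene_id}",
                    _coding_seq(truth, g.seq_id, g.strand, g.exons),
                    g.seq_id, g.strand, g.exons,
                )
            )
    transcripts.sort(key=lambda t: t.transcript_id)

    # ---- RNA-seq reads ----
    alignments: dict[str, list[SamRead]] = {}
    bases = "ACGT"
    for s in range(rnaseq_samples):
        sample = f"s{s + 1}"
        reads: list[SamRead] = []
        rno = 0
        for t in transcripts:
            if not t.anchored:
                continue
            lt = len(t.seq)
            rl = min(read_len, lt)
            starts = list(range(0, lt - rl + 1, tile_step))
            if starts[-1] != lt - rl:
                starts.append(lt - rl)  # always cover the transcript tail
            for t_a in starts:
                t_b = t_a + rl
                blocks, _j = _map_transcript_span(t_a, t_b, t.blocks, t.strand)
                # read sequence in genome-forward orientation
                fwd = "".join(
                    t.seq[t_a:t_b][::-1].translate(str.maketrans("ACGTN", "TGCAN"))
                ) if t.strand == "-" else t.seq[t_a:t_b]
                seq = list(fwd)
                if mismatch_rate > 0:
                    for k in range(len(seq)):
                        if rng.random() < mismatch_rate:
                            seq[k] = bases[int(rng.integers(4))]
                seq = "".join(seq)
                genome_ref = "".join(residues[t.seq_id][a:b] for a, b in blocks)
                nm = sum(1 for x, y in zip(seq, genome_ref) if x != y)
                cigar_parts = []
                for bi, (a, b) in enumerate(blocks):
                    if bi:
                        cigar_parts.append(f"{a - blocks[bi - 1][1]}N")
                    cigar_parts.append(f"{b - a}M")
                rno += 1
                reads.append(
                    SamRead(
                        f"{sample}_r{rno:06d}", t.seq_id, blocks[0][0],
                        "".join(cigar_parts), seq, nm, t.strand == "-",
                    )
                )
        alignments[sample] = reads

    # ---- reporter-ion quantification ----
    planted_fc: dict[tuple[str, str], float] = {}
    for f in truth.planted:
        if f.kind == "de_protein":
            planted_fc[(f.detail["protein_name"], f.detail["condition"])] = f.detail[
                "fold_change"
            ]
    novel_names = sorted(
        f.name for f in truth.planted if f.kind in ("novel_gene", "pseudogene_expressed")
    )
    background = sorted(
        g.gene_id for g in truth.coding_genes if g.gene_id in expressed
    )
    picks = [
        background[int(i)]
        for i in rng.choice(len(background), size=min(quant_n_background, len(background)), replace=False)
    ]
    peptides_per_protein: dict[str, int] = {}
    for name, _pep in detected:
        peptides_per_protein[name] = peptides_per_protein.get(name, 0) + 1
    quant_records: list[QuantRecord] = []
    conditions = ("N_def", "P_def", "Si_def")
    for name in novel_names + sorted(picks):
        base = float(2.0 ** rng.normal(18.0, 1.0))
        intensities: dict[tuple[str, str], float] = {}
        for cond in ("replete",) + conditions:
            fc = planted_fc.get((name, cond), 1.0)
            for r in range(quant_reps):
                intensities[(cond, f"r{r + 1}")] = base * fc * float(
                    2.0 ** rng.normal(0.0, quant_sigma)
                )
        quant_records.append(
            QuantRecord(name, intensities, peptides_per_protein.get(name, 0))
        )

    return Evidence(psm_tables, transcripts, alignments, quant_records, expressed)


def simulate_score_calibration(
    seed: int,
    n_true: int = 4000,
    n_false: int = 3000,
    n_decoy: int = 3000,
    mu_true: float = 3.5,
    mu_null: float = 0.0,
    sd: float = 1.0,
    engine: str = "msgf",
) -> tuple[list[PSM], set[str]]:
    """Two-Gaussian target-decoy score simulation for FDR calibration: true
    targets from N(mu_true, sd); false targets and decoys i.i.d. from
    N(mu_null, sd).  Returns the PSMs and the spectrum ids of false targets."""
    rng = np.random.default_rng(seed)
    psms: list[PSM] = []
    false_ids: set[str] = set()
    for i, score in enumerate(rng.normal(mu_true, sd, size=n_true)):
        psms.append(PSM(f"t{i:06d}", "TRUEPEPK", engine, float(score), False))
    for i, score in enumerate(rng.normal(mu_null, sd, size=n_false)):
        sid = f"f{i:06d}"
        false_ids.add(sid)
        psms.append(PSM(sid, "FALSEPEPK", engine, float(score), False))
    for i, score in enumerate(rng.normal(mu_null, sd, size=n_decoy)):
        psms.append(PSM(f"d{i:06d}", "KPEPEURT", engine, float(score), True))
    return psms, false_ids


# ---------------------------------------------------------------------------
# Recovery evaluation against planted truth
# ---------------------------------------------------------------------------


def _spans_overlap(call, feature) -> bool:
    if call.seq_id != feature.seq_id or call.strand != feature.strand:
        return False
    a, b = call.intervals[0][0], call.intervals[-1][1]
    c, d = feature.intervals[0][0], feature.intervals[-1][1]
    return min(b, d) - max(a, c) > 0


def evaluate_recovery(truth: SyntheticTruth, calls: Sequence) -> dict:
    """Per-class precision/recall of novelty calls against the planted truth,
    plus pseudogene-flag accuracy and the count of calls matching planted
    high-Hamming-distance SAAV decoys (which should stay at zero)."""
    planted = truth.planted
    by_class: dict[str, list] = {}
    for c in calls:
        by_class.setdefault(c.call_class, []).append(c)

    results: dict[str, float] = {}

    def score(cls: str, features: list, match) -> None:
        cls_calls = by_class.get(cls, [])
        matched_features = set()
        matched_calls = set()
        for f in features:
            for c in cls_calls:
                if match(c, f):
                    matched_features.add(f.name)
                    matched_calls.add(c.call_id)
                    break
        results[f"{cls}_precision"] = (
            len(matched_calls) / len(cls_calls) if cls_calls else 1.0
        )
        results[f"{cls}_recall"] = (
            len(matched_features) / len(features) if features else 1.0
        )

    novel_features = [
        f for f in planted if f.kind in ("novel_gene", "pseudogene_expressed")
    ]
    score(
        "novel_gene",
        novel_features,
        lambda c, f: _spans_overlap(c, f)
        and c.pseudogene_flag == (f.kind == "pseudogene_expressed"),
    )
    flag_ok = 0
    for f in novel_features:
        for c in by_class.get("novel_gene", []):
            if _spans_overlap(c, f):
                flag_ok += c.pseudogene_flag == (f.kind == "pseudogene_expressed")
                break
    results["pseudogene_flag_accuracy"] = (
        flag_ok / len(novel_features) if novel_features else 1.0
    )

    score(
        "revised_gene",
        [f for f in planted if f.kind.startswith("revised")],
        lambda c, f: c.target_gene == f.detail["target_gene"],
    )
    score(
        "novel_splice",
        [f for f in planted if f.kind == "splice_novel"],
        lambda c, f: c.junction == tuple(f.detail["junction"]),
    )
    score(
        "revised_splice",
        [f for f in planted if f.kind == "splice_revised"],
        lambda c, f: c.junction == tuple(f.detail["junction"])
        and c.target_gene == f.detail["target_gene"],
    )
    score(
        "saav",
        [f for f in planted if f.kind == "saav"],
        lambda c, f: c.target_gene == f.detail["target_gene"]
        and list(c.variant_detail) == [tuple(v) for v in f.detail["variants"]],
    )

    decoy_peptides = {
        f.detail["variant_peptide"].replace("I", "L")
        for f in planted
        if f.kind == "saav_decoy"
    }
    results["saav_decoy_false_calls"] = float(
        sum(
            1
            for c in by_class.get("saav", [])
            if c.gssp_peptides & decoy_peptides
        )
    )
    return results


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_quant_table(records: Sequence[QuantRecord], path: str | Path) -> Path:
    path = Path(path)
    channels = sorted({ch for r in records for ch in r.channel_intensities})
    rows = []
    for r in records:
        row = {"protein_id": r.protein_id, "n_unique_peptides": r.n_unique_peptides}
        for cond, rep in channels:
            row[f"{cond}.{rep}"] = r.channel_intensities.get((cond, rep), "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_quant_table(path: str | Path) -> list[QuantRecord]:
    df = pd.read_csv(path, sep="\t")
    channel_cols = [c for c in df.columns if "." in c]
    records = []
    for row in df.itertuples(index=False):
        intensities = {}
        for col in channel_cols:
            cond, rep = col.rsplit(".", 1)
            value = getattr(row, col, None) if col.isidentifier() else row[df.columns.get_loc(col)]
            intensities[(cond, rep)] = float(value)
        records.append(
            QuantRecord(str(row.protein_id), intensities, int(row.n_unique_peptides))
        )
    return records


def write_sam(
    reads: Sequence[SamRead], genome: Sequence[GenomeSequence], path: str | Path
) -> Path:
    path = Path(path)
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for s in genome:
        lines.append(f"@SQ\tSN:{s.seq_id}\tLN:{len(s)}")
    for r in reads:
        flag = 16 if r.reverse else 0
        lines.append(
            "\t".join(
                [
                    r.qname, str(flag), r.seq_id, str(r.pos + 1), "60", r.cigar,
                    "*", "0", "0", r.seq, "*", f"NM:i:{r.nm}",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_truth_json(truth: SyntheticTruth, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "seed": truth.seed,
        "planted": [asdict(f) for f in truth.planted],
        "products": truth.products,
        "n_genes": len(truth.annotation),
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=list) + "\n")
    return path


def write_study(truth: SyntheticTruth, evidence: Evidence, out_dir: str | Path) -> dict:
    """Write the complete synthetic study in the formats the pipeline
    consumes; returns the path manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {}
    manifest["genome"] = str(write_genome(truth.genome, out / "genome.fasta"))
    manifest["annotation"] = str(write_annotation(truth.annotation, out / "annotation.gff3"))
    manifest["transcripts"] = str(
        write_transcripts(evidence.transcripts, out / "transcripts.fasta")
    )
    manifest["psm_tables"] = []
    for engine in sorted(evidence.psm_tables):
        p = write_psm_table(evidence.psm_tables[engine], out / f"psms_{engine}.tsv")
        manifest["psm_tables"].append({"path": str(p), "engine": engine})
    manifest["rnaseq_sams"] = {}
    for sample in sorted(evidence.alignments):
        p = write_sam(evidence.alignments[sample], truth.genome, out / f"rnaseq_{sample}.sam")
        manifest["rnaseq_sams"][sample] = str(p)
    manifest["quant_table"] = str(
        write_quant_table(evidence.quant_records, out / "quant.tsv")
    )
    manifest["truth"] = str(write_truth_json(truth, out / "truth.json"))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
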