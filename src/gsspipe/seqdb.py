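"""Sequence databases for proteogenomic searching.

This module reads the genome, gene annotation and assembled transcripts, and
turns them into the two translated search spaces used for genome reannotation:

* a **six-frame translation** of every genomic sequence, segmented at stop
  codons into stop-to-stop ORFs that carry exact genomic coordinates, and
* a **three-frame translation** of assembled transcripts (forward frames
  only), after discarding transcripts shorter than a minimum length
  (default 50 nt).

It also provides in-silico tryptic digestion and assembly of the combined
target+decoy search database, indexed for exact substring lookup of
I/L-collapsed peptides.

Coordinates are 0-based half-open internally; GFF3 1-based inclusive at I/O
boundaries.  Stop-to-stop (rather than ATG-anchored) ORFs are used because
peptide evidence, not start codons, drives discovery.  Codons containing N
translate to X, and X never matches any peptide residue.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

COMPARTMENTS = ("nuclear", "chloroplast", "mitochondrion", "unmapped")


def _codon_map(table_id: int = 1) -> dict:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for codon in table.stop_codons:
        mapping[codon] = "*"
    return mapping


_CODON_MAPS: dict[int, dict] = {1: _codon_map(1)}


def translate_dna(seq: str, table: int = 1) -> str:
    """Translate DNA codon by codon; any codon containing N (or otherwise
    absent from the code table) yields X.  Trailing partial codons are
    dropped.  Stops are rendered as '*'."""
    mapping = _CODON_MAPS.get(table)
    if mapping is None:
        mapping = _CODON_MAPS.setdefault(table, _codon_map(table))
    n = len(seq) // 3
    get = mapping.get
    return "".join(get(seq[3 * i : 3 * i + 3], "X") for i in range(n))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def collapse_il(seq: str) -> str:
    """Collapse isoleucine onto leucine.  MS cannot distinguish the isobaric
    pair, so all peptide/database comparisons happen in this dialect."""
    return seq.replace("I", "L")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSequence:
    """One genomic sequence (chromosome, organelle or unmapped scaffold)."""

    seq_id: str
    residues: str
    compartment: str = "nuclear"

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"genome sequence {self.seq_id!r} is empty")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware exon structure of an annotated gene.

    ``exons`` are the coding intervals (0-based half-open, ascending on the
    forward strand).  For ``protein_coding`` genes, translating the spliced
    CDS yields ``protein`` (terminal stop excluded).  Pseudogenes carry an
    empty protein.
    """

    gene_id: str
    seq_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "protein_coding"
    protein: str = ""
    untranslatable: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        prev_end = -1
        for start, end in self.exons:
            if not (0 <= start < end):
                raise ValueError(f"gene {self.gene_id}: bad exon ({start},{end})")
            if start < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def spliced_cds(self, residues: str) -> str:
        spliced = "".join(residues[a:b] for a, b in self.exons)
        return reverse_complement(spliced) if self.strand == "-" else spliced

    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )


@dataclass(frozen=True)
class Transcript:
    """An assembled transcript, optionally anchored to the genome by an exon
    chain (``blocks``: genomic intervals in ascending order; for minus-strand
    transcripts the transcript sequence reads through the blocks from the
    highest coordinate downwards, reverse-complemented)."""

    transcript_id: str
    seq: str
    seq_id: str | None = None
    strand: str | None = None
    blocks: tuple[tuple[int, int], ...] | None = None

    @property
    def anchored(self) -> bool:
        return self.blocks is not None and self.seq_id is not None


@dataclass(frozen=True)
class TranslatedORF:
    """A stop-to-stop translation product of a genome or transcript frame.

    Genome ORFs (``source='genome_6frame'``) carry an exact genomic span:
    re-translating ``residues[start:end]`` (strand-adjusted) reproduces
    ``aa_seq``.  Transcript ORFs (``source='transcript_3frame'``) carry
    transcript-relative coordinates plus, when the transcript is anchored,
    the transcript-to-genome exon chain for downstream coordinate mapping.
    """

    orf_id: str
    source: str  # genome_6frame | transcript_3frame
    parent_id: str
    frame: int  # 0-5 genome (0-2 fwd, 3-5 rev); 0-2 transcript
    aa_seq: str
    seq_id: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    t_start: int | None = None
    t_end: int | None = None
    chain: tuple[tuple[int, int], ...] | None = None


@dataclass(frozen=True)
class DbEntry:
    entry_id: str
    aa_seq: str
    origin: str  # predicted | genome_orf | transcript_orf | decoy


class SearchDatabase:
    """Target+decoy amino-acid database with an exact-substring index over
    I/L-collapsed sequences.

    The index concatenates the collapsed sequences of one origin group with a
    separator and answers queries with ``str.find`` plus a bisect over entry
    offsets — exact, simple, and fast enough for desk-scale databases.
    """

    _SEP = "#"

    def __init__(self, entries: Sequence[DbEntry]):
        seen: set[str] = set()
        for e in entries:
            if e.entry_id in seen:
                raise ValueError(f"duplicate entry_id {e.entry_id!r}")
            seen.add(e.entry_id)
        self.entries: tuple[DbEntry, ...] = tuple(entries)
        self.by_id: dict[str, DbEntry] = {e.entry_id: e for e in self.entries}
        self._indexes: dict[frozenset, tuple] = {}

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def targets(self) -> tuple[DbEntry, ...]:
        return tuple(e for e in self.entries if e.origin != "decoy")

    @property
    def decoys(self) -> tuple[DbEntry, ...]:
        return tuple(e for e in self.entries if e.origin == "decoy")

    def _index_for(self, origins: frozenset):
        cached = self._indexes.get(origins)
        if cached is not None:
            return cached
        subset = [e for e in self.entries if e.origin in origins]
        starts: list[int] = []
        chunks: list[str] = []
        pos = 0
        for e in subset:
            starts.append(pos)
            collapsed = collapse_il(e.aa_seq)
            chunks.append(collapsed)
            pos += len(collapsed) + 1
        blob = self._SEP.join(chunks)
        cached = (blob, starts, subset)
        self._indexes[origins] = cached
        return cached

    def lookup(
        self,
        peptide: str,
        origins: Iterable[str] = ("predicted", "genome_orf", "transcript_orf"),
    ) -> list[tuple[str, int]]:
        """All (entry_id, offset) occurrences of the I/L-collapsed peptide in
        entries of the given origins.  Peptides containing X never match."""
        query = collapse_il(peptide)
        if not query or "X" in query or self._SEP in query:
            return []
        blob, starts, subset = self._index_for(frozenset(origins))
        hits: list[tuple[str, int]] = []
        pos = blob.find(query)
        while pos != -1:
            idx = bisect_right(starts, pos) - 1
            entry = subset[idx]
            hits.append((entry.entry_id, pos - starts[idx]))
            pos = blob.find(query, pos + 1)
        return hits


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_genome(
    fasta_path: str | Path,
    compartment_map: Mapping[str, str] | None = None,
) -> list[GenomeSequence]:
    """Read a genome FASTA into validated :class:`GenomeSequence` records.

    Lowercase is normalized to uppercase; residues outside {A,C,G,T,N} are
    rejected with an error naming the offending record.
    """
    path = Path(fasta_path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in records:
        residues = str(rec.seq).upper()
        bad = set(residues) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} contains invalid residues "
                f"{sorted(bad)}"
            )
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        compartment = "nuclear"
        if compartment_map and rec.id in compartment_map:
            compartment = compartment_map[rec.id]
        out.append(GenomeSequence(rec.id, residues, compartment))
    return out


def write_genome(seqs: Sequence[GenomeSequence], fasta_path: str | Path) -> Path:
    path = Path(fasta_path)
    records = [SeqRecord(Seq(s.residues), id=s.seq_id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")
    return path


_GFF_ATTR_RE = re.compile(r"([^;=]+)=([^;]*)")


def _parse_gff_attrs(text: str) -> dict[str, str]:
    return {k.strip(): v.strip() for k, v in _GFF_ATTR_RE.findall(text)}


def read_annotation(
    gff3_path: str | Path,
    genome: Sequence[GenomeSequence],
) -> list[GeneModel]:
    """Read gene models from GFF3.

    Supported dialect: top-level ``gene`` (optionally with ``biotype=``) or
    ``pseudogene`` features with ``ID=``; ``CDS``/``exon`` children pointing at
    the gene directly or through an ``mRNA`` with ``Parent=``.  GFF3 1-based
    inclusive coordinates are converted to 0-based half-open.  Protein
    sequences are derived by translating the spliced CDS; a CDS whose length
    is not divisible by three (or that translates with internal stops) is
    flagged untranslatable with a warning rather than rejected.
    """
    path = Path(gff3_path)
    seq_len = {s.seq_id: len(s) for s in genome}
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    order: list[str] = []
    pending_children: list[tuple[str, str, int, int]] = []

    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
        seqid, _src, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
        start, end = int(start_s) - 1, int(end_s)  # to 0-based half-open
        attrs = _parse_gff_attrs(attr_s)
        if ftype in ("gene", "pseudogene"):
            gid = attrs.get("ID")
            if not gid:
                raise ValueError(f"{path}:{lineno}: {ftype} without ID")
            biotype = attrs.get("biotype", "pseudogene" if ftype == "pseudogene" else "protein_coding")
            genes[gid] = {
                "seq_id": seqid,
                "strand": strand,
                "biotype": biotype,
                "children": [],
            }
            order.append(gid)
        elif ftype == "mRNA":
            tid, parent = attrs.get("ID"), attrs.get("Parent")
            if tid and parent:
                mrna_parent[tid] = parent
        elif ftype in ("CDS", "exon"):
            parent = attrs.get("Parent")
            if parent is None:
                raise ValueError(f"{path}:{lineno}: {ftype} without Parent")
            pending_children.append((parent, seqid, start, end))

    for parent, seqid, start, end in pending_children:
        gid = mrna_parent.get(parent, parent)
        if gid not in genes:
            raise ValueError(f"{path}: feature child of unknown gene {gid!r}")
        if seqid in seq_len and not (0 <= start < end <= seq_len[seqid]):
            raise ValueError(
                f"{path}: gene {gid}: interval [{start},{end}) outside "
                f"sequence {seqid} bounds"
            )
        genes[gid]["children"].append((start, end))

    residues = {s.seq_id: s.residues for s in genome}
    models: list[GeneModel] = []
    for gid in order:
        info = genes[gid]
        exons = tuple(sorted(set(info["children"])))
        if not exons:
            logger.warning("gene %s has no CDS/exon children; skipped", gid)
            continue
        model = GeneModel(
            gene_id=gid,
            seq_id=info["seq_id"],
            strand=info["strand"],
            exons=exons,
            biotype=info["biotype"],
        )
        if info["biotype"] == "protein_coding":
            seq = residues.get(info["seq_id"])
            if seq is None:
                raise ValueError(f"gene {gid}: unknown sequence {info['seq_id']!r}")
            cds = model.spliced_cds(seq)
            if len(cds) % 3 != 0:
                logger.warning("gene %s: CDS length %d not divisible by 3; flagged untranslatable", gid, len(cds))
                model = replace(model, untranslatable=True)
            else:
                protein = translate_dna(cds)
                if protein.endswith("*"):
                    protein = protein[:-1]
                if "*" in protein:
                    logger.warning("gene %s: internal stop in translation; flagged untranslatable", gid)
                    model = replace(model, untranslatable=True)
                else:
                    model = replace(model, protein=protein)
        models.append(model)
    models.sort(key=lambda m: (m.seq_id, m.start, m.gene_id))
    return models


def write_annotation(genes: Sequence[GeneModel], gff3_path: str | Path) -> Path:
    """Write gene models in the same GFF3 dialect :func:`read_annotation`
    consumes (round-trip safe)."""
    path = Path(gff3_path)
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda m: (m.seq_id, m.start, m.gene_id)):
        ftype = "pseudogene" if g.biotype == "pseudogene" else "gene"
        child = "exon" if g.biotype == "pseudogene" else "CDS"
        lines.append(
            "\t".join(
                [
                    g.seq_id, "gsspipe", ftype, str(g.start + 1), str(g.end),
                    ".", g.strand, ".", f"ID={g.gene_id};biotype={g.biotype}",
                ]
            )
        )
        for a, b in g.exons:
            lines.append(
                "\t".join(
                    [
                        g.seq_id, "gsspipe", child, str(a + 1), str(b), ".",
                        g.strand, "0" if child == "CDS" else ".",
                        f"Parent={g.gene_id}",
                    ]
                )
            )
    path.write_text("\n".join(lines) + "\n")
    return path


_ANCHOR_RE = re.compile(r"loc=([^:\s]+):([\d,\-]+):([+-])")


def read_transcripts(fasta_path: str | Path) -> list[Transcript]:
    """Read assembled transcripts; genome anchors are parsed from headers of
    the form ``>tid loc=chr1:101-250,401-700:+`` (1-based inclusive blocks)."""
    path = Path(fasta_path)
    out: list[Transcript] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        seq_id = strand = None
        blocks = None
        m = _ANCHOR_RE.search(rec.description)
        if m:
            seq_id, blocks_s, strand = m.groups()
            blocks = tuple(
                (int(a) - 1, int(b))
                for a, b in (part.split("-") for part in blocks_s.split(","))
            )
        out.append(Transcript(rec.id, seq, seq_id, strand, blocks))
    return out


def write_transcripts(transcripts: Sequence[Transcript], fasta_path: str | Path) -> Path:
    path = Path(fasta_path)
    with open(path, "w") as fh:
        for t in transcripts:
            header = f">{t.transcript_id}"
            if t.anchored:
                blocks_s = ",".join(f"{a + 1}-{b}" for a, b in t.blocks)
                header += f" loc={t.seq_id}:{blocks_s}:{t.strand}"
            fh.write(header + "\n")
            for i in range(0, len(t.seq), 60):
                fh.write(t.seq[i : i + 60] + "\n")
    return path


# ---------------------------------------------------------------------------
# Translation to ORF databases
# ---------------------------------------------------------------------------


def _segment_orfs(protein: str, min_orf_aa: int) -> Iterable[tuple[int, int]]:
    """Yield (aa_start, aa_end) of stop-to-stop segments of length >= min."""
    start = 0
    for i, aa in enumerate(protein):
        if aa == "*":
            if i - start >= min_orf_aa:
                yield (start, i)
            start = i + 1
    if len(protein) - start >= min_orf_aa:
        yield (start, len(protein))


def six_frame_translate(
    seq: GenomeSequence, min_orf_aa: int = 10, table: int = 1
) -> list[TranslatedORF]:
    """Stop-to-stop ORFs from all six reading frames of a genomic sequence.

    Frames 0-2 read the forward strand at offsets 0-2; frames 3-5 read the
    reverse complement at offsets 0-2, with genomic spans reflected back onto
    forward-strand coordinates.
    """
    if min_orf_aa < 1:
        raise ValueError("min_orf_aa must be >= 1")
    length = len(seq.residues)
    orfs: list[TranslatedORF] = []
    for strand, residues in (("+", seq.residues), ("-", reverse_complement(seq.residues))):
        for f in range(3):
            protein = translate_dna(residues[f:], table)
            frame = f if strand == "+" else f + 3
            for aa_a, aa_b in _segment_orfs(protein, min_orf_aa):
                nt_a, nt_b = f + 3 * aa_a, f + 3 * aa_b
                if strand == "+":
                    g_start, g_end = nt_a, nt_b
                else:
                    g_start, g_end = length - nt_b, length - nt_a
                orfs.append(
                    TranslatedORF(
                        orf_id=f"{seq.seq_id}|g{frame}|{g_start}-{g_end}",
                        source="genome_6frame",
                        parent_id=seq.seq_id,
                        frame=frame,
                        aa_seq=protein[aa_a:aa_b],
                        seq_id=seq.seq_id,
                        start=g_start,
                        end=g_end,
                        strand=strand,
                    )
                )
    return orfs


def three_frame_translate(
    transcripts: Iterable[Transcript | tuple[str, str]],
    min_nt: int = 50,
    min_orf_aa: int = 10,
    table: int = 1,
) -> list[TranslatedORF]:
    """Stop-to-stop ORFs from the three forward frames of each transcript.

    Transcripts shorter than ``min_nt`` (default 50 nt) are discarded before
    translation.  Anchored transcripts propagate their genome exon chain onto
    every ORF they emit so peptide hits can later be mapped to the genome.
    """
    orfs: list[TranslatedORF] = []
    for t in transcripts:
        if isinstance(t, tuple):
            t = Transcript(t[0], t[1].upper().replace("U", "T"))
        if len(t.seq) < min_nt:
            continue
        for f in range(3):
            protein = translate_dna(t.seq[f:], table)
            for aa_a, aa_b in _segment_orfs(protein, min_orf_aa):
                t_a, t_b = f + 3 * aa_a, f + 3 * aa_b
                orfs.append(
                    TranslatedORF(
                        orf_id=f"{t.transcript_id}|t{f}|{t_a}-{t_b}",
                        source="transcript_3frame",
                        parent_id=t.transcript_id,
                        frame=f,
                        aa_seq=protein[aa_a:aa_b],
                        seq_id=t.seq_id,
                        strand=t.strand,
                        t_start=t_a,
                        t_end=t_b,
                        chain=t.blocks,
                    )
                )
    return orfs


# ---------------------------------------------------------------------------
# Tryptic digestion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DigestPeptide:
    seq: str
    start: int
    missed: int


def digest_tryptic(
    protein: str,
    max_missed: int = 2,
    len_range: tuple[int, int] = (7, 45),
) -> list[DigestPeptide]:
    """In-silico tryptic digestion: cleave after K or R except before P.

    Returns every peptide with at most ``max_missed`` internal uncut sites and
    length within ``len_range``, once per occurrence with its start offset.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if not protein:
        return []
    lo, hi = len_range
    boundaries = [0]
    for i in range(len(protein) - 1):
        if protein[i] in "KR" and protein[i + 1] != "P":
            boundaries.append(i + 1)
    boundaries.append(len(protein))
    peptides: list[DigestPeptide] = []
    n = len(boundaries) - 1
    for i in range(n):
        for j in range(i + 1, min(i + 2 + max_missed, n + 1)):
            a, b = boundaries[i], boundaries[j]
            if lo <= b - a <= hi:
                peptides.append(DigestPeptide(protein[a:b], a, j - i - 1))
    return peptides


# ---------------------------------------------------------------------------
# Database assembly
# ---------------------------------------------------------------------------


def build_search_database(
    predicted: Sequence[GeneModel] | Sequence[tuple[str, str]],
    genome_orfs: Sequence[TranslatedORF] = (),
    transcript_orfs: Sequence[TranslatedORF] = (),
    decoy_mode: str = "reverse",
) -> SearchDatabase:
    """Assemble the combined predicted + ORF search database with one decoy
    per target (sequence reversal).  Entry origins are preserved so GSSP
    extraction can later distinguish predicted entries from ORF entries."""
    if decoy_mode != "reverse":
        raise ValueError(f"unsupported decoy_mode {decoy_mode!r}")
    entries: list[DbEntry] = []
    for item in predicted:
        if isinstance(item, GeneModel):
            if item.biotype != "protein_coding" or not item.protein:
                continue
            entries.append(DbEntry(item.gene_id, item.protein, "predicted"))
        else:
            entry_id, aa_seq = item
            entries.append(DbEntry(entry_id, aa_seq, "predicted"))
    for orf in genome_orfs:
        entries.append(DbEntry(orf.orf_id, orf.aa_seq, "genome_orf"))
    for orf in transcript_orfs:
        entries.append(DbEntry(orf.orf_id, orf.aa_seq, "transcript_orf"))
    if not entries:
        raise ValueError("no target entries")
    decoys = [
        DbEntry(f"DECOY_{e.entry_id}", e.aa_seq[::-1], "decoy") for e in entries
    ]
    return SearchDatabase(entries + decoys)


def write_database_fasta(db: SearchDatabase, fasta_path: str | Path) -> Path:
    """Write the search database as FASTA with origin-tagged headers
    (``>id|origin=genome_orf|loc=seq:start-end:strand``)."""
    path = Path(fasta_path)
    with open(path, "w") as fh:
        for e in db.entries:
            header = f">{e.entry_id}|origin={e.origin}"
            fh.write(header + "\n")
            for i in range(0, len(e.aa_seq), 60):
                fh.write(e.aa_seq[i : i + 60] + "\n")
    return path
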