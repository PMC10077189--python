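"""GSSP extraction and novelty classification.

A genome-search-specific peptide (GSSP) is a confidently identified peptide
with no I/L-collapsed occurrence in any predicted protein but at least one
occurrence in a translated genome/transcript ORF.  GSSPs are mapped back to
genomic coordinates and consumed by a staged classification:

1. ORFs whose mapped GSSPs overlap no same-strand protein-coding gene and
   carry >= 2 unique GSSPs become **novel genes** (with a pseudogene flag
   when they overlap an annotated pseudogene);
2. ORFs partially overlapping a protein-coding gene with >= 2 unique GSSPs
   become **revised gene models**, with per-peptide sub-evidence (intronic
   peptide, exon-boundary extension, exon merge);
3. remaining GSSPs feed splice-variant detection (junction peptides crossing
   unannotated exon-exon boundaries of anchored transcript ORFs) and
   single-amino-acid-variant detection (equal-length windows of predicted
   proteins at Hamming distance 1-2, no indels).

Each GSSP participates in at most one call class.  Loci that are explained
by a transcript ORF carrying a *novel* splice junction are deferred from
stages 1-2 so the splice stage can claim them (see
:func:`find_novel_junction_deferrals`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .psms import PeptideIdentification
from .seqdb import (
    GeneModel,
    SearchDatabase,
    TranslatedORF,
    collapse_il,
    reverse_complement,
    translate_dna,
)

logger = logging.getLogger(__name__)

CALL_CLASSES = ("novel_gene", "revised_gene", "novel_splice", "revised_splice", "saav")


@dataclass(frozen=True)
class PeptideGenomicMapping:
    """One genomic placement of a GSSP: a single interval for genome-ORF
    occurrences, or a (possibly multi-block) exon chain for anchored
    transcript-ORF occurrences."""

    peptide: str  # I/L-collapsed
    orf_id: str
    seq_id: str | None
    strand: str | None
    blocks: tuple[tuple[int, int], ...]
    offset_in_orf: int
    anchored: bool
    junctions: tuple[tuple[int, int], ...] = ()  # (donor_end, acceptor_start)

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


@dataclass
class GSSP:
    """A confident peptide absent from the predicted proteome, with all its
    ORF occurrences and genomic mappings."""

    peptide_id: PeptideIdentification
    occurrences: tuple[tuple[str, int], ...]  # (orf_id, aa offset)
    mappings: tuple[PeptideGenomicMapping, ...] = ()

    @property
    def key(self) -> str:
        return self.peptide_id.collapsed


@dataclass(frozen=True)
class NoveltyCall:
    """One classified novelty with its supporting evidence."""

    call_id: str
    call_class: str
    seq_id: str | None
    strand: str | None
    intervals: tuple[tuple[int, int], ...]
    gssp_peptides: frozenset[str]
    orf_ids: frozenset[str]
    target_gene: str | None = None
    pseudogene_flag: bool = False
    sub_evidence: frozenset[str] = frozenset()
    variant_detail: tuple[tuple[int, str, str], ...] = ()
    junction: tuple[int, int] | None = None
    rnaseq_supported: bool | None = None
    low_confidence: bool = False

    @property
    def n_gssps(self) -> int:
        return len(self.gssp_peptides)


# ---------------------------------------------------------------------------
# GSSP extraction and genome mapping
# ---------------------------------------------------------------------------


def extract_gssps(
    peptides: Sequence[PeptideIdentification],
    db: SearchDatabase,
) -> tuple[list[GSSP], list[str]]:
    """Split confident peptides into GSSPs and non-novel peptides.

    A peptide is a GSSP iff it has no I/L-collapsed occurrence in any
    predicted entry and at least one occurrence in an ORF entry.  Peptides
    matching neither are returned as orphans (a database-mismatch signal).
    """
    gssps: list[GSSP] = []
    orphans: list[str] = []
    for pep in peptides:
        if db.lookup(pep.collapsed, origins=("predicted",)):
            continue
        orf_hits = db.lookup(pep.collapsed, origins=("genome_orf", "transcript_orf"))
        if not orf_hits:
            orphans.append(pep.peptide)
            continue
        gssps.append(GSSP(peptide_id=pep, occurrences=tuple(sorted(orf_hits))))
    if orphans:
        logger.warning("%d confident peptides match neither predicted nor ORF entries", len(orphans))
    return gssps, orphans


def _map_transcript_span(
    t_a: int, t_b: int, blocks: Sequence[tuple[int, int]], strand: str
) -> tuple[tuple[tuple[int, int], ...], tuple[tuple[int, int], ...]]:
    """Map a transcript nt span [t_a, t_b) through an exon chain to genomic
    blocks (ascending) plus the chain junctions the span crosses."""
    lens = [b - a for a, b in blocks]
    total = sum(lens)
    if not (0 <= t_a < t_b <= total):
        raise ValueError(f"transcript span [{t_a},{t_b}) outside chain of length {total}")
    # walk blocks in transcript order
    order = list(range(len(blocks))) if strand == "+" else list(range(len(blocks) - 1, -1, -1))
    out: list[tuple[int, int]] = []
    cursor = 0
    for bi in order:
        a, b = blocks[bi]
        blen = b - a
        lo = max(t_a - cursor, 0)
        hi = min(t_b - cursor, blen)
        if lo < hi:
            if strand == "+":
                out.append((a + lo, a + hi))
            else:
                out.append((b - hi, b - lo))
        cursor += blen
    out.sort()
    junctions = tuple((out[i][1], out[i + 1][0]) for i in range(len(out) - 1))
    return tuple(out), junctions


def map_gssp_to_genome(
    gssp: GSSP,
    orfs_by_id: Mapping[str, TranslatedORF],
    genome_residues: Mapping[str, str] | None = None,
) -> GSSP:
    """Compute genomic mappings for every ORF occurrence of a GSSP.

    Genome-ORF occurrences become a single interval at
    ``orf_start + 3 * aa_offset`` (mirrored within the span on the minus
    strand).  Anchored transcript-ORF occurrences are pushed through the
    transcript's exon chain; unanchored ones are flagged.  Every mapping is
    verified by re-translation (against the genome when residues are
    provided, always against the ORF's amino-acid sequence).
    """
    peptide = gssp.key
    m = len(peptide)
    mappings: list[PeptideGenomicMapping] = []
    for orf_id, offset in gssp.occurrences:
        orf = orfs_by_id.get(orf_id)
        if orf is None:
            continue
        window = collapse_il(orf.aa_seq[offset : offset + m])
        if window != peptide:
            raise AssertionError(
                f"internal invariant breach: ORF {orf_id} window at {offset} "
                f"does not re-translate to peptide {peptide}"
            )
        if orf.source == "genome_6frame":
            if orf.strand == "+":
                a = orf.start + 3 * offset
                blocks = ((a, a + 3 * m),)
            else:
                b = orf.end - 3 * offset
                blocks = ((b - 3 * m, b),)
            if genome_residues is not None:
                nt = genome_residues[orf.seq_id][blocks[0][0] : blocks[0][1]]
                if orf.strand == "-":
                    nt = reverse_complement(nt)
                if collapse_il(translate_dna(nt)) != peptide:
                    raise AssertionError(
                        f"internal invariant breach: genome re-translation of "
                        f"{orf_id} at {blocks[0]} != {peptide}"
                    )
            mappings.append(
                PeptideGenomicMapping(
                    peptide, orf_id, orf.seq_id, orf.strand, blocks, offset, True
                )
            )
        else:  # transcript_3frame
            t_a = orf.t_start + 3 * offset
            t_b = t_a + 3 * m
            if orf.chain is None or orf.seq_id is None:
                mappings.append(
                    PeptideGenomicMapping(
                        peptide, orf_id, None, None, ((t_a, t_b),), offset, False
                    )
                )
                continue
            blocks, junctions = _map_transcript_span(t_a, t_b, orf.chain, orf.strand)
            mappings.append(
                PeptideGenomicMapping(
                    peptide, orf_id, orf.seq_id, orf.strand, blocks, offset, True,
                    junctions,
                )
            )
    return replace(gssp, mappings=tuple(mappings))


def map_all_gssps(
    gssps: Sequence[GSSP],
    orfs: Sequence[TranslatedORF],
    genome_residues: Mapping[str, str] | None = None,
) -> list[GSSP]:
    orfs_by_id = {o.orf_id: o for o in orfs}
    return [map_gssp_to_genome(g, orfs_by_id, genome_residues) for g in gssps]


# ---------------------------------------------------------------------------
# Annotation geometry helpers
# ---------------------------------------------------------------------------


class _AnnotationIndex:
    def __init__(self, annotation: Sequence[GeneModel]):
        self.genes = {g.gene_id: g for g in annotation}
        self.trees: dict[tuple[str, str], IntervalTree] = {}
        for g in annotation:
            tree = self.trees.setdefault((g.seq_id, g.strand), IntervalTree())
            tree[g.start : g.end] = g.gene_id
        self.junctions: set[tuple[str, int, int]] = set()
        for g in annotation:
            for a, b in g.introns():
                self.junctions.add((g.seq_id, a, b))

    def overlapping(
        self, seq_id: str, strand: str, start: int, end: int, biotype: str | None = None
    ) -> list[GeneModel]:
        tree = self.trees.get((seq_id, strand))
        if tree is None:
            return []
        genes = [self.genes[iv.data] for iv in tree.overlap(start, end)]
        if biotype is not None:
            genes = [g for g in genes if g.biotype == biotype]
        return sorted(genes, key=lambda g: g.gene_id)


def _overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    ivs = sorted(intervals)
    if not ivs:
        return ()
    merged = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return tuple((a, b) for a, b in merged)


# ---------------------------------------------------------------------------
# Splice-junction helpers (shared by deferral and the splice stage)
# ---------------------------------------------------------------------------


def _junction_peptides(
    orf_gssps: Sequence[tuple[GSSP, PeptideGenomicMapping]],
    index: _AnnotationIndex,
    min_flank: int,
) -> list[tuple[GSSP, PeptideGenomicMapping, tuple[int, int]]]:
    """GSSP mappings that cross an *unannotated* chain junction with at least
    ``min_flank`` aa (3*min_flank nt) mapped on each side."""
    out = []
    for gssp, mapping in orf_gssps:
        if not mapping.junctions:
            continue
        for j, (donor, acceptor) in enumerate(mapping.junctions):
            left = sum(b - a for a, b in mapping.blocks if b <= donor)
            right = sum(b - a for a, b in mapping.blocks if a >= acceptor)
            if left < 3 * min_flank or right < 3 * min_flank:
                continue
            if (mapping.seq_id, donor, acceptor) in index.junctions:
                continue
            out.append((gssp, mapping, (donor, acceptor)))
    return out


def find_novel_junction_deferrals(
    gssps: Sequence[GSSP],
    annotation: Sequence[GeneModel],
    min_flank: int = 2,
) -> set[str]:
    """Peptide keys of GSSPs belonging to a transcript ORF that carries a
    novel-junction peptide.  These loci are best explained as splice variants,
    so the novel/revised stages leave them for the splice stage."""
    index = _AnnotationIndex(annotation)
    by_orf: dict[str, list[tuple[GSSP, PeptideGenomicMapping]]] = {}
    for g in gssps:
        for m in g.mappings:
            if m.anchored and m.junctions:
                by_orf.setdefault(m.orf_id, []).append((g, m))
    novel_orfs = {
        orf_id
        for orf_id, pairs in by_orf.items()
        if _junction_peptides(pairs, index, min_flank)
    }
    deferred: set[str] = set()
    for g in gssps:
        if any(m.orf_id in novel_orfs for m in g.mappings):
            deferred.add(g.key)
        else:
            # supporters: peptides co-occurring on the same transcript ORF as
            # a junction peptide, even without a junction of their own
            for orf_id, _ in g.occurrences:
                if orf_id in novel_orfs:
                    deferred.add(g.key)
                    break
    return deferred


# ---------------------------------------------------------------------------
# Stage 1+2: novel and revised gene calls
# ---------------------------------------------------------------------------


def _sub_evidence(
    mapping: PeptideGenomicMapping, gene: GeneModel
) -> tuple[str, int | None]:
    """Classify one GSSP interval against a gene: returns (kind, intron_idx)
    where kind is intron_peptide or exon_extension."""
    start, end = mapping.start, mapping.end
    locus = (gene.start, gene.end)
    if _overlap_len((start, end), locus) == 0:
        return "exon_extension", None  # extension into flank beyond the locus
    exon_overlap = any(_overlap_len((start, end), e) > 0 for e in gene.exons)
    if not exon_overlap:
        for i, (a, b) in enumerate(gene.introns()):
            if start >= a and end <= b:
                return "intron_peptide", i
        return "intron_peptide", None
    return "exon_extension", None


def classify_orfs(
    gssps: Sequence[GSSP],
    annotation: Sequence[GeneModel],
    min_unique: int = 2,
    deferred: Iterable[str] = (),
) -> tuple[list[NoveltyCall], list[GSSP]]:
    """Staged novel/revised classification.

    Stage 1 calls novel genes from ORFs whose GSSP intervals overlap no
    same-strand protein-coding gene (pseudogene overlap sets the pseudogene
    flag).  Stage 2 calls revised gene models from ORFs partially overlapping
    a protein-coding gene (maximal-overlap gene; ties broken by gene id).
    Both require >= ``min_unique`` distinct GSSPs.  Consumed GSSPs are
    removed; the remainder (including any ``deferred`` keys) is returned for
    the splice/SAAV stages.
    """
    index = _AnnotationIndex(annotation)
    deferred = set(deferred)

    by_orf: dict[str, list[tuple[GSSP, PeptideGenomicMapping]]] = {}
    for g in gssps:
        if g.key in deferred:
            continue
        for m in g.mappings:
            if m.anchored:
                by_orf.setdefault(m.orf_id, []).append((g, m))

    claimed: set[str] = set()
    calls: list[NoveltyCall] = []

    def unclaimed(orf_id: str) -> list[tuple[GSSP, PeptideGenomicMapping]]:
        return [(g, m) for g, m in by_orf[orf_id] if g.key not in claimed]

    orf_order = sorted(
        by_orf, key=lambda oid: (-len({g.key for g, _ in by_orf[oid]}), oid)
    )

    # Stage 1: novel genes
    n_novel = 0
    for orf_id in orf_order:
        pairs = unclaimed(orf_id)
        keys = {g.key for g, _ in pairs}
        if len(keys) < min_unique:
            continue
        coding = set()
        pseudo = set()
        for _, m in pairs:
            for gene in index.overlapping(m.seq_id, m.strand, m.start, m.end):
                (pseudo if gene.biotype == "pseudogene" else coding).add(gene.gene_id)
        if coding:
            continue
        n_novel += 1
        seq_id, strand = pairs[0][1].seq_id, pairs[0][1].strand
        calls.append(
            NoveltyCall(
                call_id=f"NG{n_novel:04d}",
                call_class="novel_gene",
                seq_id=seq_id,
                strand=strand,
                intervals=tuple(sorted({iv for _, m in pairs for iv in m.blocks})),
                gssp_peptides=frozenset(keys),
                orf_ids=frozenset({orf_id}),
                pseudogene_flag=bool(pseudo),
                target_gene=sorted(pseudo)[0] if pseudo else None,
            )
        )
        claimed |= keys

    # Stage 2: revised gene models
    n_revised = 0
    for orf_id in orf_order:
        pairs = unclaimed(orf_id)
        keys = {g.key for g, _ in pairs}
        if len(keys) < min_unique:
            continue
        span = (min(m.start for _, m in pairs), max(m.end for _, m in pairs))
        candidates = index.overlapping(
            pairs[0][1].seq_id, pairs[0][1].strand, span[0], span[1],
            biotype="protein_coding",
        )
        if not candidates:
            continue
        target = max(
            candidates,
            key=lambda gene: (_overlap_len(span, (gene.start, gene.end)), gene.gene_id),
        )
        # deterministic tie-break: maximal overlap, then smallest gene_id
        best = _overlap_len(span, (target.start, target.end))
        tied = [
            g for g in candidates
            if _overlap_len(span, (g.start, g.end)) == best
        ]
        target = min(tied, key=lambda g: g.gene_id)

        evidence: set[str] = set()
        intron_hits: set[int] = set()
        for _, m in pairs:
            kind, intron_idx = _sub_evidence(m, target)
            evidence.add(kind)
            if kind == "intron_peptide" and intron_idx is not None:
                intron_hits.add(intron_idx)
        if len(intron_hits) >= 2:
            evidence.add("exon_merge")
        n_revised += 1
        calls.append(
            NoveltyCall(
                call_id=f"RG{n_revised:04d}",
                call_class="revised_gene",
                seq_id=pairs[0][1].seq_id,
                strand=pairs[0][1].strand,
                intervals=tuple(sorted({iv for _, m in pairs for iv in m.blocks})),
                gssp_peptides=frozenset(keys),
                orf_ids=frozenset({orf_id}),
                target_gene=target.gene_id,
                sub_evidence=frozenset(evidence),
            )
        )
        claimed |= keys

    remaining = [g for g in gssps if g.key not in claimed]
    return calls, remaining


# ---------------------------------------------------------------------------
# Stage 3a: splice variants
# ---------------------------------------------------------------------------


def detect_splice_variants(
    remaining: Sequence[GSSP],
    transcript_orfs: Sequence[TranslatedORF],
    annotation: Sequence[GeneModel],
    prior_calls: Sequence[NoveltyCall] = (),
    min_flank: int = 2,
    min_supporting: int = 1,
) -> tuple[list[NoveltyCall], list[GSSP]]:
    """Call splice variants from junction peptides of anchored transcript ORFs.

    A junction peptide crosses a transcript exon-exon junction with at least
    ``min_flank`` aa mapped on each side; the implied (donor, acceptor) pair
    must be absent from the annotation.  A call requires >= 1 junction peptide
    plus >= ``min_supporting`` additional unique GSSPs on the same ORF, and is
    ``novel_splice`` when its locus overlaps no same-strand annotated gene,
    ``revised_splice`` otherwise.  Unanchored transcript ORFs are excluded
    with a warning.
    """
    index = _AnnotationIndex(annotation)
    orf_ids = {o.orf_id for o in transcript_orfs}
    unanchored = {o.orf_id for o in transcript_orfs if o.chain is None}
    if any(
        m.orf_id in unanchored for g in remaining for m in g.mappings if not m.anchored
    ):
        logger.warning("unanchored transcript ORFs excluded from splice detection")

    by_orf: dict[str, list[tuple[GSSP, PeptideGenomicMapping]]] = {}
    for g in remaining:
        for m in g.mappings:
            if m.anchored and m.orf_id in orf_ids:
                by_orf.setdefault(m.orf_id, []).append((g, m))

    claimed: set[str] = set()
    calls: list[NoveltyCall] = []
    n_novel = n_revised = 0
    for orf_id in sorted(by_orf, key=lambda oid: (-len({g.key for g, _ in by_orf[oid]}), oid)):
        pairs = [(g, m) for g, m in by_orf[orf_id] if g.key not in claimed]
        junctions = _junction_peptides(pairs, index, min_flank)
        if not junctions:
            continue
        keys = {g.key for g, _ in pairs}
        junction_keys = {g.key for g, _, _ in junctions}
        if len(keys - junction_keys) < min_supporting:
            continue
        seq_id, strand = pairs[0][1].seq_id, pairs[0][1].strand
        span = (min(m.start for _, m in pairs), max(m.end for _, m in pairs))
        overlapping = index.overlapping(seq_id, strand, span[0], span[1])
        junction = junctions[0][2]
        if overlapping:
            n_revised += 1
            call_id, call_class = f"RS{n_revised:04d}", "revised_splice"
            target = min(overlapping, key=lambda g: g.gene_id).gene_id
        else:
            n_novel += 1
            call_id, call_class = f"NS{n_novel:04d}", "novel_splice"
            target = None
        calls.append(
            NoveltyCall(
                call_id=call_id,
                call_class=call_class,
                seq_id=seq_id,
                strand=strand,
                intervals=tuple(sorted({iv for _, m in pairs for iv in m.blocks})),
                gssp_peptides=frozenset(keys),
                orf_ids=frozenset({orf_id}),
                target_gene=target,
                sub_evidence=frozenset({"junction_peptide"}),
                junction=junction,
            )
        )
        claimed |= keys
    return calls, [g for g in remaining if g.key not in claimed]


# ---------------------------------------------------------------------------
# Stage 3b: single amino acid variants
# ---------------------------------------------------------------------------


def _best_windows(peptide: str, protein_collapsed: str, max_dist: int):
    """Scan equal-length windows; return (best_distance, leftmost position at
    that distance, substitution positions) or None."""
    m = len(peptide)
    best = None
    for pos in range(len(protein_collapsed) - m + 1):
        dist = 0
        for j in range(m):
            if peptide[j] != protein_collapsed[pos + j]:
                dist += 1
                if dist > max_dist:
                    break
        else:
            if best is None or dist < best[0]:
                diffs = tuple(
                    j for j in range(m) if peptide[j] != protein_collapsed[pos + j]
                )
                best = (dist, pos, diffs)
                if dist == 0:
                    break
    return best


def detect_saavs(
    remaining: Sequence[GSSP],
    predicted_proteins: Sequence[tuple[str, str]],
    max_dist: int = 2,
    novel_ids: Iterable[str] = (),
) -> tuple[list[NoveltyCall], list[str]]:
    """Call single amino acid variants from the still-unclaimed GSSPs.

    Each GSSP is scanned against every predicted protein (plus accepted
    novel/revised ORF products, passed in the same list) for an equal-length
    window at I/L-collapsed Hamming distance 1-2 with no indels.  The
    minimum-distance hit wins (leftmost window within a protein); equally
    good hits in *different* proteins are ambiguous — reported, flagged, not
    counted as calls.  Variant details are (1-based protein position,
    reference residue, observed residue), at most two per peptide.
    """
    novel_ids = set(novel_ids)
    collapsed_db = [(pid, seq, collapse_il(seq)) for pid, seq in predicted_proteins]
    calls: list[NoveltyCall] = []
    ambiguous: list[str] = []
    n = 0
    for gssp in sorted(remaining, key=lambda g: g.key):
        peptide = gssp.key
        best_dist = max_dist + 1
        hits: list[tuple[str, str, int, tuple[int, ...]]] = []
        for pid, seq, cseq in collapsed_db:
            found = _best_windows(peptide, cseq, max_dist)
            if found is None:
                continue
            dist, pos, diffs = found
            if dist == 0:
                # exact occurrence in an (augmented) protein: explained, not a SAAV
                hits = []
                best_dist = 0
                break
            if dist < best_dist:
                best_dist = dist
                hits = [(pid, seq, pos, diffs)]
            elif dist == best_dist:
                hits.append((pid, seq, pos, diffs))
        if best_dist == 0 or best_dist > max_dist:
            continue
        if len({pid for pid, *_ in hits}) > 1:
            ambiguous.append(peptide)
            continue
        pid, seq, pos, diffs = hits[0]
        original = gssp.peptide_id.peptide
        detail = tuple(
            (pos + j + 1, seq[pos + j], original[j] if j < len(original) else peptide[j])
            for j in diffs
        )
        n += 1
        mapping = gssp.mappings[0] if gssp.mappings else None
        calls.append(
            NoveltyCall(
                call_id=f"SV{n:04d}",
                call_class="saav",
                seq_id=mapping.seq_id if mapping else None,
                strand=mapping.strand if mapping else None,
                intervals=mapping.blocks if mapping else (),
                gssp_peptides=frozenset({peptide}),
                orf_ids=frozenset(o for o, _ in gssp.occurrences),
                target_gene=pid,
                variant_detail=detail,
                sub_evidence=frozenset({"substitution"}),
                low_confidence=True,  # single variant peptide supports the call
            )
        )
    if ambiguous:
        logger.info("%d SAAV candidates ambiguous across proteins; flagged, not called", len(ambiguous))
    # cross-annotate calls landing on accepted novel/revised products
    calls = [
        replace(c, sub_evidence=c.sub_evidence | {"on_novel_product"})
        if c.target_gene in novel_ids
        else c
        for c in calls
    ]
    return calls, ambiguous
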