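"""Pipeline orchestration, configuration and report writing.

``run_pipeline`` executes the full reannotation flow —
build databases → FDR filter → engine merge → protein inference → GSSP
extraction → novelty classification → RNA-seq validation → augmented-database
re-identification → differential expression — writing every intermediate
table plus a JSON run summary with input/config provenance hashes.  Outputs
are deterministic under a fixed configuration and inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import classify as _classify
from . import psms as _psms
from . import seqdb as _seqdb
from . import synthetic as _synthetic
from . import validate as _validate
from .classify import GSSP, NoveltyCall
from .psms import InferenceResult, PeptideIdentification
from .seqdb import DbEntry, SearchDatabase

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (unknown keys, bad values)."""


@dataclass
class PipelineConfig:
    """All pipeline tunables and input paths; unknown keys are rejected."""

    genome_fasta: str
    annotation_gff3: str
    out_dir: str
    psm_tables: list[dict] = field(default_factory=list)  # {path, engine}
    transcripts_fasta: str | None = None
    rnaseq_sams: dict[str, str] = field(default_factory=dict)  # sample -> path
    quant_table: str | None = None

    fdr_threshold: float = 0.01
    min_orf_aa: int = 10
    min_transcript_nt: int = 50
    max_missed: int = 2
    peptide_len_range: tuple[int, int] = (7, 45)
    decoy_mode: str = "reverse"
    min_gssps: int = 2
    min_flank: int = 2
    saav_max_dist: int = 2
    min_reads: int = 2
    max_mismatches: int = 3
    fc_up: float = 1.5
    fc_down: float = 0.67
    alpha: float = 0.05
    conditions: tuple[str, ...] = ("N_def", "P_def", "Si_def")
    reference: str = "replete"
    seed: int = 0

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = {"genome_fasta", "annotation_gff3", "out_dir"} - set(data)
        if missing:
            raise ConfigError(f"missing config keys: {sorted(missing)}")
        cfg = cls(**{k: v for k, v in data.items()})
        cfg.peptide_len_range = tuple(cfg.peptide_len_range)  # type: ignore[assignment]
        cfg.conditions = tuple(cfg.conditions)  # type: ignore[assignment]
        if not (0 < cfg.fdr_threshold <= 1):
            raise ConfigError("fdr_threshold must be in (0, 1]")
        if cfg.min_orf_aa < 1 or cfg.min_gssps < 1:
            raise ConfigError("min_orf_aa and min_gssps must be >= 1")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunSummary:
    """Per-category counts of one pipeline run plus provenance."""

    n_spectra: int = 0
    n_peptides: int = 0
    n_proteins_identified: int = 0
    n_proteins_multi_peptide: int = 0
    n_proteins_single_peptide: int = 0
    n_gssps: int = 0
    n_orphan_peptides: int = 0
    calls_per_class: dict = field(default_factory=dict)
    n_pseudogene_flagged: int = 0
    n_rnaseq_supported: int = 0
    n_reidentified_novel: int = 0
    n_quantifiable_novel: int = 0
    n_de_calls: int = 0
    de_per_condition: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _file_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

_GFF_TYPES = {
    "novel_gene": "novel_gene",
    "revised_gene": "revised_gene_evidence",
    "novel_splice": "splice_variant",
    "revised_splice": "splice_variant",
    "saav": "saav",
}


def write_calls_gff3(calls: Sequence[NoveltyCall], path: str | Path) -> Path:
    path = Path(path)
    lines = ["##gff-version 3"]
    for c in sorted(calls, key=lambda c: (c.seq_id or "", c.intervals, c.call_id)):
        if c.seq_id is None or not c.intervals:
            continue
        attrs = [
            f"ID={c.call_id}",
            f"call_class={c.call_class}",
            f"n_gssps={c.n_gssps}",
            "peptides=" + ",".join(sorted(c.gssp_peptides)),
        ]
        if c.target_gene:
            attrs.append(f"target_gene={c.target_gene}")
        if c.pseudogene_flag:
            attrs.append("pseudogene=true")
        if c.sub_evidence:
            attrs.append("sub_evidence=" + ",".join(sorted(c.sub_evidence)))
        if c.variant_detail:
            attrs.append(
                "variant=" + ",".join(f"{p}:{r}>{a}" for p, r, a in c.variant_detail)
            )
        if c.junction:
            attrs.append(f"junction={c.junction[0]}-{c.junction[1]}")
        if c.rnaseq_supported is not None:
            attrs.append(f"rnaseq_supported={str(c.rnaseq_supported).lower()}")
        lines.append(
            "\t".join(
                [
                    c.seq_id, "gsspipe", _GFF_TYPES[c.call_class],
                    str(c.intervals[0][0] + 1), str(c.intervals[-1][1]),
                    ".", c.strand or ".", ".", ";".join(attrs),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_reports(
    calls: Sequence[NoveltyCall],
    peptides: Sequence[PeptideIdentification],
    inference: InferenceResult,
    summary: RunSummary,
    out_dir: str | Path,
    support: Sequence[_validate.SupportResult] = (),
    de_calls: Sequence[_validate.DECall] = (),
) -> dict[str, str]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    paths["calls_gff3"] = str(write_calls_gff3(calls, out / "calls.gff3"))

    call_lines = ["call_id\tclass\tseq_id\tstrand\tstart\tend\tn_gssps\ttarget_gene\tpseudogene\tsub_evidence\tvariant\trnaseq_supported"]
    for c in sorted(calls, key=lambda c: c.call_id):
        start = c.intervals[0][0] if c.intervals else ""
        end = c.intervals[-1][1] if c.intervals else ""
        call_lines.append(
            "\t".join(
                str(x)
                for x in [
                    c.call_id, c.call_class, c.seq_id or "", c.strand or "",
                    start, end, c.n_gssps, c.target_gene or "",
                    int(c.pseudogene_flag), ",".join(sorted(c.sub_evidence)),
                    ",".join(f"{p}:{r}>{a}" for p, r, a in c.variant_detail),
                    "" if c.rnaseq_supported is None else int(c.rnaseq_supported),
                ]
            )
        )
    (out / "calls.tsv").write_text("\n".join(call_lines) + "\n")
    paths["calls_tsv"] = str(out / "calls.tsv")

    pep_lines = ["peptide\tq_value\tengines\tn_spectra"]
    for p in sorted(peptides, key=lambda p: p.peptide):
        pep_lines.append(
            f"{p.peptide}\t{p.q_value:.6g}\t{','.join(sorted(p.engines))}\t{len(p.supporting_spectra)}"
        )
    (out / "peptides.tsv").write_text("\n".join(pep_lines) + "\n")
    paths["peptides_tsv"] = str(out / "peptides.tsv")

    prot_lines = ["entry_id\tn_unique\tn_shared\tcoverage_pct\tconfidence"]
    for pr in sorted(inference.proteins, key=lambda p: p.entry_id):
        prot_lines.append(
            f"{pr.entry_id}\t{len(pr.unique_peptides)}\t{len(pr.shared_peptides)}"
            f"\t{pr.coverage_pct}\t{pr.confidence}"
        )
    (out / "proteins.tsv").write_text("\n".join(prot_lines) + "\n")
    paths["proteins_tsv"] = str(out / "proteins.tsv")

    if support:
        sup_lines = ["call_id\tn_supporting_reads\tsupported\tper_sample"]
        for s in sorted(support, key=lambda s: s.call_id):
            per = ",".join(f"{name}:{int(ok)}" for name, ok in s.per_sample_support)
            val = "" if s.supported is None else int(s.supported)
            sup_lines.append(f"{s.call_id}\t{s.n_supporting_reads}\t{val}\t{per}")
        (out / "support.tsv").write_text("\n".join(sup_lines) + "\n")
        paths["support_tsv"] = str(out / "support.tsv")

    if de_calls:
        de_lines = ["protein_id\tcondition\tmean_fold_change\tp_value\tregulation"]
        for d in sorted(de_calls, key=lambda d: (d.protein_id, d.condition)):
            de_lines.append(
                f"{d.protein_id}\t{d.condition}\t{d.mean_fold_change:.6g}"
                f"\t{d.p_value:.6g}\t{d.regulation}"
            )
        (out / "de.tsv").write_text("\n".join(de_lines) + "\n")
        paths["de_tsv"] = str(out / "de.tsv")

    (out / "summary.json").write_text(
        json.dumps(summary.to_dict(), indent=1, sort_keys=True, default=list) + "\n"
    )
    paths["summary_json"] = str(out / "summary.json")
    return paths


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    """Rich result of one pipeline run (the summary plus the objects the
    reports were written from)."""

    summary: RunSummary
    calls: tuple[NoveltyCall, ...]
    peptides: tuple[PeptideIdentification, ...]
    inference: InferenceResult
    support: tuple = ()
    de_calls: tuple = ()


def run_pipeline(config: PipelineConfig) -> RunSummary:
    """Execute the full reannotation pipeline for one configured study."""
    return run_pipeline_result(config).summary


def run_pipeline_result(config: PipelineConfig) -> PipelineResult:
    """As :func:`run_pipeline`, returning the full result objects."""
    summary = RunSummary()
    stage = "read-inputs"
    try:
        genome = _seqdb.read_genome(config.genome_fasta)
        annotation = _seqdb.read_annotation(config.annotation_gff3, genome)
        transcripts = (
            _seqdb.read_transcripts(config.transcripts_fasta)
            if config.transcripts_fasta
            else []
        )

        stage = "build-db"
        genome_orfs = [
            orf
            for seq in genome
            for orf in _seqdb.six_frame_translate(seq, config.min_orf_aa)
        ]
        transcript_orfs = _seqdb.three_frame_translate(
            transcripts, config.min_transcript_nt, config.min_orf_aa
        )
        db = _seqdb.build_search_database(
            annotation, genome_orfs, transcript_orfs, config.decoy_mode
        )

        stage = "filter-psms"
        per_engine: list[list[_psms.PSM]] = []
        for item in config.psm_tables:
            table = _psms.read_psm_table(item["path"], item["engine"])
            with_q = _psms.estimate_qvalues(table)
            per_engine.append(_psms.filter_qvalue(with_q, config.fdr_threshold))

        stage = "merge-engines"
        peptides = _psms.merge_engines(per_engine)
        summary.n_peptides = len(peptides)
        summary.n_spectra = len(
            {sid for p in peptides for sid in p.supporting_spectra}
        )

        stage = "infer-proteins"
        inference = _psms.infer_proteins(peptides, db, origins=("predicted",))
        summary.n_proteins_identified = len(inference.proteins)
        summary.n_proteins_multi_peptide = sum(
            1 for p in inference.proteins if p.confidence == "multi_peptide"
        )
        summary.n_proteins_single_peptide = sum(
            1 for p in inference.proteins if p.confidence == "single_peptide_flagged"
        )

        stage = "extract-gssps"
        gssps, orphans = _classify.extract_gssps(peptides, db)
        all_orfs = genome_orfs + transcript_orfs
        residues = {s.seq_id: s.residues for s in genome}
        gssps = _classify.map_all_gssps(gssps, all_orfs, residues)
        summary.n_gssps = len(gssps)
        summary.n_orphan_peptides = len(orphans)

        stage = "classify"
        deferred = _classify.find_novel_junction_deferrals(
            gssps, annotation, config.min_flank
        )
        gene_calls, remaining = _classify.classify_orfs(
            gssps, annotation, config.min_gssps, deferred
        )
        splice_calls, remaining = _classify.detect_splice_variants(
            remaining, transcript_orfs, annotation, gene_calls, config.min_flank
        )
        accepted = gene_calls + splice_calls
        orfs_by_id = {o.orf_id: o for o in all_orfs}
        novel_products: list[tuple[str, str]] = []
        for call in accepted:
            orf_id = sorted(call.orf_ids)[0]
            novel_products.append((call.call_id, orfs_by_id[orf_id].aa_seq))
        saav_space = [
            (g.gene_id, g.protein) for g in annotation if g.protein
        ] + novel_products
        saav_calls, ambiguous_saavs = _classify.detect_saavs(
            remaining, saav_space, config.saav_max_dist,
            novel_ids={cid for cid, _ in novel_products},
        )
        calls = accepted + saav_calls
        summary.calls_per_class = {
            cls: sum(1 for c in calls if c.call_class == cls)
            for cls in _classify.CALL_CLASSES
        }
        summary.n_pseudogene_flagged = sum(1 for c in calls if c.pseudogene_flag)

        stage = "validate-rnaseq"
        support: list[_validate.SupportResult] = []
        if config.rnaseq_sams:
            alignments = {
                sample: _validate.read_alignments(path)
                for sample, path in sorted(config.rnaseq_sams.items())
            }
            by_id = {}
            for call in calls:
                res = _validate.assess_support(
                    call, alignments, config.min_reads, config.max_mismatches
                )
                support.append(res)
                by_id[call.call_id] = res.supported
            calls = [
                dataclasses.replace(c, rnaseq_supported=by_id.get(c.call_id))
                for c in calls
            ]
            summary.n_rnaseq_supported = sum(
                1 for s in support if s.supported
            )

        stage = "reidentify"
        augmented = SearchDatabase(
            [DbEntry(g.gene_id, g.protein, "predicted") for g in annotation if g.protein]
            + [DbEntry(cid, seq, "predicted") for cid, seq in novel_products]
        )
        reident, quantifiable = _validate.reidentify_against_augmented_db(
            [
                _psms.read_psm_table(item["path"], item["engine"])
                for item in config.psm_tables
            ],
            augmented,
            novel_ids={cid for cid, _ in novel_products},
            fdr_threshold=config.fdr_threshold,
        )
        novel_ids = {cid for cid, _ in novel_products}
        summary.n_reidentified_novel = sum(
            1 for p in reident.proteins if p.entry_id in novel_ids
        )
        summary.n_quantifiable_novel = len(quantifiable)

        stage = "quantify"
        de_calls: list[_validate.DECall] = []
        if config.quant_table:
            records = _synthetic.read_quant_table(config.quant_table)
            de_calls = _validate.call_de_table(
                records, config.conditions, config.reference,
                config.fc_up, config.fc_down, config.alpha,
            )
            regulated = [d for d in de_calls if d.regulation != "unchanged"]
            summary.n_de_calls = len({d.protein_id for d in regulated})
            summary.de_per_condition = {
                cond: len({d.protein_id for d in regulated if d.condition == cond})
                for cond in config.conditions
            }

        stage = "write-reports"
        summary.provenance = {
            "config_hash": config.config_hash(),
            "inputs": {
                "genome": _file_hash(config.genome_fasta),
                "annotation": _file_hash(config.annotation_gff3),
                **(
                    {"transcripts": _file_hash(config.transcripts_fasta)}
                    if config.transcripts_fasta
                    else {}
                ),
                "psm_tables": [
                    _file_hash(item["path"]) for item in config.psm_tables
                ],
            },
            "version": _package_version(),
        }
        write_reports(
            calls, peptides, inference, summary, config.out_dir, support, de_calls
        )
        return PipelineResult(
            summary, tuple(calls), tuple(peptides), inference, tuple(support),
            tuple(de_calls),
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _package_version() -> str:
    from . import __version__

    return __version__
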