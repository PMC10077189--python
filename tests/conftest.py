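"""Shared fixtures: a small planted synthetic study reused across suites."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

import gsspipe as g

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

SMALL_COUNTS = {
    "novel_gene": 2,
    "pseudogene_expressed": 1,
    "revised_intron": 1,
    "revised_merge": 1,
    "revised_extension": 1,
    "splice_novel": 1,
    "splice_revised": 1,
    "saav": 2,
    "saav_decoy": 1,
    "de_protein": 1,
}


@pytest.fixture(scope="session")
def small_truth() -> g.SyntheticTruth:
    truth = g.generate_genome(1, n_chromosomes=2, n_genes=12, genome_length=200_000)
    return g.plant_novelties(truth, SMALL_COUNTS, seed=2)


@pytest.fixture(scope="session")
def small_evidence(small_truth) -> g.Evidence:
    return g.simulate_evidence(small_truth, seed=3)


@pytest.fixture(scope="session")
def study_dir(small_truth, small_evidence, tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    manifest = g.write_study(small_truth, small_evidence, out)
    return manifest


@pytest.fixture(scope="session")
def small_run(study_dir, tmp_path_factory):
    """One full pipeline run over the small study; (config, summary, out_dir)."""
    out_dir = tmp_path_factory.mktemp("run")
    cfg = g.PipelineConfig.from_dict(
        {
            "genome_fasta": study_dir["genome"],
            "annotation_gff3": study_dir["annotation"],
            "transcripts_fasta": study_dir["transcripts"],
            "psm_tables": study_dir["psm_tables"],
            "rnaseq_sams": study_dir["rnaseq_sams"],
            "quant_table": study_dir["quant_table"],
            "out_dir": str(out_dir),
        }
    )
    summary = g.run_pipeline(cfg)
    return cfg, summary, out_dir


@pytest.fixture(scope="session")
def small_dbs(small_truth, small_evidence):
    """Search database plus ORF lists for the small study."""
    truth = small_truth
    genome_orfs = [o for s in truth.genome for o in g.six_frame_translate(s)]
    t_orfs = g.three_frame_translate(small_evidence.transcripts)
    db = g.build_search_database(truth.annotation, genome_orfs, t_orfs)
    return db, genome_orfs, t_orfs


@pytest.fixture(scope="session")
def small_gssps(small_truth, small_evidence, small_dbs):
    """Mapped GSSPs for the small study (post-FDR, post-merge)."""
    db, genome_orfs, t_orfs = small_dbs
    per_engine = [
        g.filter_qvalue(g.estimate_qvalues(psms), 0.01)
        for psms in small_evidence.psm_tables.values()
    ]
    peptides = g.merge_engines(per_engine)
    gssps, orphans = g.extract_gssps(peptides, db)
    gssps = g.map_all_gssps(gssps, genome_orfs + t_orfs, small_truth.residues())
    return peptides, gssps, orphans
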