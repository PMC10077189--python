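"""RNA-seq and quantitative-proteomics validation of novelty calls.

RNA-seq support follows a deterministic reading of the study's visual
verification rule: a read supports a call iff it aligns with at most three
mismatches and covers at least half of one of the call's evidence intervals
(splice calls instead require the read's block chain to reproduce the exact
junction).  A call is supported when at least ``min_reads`` such reads exist
in at least one sample.

Quantitative validation re-attributes the PSM evidence against the augmented
database (predicted proteins + accepted novel products); novel proteins
re-identified with >= 2 unique peptides are quantifiable.  Differential
expression of reporter-ion data uses per-replicate condition/reference
ratios: a protein is regulated when the arithmetic mean fold change exceeds
1.5 (or falls below 0.67) and a two-sided one-sample t-test of the log2
ratios against zero gives P < 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from scipy import stats

from .classify import NoveltyCall, _overlap_len
from .psms import (
    PSM,
    InferenceResult,
    estimate_qvalues,
    filter_qvalue,
    infer_proteins,
    merge_engines,
)
from .seqdb import SearchDatabase

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadAlignment:
    read_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    blocks: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class SupportResult:
    call_id: str
    n_supporting_reads: int
    supported: bool | None
    per_sample_support: tuple[tuple[str, bool], ...]


@dataclass(frozen=True)
class QuantRecord:
    protein_id: str
    channel_intensities: Mapping[tuple[str, str], float]  # (condition, replicate)
    n_unique_peptides: int


@dataclass(frozen=True)
class DECall:
    protein_id: str
    condition: str
    mean_fold_change: float
    p_value: float
    regulation: str  # up | down | unchanged


# ---------------------------------------------------------------------------
# RNA-seq alignments
# ---------------------------------------------------------------------------


def _mismatches_from_md(md: str) -> int:
    count = 0
    i = 0
    while i < len(md):
        c = md[i]
        if c.isdigit():
            i += 1
        elif c == "^":  # deletion run
            i += 1
            while i < len(md) and md[i].isalpha():
                i += 1
        else:
            count += 1
            i += 1
    return count


def read_alignments(sam_path: str | Path) -> list[ReadAlignment]:
    """Read a SAM file into :class:`ReadAlignment` records.

    Unmapped, secondary and supplementary records are skipped.  Mismatch
    counts come from the NM tag (MD fallback); records with neither are
    skipped with a warning.  CIGAR N operations split the alignment into
    spliced blocks; coordinates are 0-based half-open.
    """
    out: list[ReadAlignment] = []
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            elif rec.has_tag("MD"):
                nm = _mismatches_from_md(str(rec.get_tag("MD")))
            else:
                logger.warning("read %s lacks NM and MD tags; skipped", rec.query_name)
                continue
            blocks: list[tuple[int, int]] = []
            pos = rec.reference_start
            cur_start = pos
            for op, length in rec.cigartuples or ():
                if op in (0, 7, 8):  # M, =, X consume both
                    pos += length
                elif op == 2:  # D consumes reference, stays in block
                    pos += length
                elif op == 3:  # N: splice — close the block
                    blocks.append((cur_start, pos))
                    pos += length
                    cur_start = pos
                # I, S, H, P consume no reference
            blocks.append((cur_start, pos))
            out.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    seq_id=rec.reference_name,
                    start=rec.reference_start,
                    end=pos,
                    strand="-" if rec.is_reverse else "+",
                    mismatches=nm,
                    blocks=tuple(blocks),
                )
            )
    return out


def _read_supports(
    read: ReadAlignment,
    call: NoveltyCall,
    max_mismatches: int,
    min_overlap_frac: float,
) -> bool:
    if read.seq_id != call.seq_id or read.mismatches > max_mismatches:
        return False
    if call.junction is not None:
        adjacencies = {
            (read.blocks[i][1], read.blocks[i + 1][0])
            for i in range(len(read.blocks) - 1)
        }
        return call.junction in adjacencies
    for iv in call.intervals:
        length = iv[1] - iv[0]
        if length <= 0:
            continue
        covered = sum(_overlap_len(iv, b) for b in read.blocks)
        if covered / length >= min_overlap_frac:
            return True
    return False


def assess_support(
    call: NoveltyCall,
    alignments_by_sample: Mapping[str, Sequence[ReadAlignment]],
    min_reads: int = 2,
    max_mismatches: int = 3,
    min_overlap_frac: float = 0.5,
) -> SupportResult:
    """RNA-seq support for one call: reads with <= ``max_mismatches``
    mismatches covering >= half of an evidence interval (or reproducing the
    exact splice junction) count; >= ``min_reads`` such reads in any sample
    support the call.  Calls without genome anchors yield null support."""
    if call.seq_id is None or not call.intervals:
        logger.warning("call %s has no genome anchor; support undefined", call.call_id)
        return SupportResult(call.call_id, 0, None, ())
    per_sample: list[tuple[str, bool]] = []
    total = 0
    for sample in sorted(alignments_by_sample):
        count = sum(
            1
            for read in alignments_by_sample[sample]
            if _read_supports(read, call, max_mismatches, min_overlap_frac)
        )
        total += count
        per_sample.append((sample, count >= min_reads))
    return SupportResult(
        call.call_id, total, any(ok for _, ok in per_sample), tuple(per_sample)
    )


# ---------------------------------------------------------------------------
# Re-identification against the augmented database
# ---------------------------------------------------------------------------


def reidentify_against_augmented_db(
    psm_lists: Sequence[Sequence[PSM]],
    augmented_db: SearchDatabase,
    novel_ids: Iterable[str],
    fdr_threshold: float = 0.01,
) -> tuple[InferenceResult, set[str]]:
    """Re-run the identification stages against the augmented database
    (predicted entries + accepted novel products) and mark novel proteins
    re-identified with >= 2 unique peptides as quantifiable."""
    novel_ids = set(novel_ids)
    filtered = [
        filter_qvalue(estimate_qvalues(psms), fdr_threshold) for psms in psm_lists
    ]
    peptides = merge_engines(filtered)
    inference = infer_proteins(peptides, augmented_db, origins=("predicted",))
    quantifiable = {
        p.entry_id
        for p in inference.proteins
        if p.entry_id in novel_ids and len(p.unique_peptides) >= 2
    }
    return inference, quantifiable


# ---------------------------------------------------------------------------
# Differential expression of reporter-ion data
# ---------------------------------------------------------------------------


def call_de(
    record: QuantRecord,
    condition: str,
    reference: str,
    fc_up: float = 1.5,
    fc_down: float = 0.67,
    alpha: float = 0.05,
) -> DECall:
    """Differential-expression call for one protein and condition.

    Per-replicate ratios (condition / reference, paired by replicate label)
    give the arithmetic-mean fold change; significance is a two-sided
    one-sample t-test of the log2 ratios against zero.  Regulation gates are
    strict: up iff FC > ``fc_up`` and P < ``alpha``; down iff FC < ``fc_down``
    and P < ``alpha``.
    """
    cond = {
        rep: v for (c, rep), v in record.channel_intensities.items() if c == condition
    }
    ref = {
        rep: v for (c, rep), v in record.channel_intensities.items() if c == reference
    }
    reps = sorted(set(cond) & set(ref))
    if len(reps) < 2:
        raise ValueError(
            f"protein {record.protein_id}: need >= 2 paired replicates for "
            f"{condition} vs {reference}, found {len(reps)}"
        )
    ratios = np.array([cond[r] / ref[r] for r in reps], dtype=float)
    if np.any(ratios <= 0):
        raise ValueError(f"protein {record.protein_id}: non-positive intensity ratio")
    mean_fc = float(np.mean(ratios))
    log_ratios = np.log2(ratios)
    if np.allclose(log_ratios.std(ddof=1), 0.0):
        p_value = 1.0 if math.isclose(float(log_ratios.mean()), 0.0, abs_tol=1e-12) else 0.0
    else:
        p_value = float(stats.ttest_1samp(log_ratios, 0.0).pvalue)
    if mean_fc > fc_up and p_value < alpha:
        regulation = "up"
    elif mean_fc < fc_down and p_value < alpha:
        regulation = "down"
    else:
        regulation = "unchanged"
    return DECall(record.protein_id, condition, mean_fc, p_value, regulation)


def call_de_table(
    records: Sequence[QuantRecord],
    conditions: Sequence[str],
    reference: str,
    fc_up: float = 1.5,
    fc_down: float = 0.67,
    alpha: float = 0.05,
    min_unique_peptides: int = 2,
) -> list[DECall]:
    """DE calls for every quantifiable record across all test conditions."""
    calls: list[DECall] = []
    for rec in records:
        if rec.n_unique_peptides < min_unique_peptides:
            continue
        for cond in conditions:
            calls.append(call_de(rec, cond, reference, fc_up, fc_down, alpha))
    return calls
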