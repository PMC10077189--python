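"""Peptide-spectrum-match ingestion, FDR control and protein inference.

PSM tables from multiple search engines (MSGF+, X!Tandem, Mascot, ...) are
consumed as TSV, filtered to a target-decoy q-value threshold (default 1%)
*within each engine* — engine scores are never compared across engines — and
then merged: any spectrum assigned non-identical I/L-collapsed peptides by
different engines is discarded entirely.  Surviving peptides are aggregated
and attributed to database entries; proteins with >= 2 unique peptides are
confidently identified, single-unique-peptide proteins are flagged for
review, and proteins carrying only shared peptides are reported separately
as ambiguous.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqdb import AA_ALPHABET, SearchDatabase, collapse_il

logger = logging.getLogger(__name__)

ENGINES = ("msgf", "xtandem", "mascot", "other")

#: Modification-stripping grammar: bracketed tags ("[+79.97]", "(Oxidation)")
#: and bare signed mass deltas ("+57.021") are removed from peptide strings.
_MOD_RE = re.compile(r"\[[^\]]*\]|\([^)]*\)|[+-]\d+(?:\.\d+)?")

REQUIRED_COLUMNS = ("spectrum_id", "peptide", "score", "is_decoy")


@dataclass(frozen=True)
class PSM:
    """One spectrum-to-peptide assignment (rank 1 within its engine)."""

    spectrum_id: str
    peptide: str
    engine: str
    score: float
    is_decoy: bool
    charge: int = 2
    q_value: float | None = None


@dataclass(frozen=True)
class PeptideIdentification:
    """A confident peptide aggregated over engines and spectra."""

    peptide: str
    collapsed: str
    supporting_spectra: frozenset[str]
    engines: frozenset[str]
    best_score: float
    q_value: float


@dataclass(frozen=True)
class ProteinIdentification:
    entry_id: str
    unique_peptides: frozenset[str]
    shared_peptides: frozenset[str]
    coverage_pct: float
    confidence: str  # multi_peptide | single_peptide_flagged


@dataclass(frozen=True)
class InferenceResult:
    proteins: tuple[ProteinIdentification, ...]
    ambiguous: tuple[str, ...]  # entries with shared peptides only


def strip_modifications(peptide: str) -> str:
    return _MOD_RE.sub("", peptide).strip().upper()


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("1", "true", "t", "yes"):
        return True
    if text in ("0", "false", "f", "no", ""):
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def read_psm_table(path: str | Path, engine: str) -> list[PSM]:
    """Read one engine's PSM TSV (columns: spectrum_id, peptide, score,
    is_decoy; optional protein_ids, charge).  Modification annotations are
    stripped; only the rank-1 (highest-scoring) PSM per spectrum is kept."""
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    scores = pd.to_numeric(df["score"], errors="coerce")
    bad = scores.isna() & df["score"].notna()
    if bad.any():
        lineno = int(bad.idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path}:{lineno}: non-numeric score {df['score'][bad.idxmax()]!r}")
    df = df.assign(score_parsed=scores)

    psms: dict[str, PSM] = {}
    for row in df.itertuples(index=False):
        peptide = strip_modifications(str(row.peptide))
        if not peptide or set(peptide) - AA_ALPHABET:
            raise ValueError(f"{path}: invalid peptide {row.peptide!r}")
        psm = PSM(
            spectrum_id=str(row.spectrum_id),
            peptide=peptide,
            engine=engine,
            score=float(row.score_parsed),
            is_decoy=_parse_bool(row.is_decoy),
            charge=int(getattr(row, "charge", 2) or 2),
        )
        prev = psms.get(psm.spectrum_id)
        if prev is None or psm.score > prev.score:
            psms[psm.spectrum_id] = psm
    return list(psms.values())


def write_psm_table(psms: Sequence[PSM], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "spectrum_id": [p.spectrum_id for p in psms],
            "peptide": [p.peptide for p in psms],
            "score": [p.score for p in psms],
            "is_decoy": [int(p.is_decoy) for p in psms],
            "charge": [p.charge for p in psms],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def estimate_qvalues(psms: Sequence[PSM]) -> list[PSM]:
    """Target-decoy q-values, computed per engine.

    PSMs are sorted by descending score; at each threshold
    ``FDR_est = (#decoys >= t) / (#targets >= t)`` and the q-value is the
    running minimum of FDR_est taken from the permissive end.  Ties share the
    FDR of their full tie group.
    """
    out: list[PSM] = []
    by_engine: dict[str, list[PSM]] = {}
    for p in psms:
        by_engine.setdefault(p.engine, []).append(p)
    for engine, group in by_engine.items():
        n = len(group)
        scores = np.array([p.score for p in group], dtype=float)
        decoy = np.array([p.is_decoy for p in group], dtype=bool)
        if not decoy.any():
            logger.warning("engine %s: zero decoys; q-values uncalibrated (all 0)", engine)
            out.extend(replace(p, q_value=0.0) for p in group)
            continue
        order = np.argsort(-scores, kind="stable")
        s_sorted = scores[order]
        d_cum = np.cumsum(decoy[order])
        t_cum = np.cumsum(~decoy[order])
        # tie groups: use cumulative counts at the *end* of each tie run
        is_last = np.ones(n, dtype=bool)
        is_last[:-1] = s_sorted[:-1] != s_sorted[1:]
        ends = np.empty(n, dtype=int)
        current = n - 1
        for i in range(n - 1, -1, -1):
            if is_last[i]:
                current = i
            ends[i] = current
        with np.errstate(divide="ignore", invalid="ignore"):
            fdr = np.where(t_cum[ends] > 0, d_cum[ends] / t_cum[ends], 1.0)
        fdr = np.minimum(fdr, 1.0)
        qvals = np.minimum.accumulate(fdr[::-1])[::-1]
        q_by_pos = np.empty(n)
        q_by_pos[order] = qvals
        out.extend(replace(p, q_value=float(q)) for p, q in zip(group, q_by_pos))
    return out


def filter_qvalue(psms: Iterable[PSM], threshold: float = 0.01) -> list[PSM]:
    """Retain target PSMs at q <= threshold (decoys are dropped here)."""
    return [p for p in psms if not p.is_decoy and p.q_value is not None and p.q_value <= threshold]


def merge_engines(per_engine: Sequence[Sequence[PSM]]) -> list[PeptideIdentification]:
    """Merge already-filtered per-engine PSM lists into peptide identifications.

    Peptides are compared I/L-collapsed.  Any spectrum assigned non-identical
    collapsed peptides by different engines is discarded entirely; surviving
    PSMs are aggregated per collapsed peptide (union of engines and spectra).
    """
    all_psms = [p for group in per_engine for p in group if not p.is_decoy]
    assignments: dict[str, set[str]] = {}
    for p in all_psms:
        assignments.setdefault(p.spectrum_id, set()).add(collapse_il(p.peptide))
    conflicted = {sid for sid, peps in assignments.items() if len(peps) > 1}
    if conflicted:
        logger.info("discarding %d spectra with cross-engine peptide conflicts", len(conflicted))

    grouped: dict[str, list[PSM]] = {}
    for p in all_psms:
        if p.spectrum_id in conflicted:
            continue
        grouped.setdefault(collapse_il(p.peptide), []).append(p)

    out: list[PeptideIdentification] = []
    for collapsed in sorted(grouped):
        group = grouped[collapsed]
        out.append(
            PeptideIdentification(
                peptide=min(p.peptide for p in group),
                collapsed=collapsed,
                supporting_spectra=frozenset(p.spectrum_id for p in group),
                engines=frozenset(p.engine for p in group),
                best_score=max(p.score for p in group),
                q_value=min(
                    (p.q_value for p in group if p.q_value is not None), default=0.0
                ),
            )
        )
    return out


def compute_coverage(protein: str, peptides: Iterable[str]) -> float:
    """Percent of protein residues covered by >= 1 peptide occurrence
    (I/L-collapsed matching; all occurrences counted, overlaps once),
    rounded to 0.1."""
    if not protein:
        return 0.0
    target = collapse_il(protein)
    mask = np.zeros(len(target), dtype=bool)
    for pep in peptides:
        query = collapse_il(pep)
        pos = target.find(query)
        if pos == -1:
            logger.warning("peptide %s not found in protein; ignored for coverage", pep)
            continue
        while pos != -1:
            mask[pos : pos + len(query)] = True
            pos = target.find(query, pos + 1)
    return round(100.0 * mask.sum() / len(target), 1)


def infer_proteins(
    peptides: Sequence[PeptideIdentification],
    db: SearchDatabase,
    origins: Iterable[str] = ("predicted",),
) -> InferenceResult:
    """Attribute peptides to database entries and call protein identifications.

    A peptide is *unique* iff it occurs (I/L-collapsed) in exactly one target
    entry of the searched origins.  Entries with >= 2 unique peptides are
    ``multi_peptide``; exactly one unique peptide gives
    ``single_peptide_flagged`` (the manual-review tier); entries carrying only
    shared peptides are returned in the separate ambiguous list.
    """
    origins = tuple(origins)
    entry_unique: dict[str, set[str]] = {}
    entry_shared: dict[str, set[str]] = {}
    entry_peptides: dict[str, set[str]] = {}
    for pep in peptides:
        hits = db.lookup(pep.collapsed, origins=origins)
        entry_ids = sorted({eid for eid, _ in hits})
        for eid in entry_ids:
            entry_peptides.setdefault(eid, set()).add(pep.peptide)
            if len(entry_ids) == 1:
                entry_unique.setdefault(eid, set()).add(pep.peptide)
            else:
                entry_shared.setdefault(eid, set()).add(pep.peptide)

    proteins: list[ProteinIdentification] = []
    ambiguous: list[str] = []
    for eid in sorted(entry_peptides):
        uniq = frozenset(entry_unique.get(eid, ()))
        shared = frozenset(entry_shared.get(eid, ()))
        if not uniq:
            ambiguous.append(eid)
            continue
        entry = db.by_id.get(eid)
        coverage = (
            compute_coverage(entry.aa_seq, uniq | shared) if entry is not None else 0.0
        )
        proteins.append(
            ProteinIdentification(
                entry_id=eid,
                unique_peptides=uniq,
                shared_peptides=shared,
                coverage_pct=coverage,
                confidence="multi_peptide" if len(uniq) >= 2 else "single_peptide_flagged",
            )
        )
    return InferenceResult(tuple(proteins), tuple(ambiguous))
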