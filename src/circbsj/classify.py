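"""Mapping and classification of identified peptides.

A peptide identified against the concatenated search database is either
canonical (group PC) or circRNA-derived (group CIRC); a CIRC peptide is
further split by whether any of its residues sit on the back-splice junction
(circRNA-BSJ, one or two residues depending on the junction/codon phase) or
not (circRNA-not-BSJ).  The screens applied here mirror the discovery
workflow: exact-substring reassignment against a canonical proteome,
exclusion of identifications explained at least as well by a modified
canonical peptide, HLA-class length windows, and <2 %rank binder annotation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io import PeGroup, ProteomeRecord
from .reference import BsjOrfWindow

__all__ = [
    "LengthClass",
    "PeptideMatch",
    "ClassifiedPeptide",
    "BinderAnnotation",
    "strip_modifications",
    "map_peptide",
    "classify_bsj",
    "context_string",
    "canonical_screen",
    "ambiguity_filter",
    "length_filter",
    "annotate_binders",
    "classify_peptides",
]

logger = logging.getLogger(__name__)

_MOD = re.compile(r"\([^()]*\)")

LENGTH_BOUNDS = {"HLA_I": (8, 15), "HLA_II": (9, 25)}


class LengthClass(str, Enum):
    HLA_I = "HLA_I"
    HLA_II = "HLA_II"


@dataclass(frozen=True)
class PeptideMatch:
    """One exact occurrence of a peptide in a window (1-based inclusive)."""

    window_id: str
    start: int
    end: int


@dataclass
class ClassifiedPeptide:
    sequence: str
    group: PeGroup
    bsj_overlap: bool
    n_bsj_residues: int
    matches: list[tuple[str, int, int, Optional[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.bsj_overlap and self.group is not PeGroup.CIRC:
            raise ValueError("BSJ-overlapping peptides must be in the CIRC group")


@dataclass(frozen=True)
class BinderAnnotation:
    """Best-allele HLA binding call; binder means %rank strictly below 2."""

    allele: Optional[str]
    percent_rank: Optional[float]
    is_binder: Optional[bool]


def strip_modifications(peptide: str) -> str:
    """Collapse a modified peptide (e.g. ``ASM(Ox)AGGFLLR``) to its sequence."""
    return _MOD.sub("", peptide)


def map_peptide(peptide: str, windows: Sequence[BsjOrfWindow]) -> list[PeptideMatch]:
    """All exact substring occurrences of ``peptide`` across the windows."""
    if not peptide:
        raise ValueError("empty peptide")
    out: list[PeptideMatch] = []
    n = len(peptide)
    for w in windows:
        pos = w.aa_seq.find(peptide)
        while pos != -1:
            out.append(PeptideMatch(w.window_id, pos + 1, pos + n))
            pos = w.aa_seq.find(peptide, pos + 1)
    return out


def classify_bsj(match: PeptideMatch, window: BsjOrfWindow) -> tuple[bool, int]:
    """Does the matched stretch touch the window's BSJ residues, and how many."""
    s, e = window.bsj_span
    lo, hi = max(match.start, s), min(match.end, e)
    n = max(0, hi - lo + 1)
    return n > 0, n


def context_string(match: PeptideMatch, window: BsjOrfWindow) -> str:
    """Table-style BSJ context: ``UP- > pre[BSJ]suf < -DOWN``.

    Brackets wrap the BSJ residues covered by the peptide; the flanks are the
    window residues outside the peptide.  Only defined for BSJ-overlapping
    matches.
    """
    overlap, _ = classify_bsj(match, window)
    if not overlap:
        raise ValueError("context_string is only defined for BSJ-overlapping matches")
    s, e = window.bsj_span
    lo, hi = max(match.start, s), min(match.end, e)
    pep = window.aa_seq[match.start - 1 : match.end]
    up = window.aa_seq[: match.start - 1]
    down = window.aa_seq[match.end :]
    pre = pep[: lo - match.start]
    bsj = pep[lo - match.start : hi - match.start + 1]
    suf = pep[hi - match.start + 1 :]
    return f"{up}- > {pre}[{bsj}]{suf} < -{down}"


def canonical_screen(
    peptides: Iterable[str],
    proteome: Sequence[ProteomeRecord],
    il_equivalence: bool = False,
) -> set[str]:
    """Peptides occurring verbatim inside any canonical protein.

    Returns the set to be re-annotated to the PC group.  With
    ``il_equivalence`` Ile and Leu are treated as indistinguishable (as they
    are by MS); off by default, matching a BLAST-style exact screen.
    """
    seqs = [p.aa_seq for p in proteome if p.pe_group is PeGroup.PC]
    hay = "|".join(seqs)
    if il_equivalence:
        hay = hay.replace("I", "L")
    hits: set[str] = set()
    for pep in peptides:
        needle = pep.replace("I", "L") if il_equivalence else pep
        if needle and needle in hay:
            hits.add(pep)
    return hits


def ambiguity_filter(
    circ_psm_score: float, best_modified_pc_score: Optional[float]
) -> bool:
    """Keep a circRNA PSM only if it beats every modified-PC explanation.

    A modified canonical peptide with equal or higher score (delta score <= 0)
    makes the identification ambiguous and the PSM is dropped.
    """
    if circ_psm_score is None:
        raise ValueError("circRNA PSM score is required")
    if best_modified_pc_score is None:
        return True
    return best_modified_pc_score < circ_psm_score


def length_filter(
    peptides: Iterable[str], mode: LengthClass | str = LengthClass.HLA_I
) -> list[str]:
    """Reporting length window: 8-15 aa for HLA-I, 9-25 aa for HLA-II."""
    lo, hi = LENGTH_BOUNDS[LengthClass(mode).value]
    return [p for p in peptides if lo <= len(strip_modifications(p)) <= hi]


def annotate_binders(
    peptides: Iterable[str], rank_table: pd.DataFrame
) -> dict[str, BinderAnnotation]:
    """Best-allele annotation from a precomputed %rank table.

    ``rank_table`` needs columns ``peptide``, ``allele``, ``percent_rank``.
    A peptide absent from the table is annotated unknown with a warning.
    """
    required = {"peptide", "allele", "percent_rank"}
    missing = required - set(rank_table.columns)
    if missing:
        raise ValueError(f"rank table is missing column(s) {sorted(missing)}")
    best = (
        rank_table.sort_values(["peptide", "percent_rank"], kind="mergesort")
        .groupby("peptide", sort=False)
        .first()
    )
    out: dict[str, BinderAnnotation] = {}
    for pep in peptides:
        if pep in best.index:
            row = best.loc[pep]
            rank = float(row["percent_rank"])
            out[pep] = BinderAnnotation(str(row["allele"]), rank, rank < 2.0)
        else:
            logger.warning("peptide %s absent from the %%rank table", pep)
            out[pep] = BinderAnnotation(None, None, None)
    return out


def classify_peptides(
    peptides: Iterable[str],
    windows: Sequence[BsjOrfWindow],
    proteome: Sequence[ProteomeRecord] = (),
    il_equivalence: bool = False,
) -> list[ClassifiedPeptide]:
    """Full classification of a peptide list against windows and proteome.

    Modified peptides are collapsed to their stripped sequence before
    matching; a peptide matching the canonical proteome is PC regardless of
    any window match; a peptide matching neither raises (unmapped).
    """
    window_by_id = {w.window_id: w for w in windows}
    canonical = canonical_screen(
        {strip_modifications(p) for p in peptides}, proteome, il_equivalence
    )
    out: list[ClassifiedPeptide] = []
    for pep in peptides:
        seq = strip_modifications(pep)
        matches = map_peptide(seq, windows) if windows else []
        if seq in canonical:
            out.append(
                ClassifiedPeptide(
                    seq,
                    PeGroup.PC,
                    False,
                    0,
                    [(m.window_id, m.start, m.end, None) for m in matches],
                )
            )
            continue
        if not matches:
            raise ValueError(f"peptide {seq!r} matches neither proteome nor windows")
        annotated = []
        best_n = 0
        for m in matches:
            w = window_by_id[m.window_id]
            overlap, n = classify_bsj(m, w)
            ctx = context_string(m, w) if overlap else None
            annotated.append((m.window_id, m.start, m.end, ctx))
            best_n = max(best_n, n)
        out.append(
            ClassifiedPeptide(seq, PeGroup.CIRC, best_n > 0, best_n, annotated)
        )
    return out
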