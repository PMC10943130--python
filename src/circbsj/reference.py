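"""BSJ-ORF reference construction from circRNA spliced sequences.

The back-splice junction (BSJ) of a circRNA is the wrap point between the end
and the start of its linear spliced representation.  Peptides whose codons
span this junction cannot arise from the linear transcript, so a search
database of junction-spanning ORF windows is the key reagent for finding them
by MS.  The construction:

1.  Concatenate the circRNA sequence ``k`` times -- ``k = 2`` when the length
    is a multiple of 3 (the reading frame is invariant across the junction),
    ``k = 4`` otherwise (the frame shifts at each junction, and four copies
    expose every junction/codon phase relationship to a linear scan).
2.  In each of the three start frames, list the coordinates of all in-frame
    ATG codons, stop codons (TAA/TAG/TGA; codons containing N are treated as
    terminators) and junctions, sorted by coordinate.
3.  Each junction inside a stop-to-stop interval with an ATG strictly between
    the preceding stop and the junction yields a translatable span; residues
    N-terminal to the first Met are removed.
4.  Translated spans are trimmed to at most 24 residues on each side of the
    junction residue (23 when the junction falls between two codons, which
    puts two residues in the BSJ span), giving windows of at most 49 (48)
    amino acids -- long enough to host any 8-25-mer HLA-I/II peptide with at
    least one junction residue.
5.  A reading frame of the circle with no stop codon at all supports
    rolling-circle (infinite) translation; its windows are flagged and built
    with full flanks, since a Met recurs every rotation upstream.

Windows are produced only from spans whose two bounding stops are both real
codons inside the scan (or from rolling-circle frames): a span truncated by a
scan boundary can misreport the first ATG or a flank, and every junction
phase is guaranteed a fully stop-bounded occurrence somewhere across the
three start frames, so nothing is lost.  Deduplication is per junction phase
within a circRNA; identical windows from different circRNAs are kept, since
a peptide's multi-circRNA evidence matters downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq

from .io import CircRNARecord

__all__ = [
    "STOP_CODONS",
    "ElementKind",
    "CodingElement",
    "ConcatenatedScan",
    "TranslatableSpan",
    "BsjOrfWindow",
    "concatenation_factor",
    "build_scans",
    "enumerate_elements",
    "find_translatable_spans",
    "translate_span",
    "trim_window",
    "detect_infinite",
    "build_reference",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: default width-1 flank; width-2 windows use one residue less per side
DEFAULT_FLANK = 24


class ElementKind(IntEnum):
    """Scan element kinds; the order is the tie-break at equal coordinates."""

    STP = 0
    BSJ = 1
    ATG = 2


@dataclass(frozen=True, order=True)
class CodingElement:
    coord: int
    kind: ElementKind


@dataclass(frozen=True)
class ConcatenatedScan:
    """One start frame of the k-fold concatenated circRNA sequence."""

    circ_id: str
    k: int
    seq: str
    bsj_coords: tuple[int, ...]  # 0-based index of the first nt after each junction
    start_frame: int

    @property
    def circ_length(self) -> int:
        return len(self.seq) // self.k


@dataclass(frozen=True)
class TranslatableSpan:
    """A junction-bearing, ATG-initiated stretch inside a stop-to-stop interval.

    ``end_stop`` is None only for rolling-circle (infinite) spans; a finite
    span that runs into the scan boundary records the translation end there
    and is marked ``downstream_bounded=False``.
    """

    start_atg: int
    end_stop: Optional[int]
    bsj_list: tuple[int, ...]
    infinite: bool
    upstream_bounded: bool
    downstream_bounded: bool


@dataclass(frozen=True)
class BsjOrfWindow:
    """A trimmed, junction-spanning translated window.

    ``bsj_span`` holds the 1-based inclusive window positions of the BSJ
    residue(s): one residue when the junction falls inside a codon, two when
    it falls between codons.
    """

    window_id: str
    source_circ: str
    frame: int  # junction phase class, the _0/_1/_2 id suffix
    aa_seq: str
    bsj_span: tuple[int, int]
    infinite: bool

    def __post_init__(self) -> None:
        s, e = self.bsj_span
        if not (1 <= s <= e <= len(self.aa_seq)):
            raise ValueError(f"{self.window_id}: BSJ span {self.bsj_span} outside window")
        if "*" in self.aa_seq:
            raise ValueError(f"{self.window_id}: stop symbol inside window")

    @property
    def width(self) -> int:
        return self.bsj_span[1] - self.bsj_span[0] + 1

    @property
    def upstream_flank(self) -> int:
        return self.bsj_span[0] - 1

    @property
    def downstream_flank(self) -> int:
        return len(self.aa_seq) - self.bsj_span[1]


def _is_terminator(codon: str) -> bool:
    return codon in STOP_CODONS or "N" in codon


def concatenation_factor(length_nt: int) -> int:
    """2 when the circRNA holds an integral number of codons, else 4."""
    if length_nt < 1:
        raise ValueError(f"circRNA length must be >= 1, got {length_nt}")
    return 2 if length_nt % 3 == 0 else 4


def build_scans(circ: CircRNARecord) -> list[ConcatenatedScan]:
    """One scan per start frame in {0,1,2}; forward strand only."""
    L = circ.length_nt
    k = concatenation_factor(L)
    seq = circ.seq * k
    bsj = tuple(L * i for i in range(1, k))
    return [ConcatenatedScan(circ.circ_id, k, seq, bsj, f) for f in range(3)]


def enumerate_elements(scan: ConcatenatedScan) -> list[CodingElement]:
    """All in-frame ATG/stop codon starts plus junction coordinates, sorted.

    Ties at one coordinate order STP < BSJ < ATG, so a stop ending exactly at
    a junction closes its interval first, and an ATG starting exactly at a
    junction does not count as upstream of it.
    """
    out = [CodingElement(j, ElementKind.BSJ) for j in scan.bsj_coords]
    seq = scan.seq
    for c in range(scan.start_frame, len(seq) - 2, 3):
        codon = seq[c : c + 3]
        if codon == "ATG":
            out.append(CodingElement(c, ElementKind.ATG))
        elif _is_terminator(codon):
            out.append(CodingElement(c, ElementKind.STP))
    out.sort()
    return out


def find_translatable_spans(
    elements: Sequence[CodingElement], scan: ConcatenatedScan
) -> list[TranslatableSpan]:
    """One span per junction with an ATG strictly between it and the last stop.

    Scan boundaries act as virtual stops; a scan with no stop codon at all is
    a rolling-circle frame and its spans are marked infinite.
    """
    infinite_scan = not any(e.kind is ElementKind.STP for e in elements)
    virtual_end = scan.start_frame + 3 * ((len(scan.seq) - scan.start_frame) // 3)
    spans: list[TranslatableSpan] = []
    pending: list[tuple[int, int, bool]] = []  # (start_atg, bsj, upstream_bounded)
    atgs: list[int] = []
    upstream_bounded = False
    for e in elements:
        if e.kind is ElementKind.STP:
            for start_atg, j, ub in pending:
                spans.append(
                    TranslatableSpan(start_atg, e.coord, (j,), False, ub, True)
                )
            pending.clear()
            atgs.clear()
            upstream_bounded = True
        elif e.kind is ElementKind.ATG:
            atgs.append(e.coord)
        else:  # BSJ
            if atgs:
                pending.append((atgs[0], e.coord, upstream_bounded))
    for start_atg, j, ub in pending:
        if infinite_scan:
            spans.append(TranslatableSpan(start_atg, None, (j,), True, ub, False))
        else:
            spans.append(
                TranslatableSpan(start_atg, virtual_end, (j,), False, ub, False)
            )
    return spans


def translate_span(
    scan: ConcatenatedScan, span: TranslatableSpan
) -> tuple[str, tuple[int, ...], int]:
    """Translate a span and locate its junction residue(s).

    Returns ``(aa_seq, bsj_residue_indices, width)`` with 0-based residue
    indices into ``aa_seq``.  A junction inside a codon marks that single
    residue (width 1); a junction on a codon boundary marks the two flanking
    residues (width 2).
    """
    start = span.start_atg
    end = span.end_stop
    if end is None:
        end = scan.start_frame + 3 * ((len(scan.seq) - scan.start_frame) // 3)
    if end - start < 3:
        raise ValueError("span shorter than one codon")
    aa = str(Seq(scan.seq[start:end]).translate())
    j = span.bsj_list[0]
    phase = (j - scan.start_frame) % 3
    if phase == 0:
        if j - 3 < start or j + 3 > end:
            raise ValueError("BSJ residues fall outside the translated span")
        idx = ((j - 3 - start) // 3, (j - start) // 3)
        width = 2
    else:
        c = j - phase
        if c < start or c + 3 > end:
            raise ValueError("BSJ residue falls outside the translated span")
        idx = ((c - start) // 3,)
        width = 1
    return aa, idx, width


def trim_window(
    aa_seq: str,
    bsj_residue_indices: Sequence[int],
    width: int,
    *,
    circ_id: str = "circ",
    frame: int = 0,
    infinite: bool = False,
    flank: int = DEFAULT_FLANK,
) -> BsjOrfWindow:
    """Keep at most W residues on each side of the BSJ span.

    W = ``flank`` (24) for width 1 and ``flank - 1`` (23) for width 2, so the
    window never exceeds 2*flank + 1 residues.  Shorter flanks occur when the
    initiator Met or the stop codon is closer than W.
    """
    W = flank if width == 1 else flank - 1
    first, last = min(bsj_residue_indices), max(bsj_residue_indices)
    lo = max(0, first - W)
    hi = min(len(aa_seq) - 1, last + W)
    window = aa_seq[lo : hi + 1]
    return BsjOrfWindow(
        window_id=f"{circ_id}_{frame}",
        source_circ=circ_id,
        frame=frame,
        aa_seq=window,
        bsj_span=(first - lo + 1, last - lo + 1),
        infinite=infinite,
    )


def _wrapped_codon(seq: str, o: int) -> str:
    L = len(seq)
    return seq[o % L] + seq[(o + 1) % L] + seq[(o + 2) % L]


def detect_infinite(circ: CircRNARecord) -> tuple[bool, bool, bool]:
    """Per-start-frame rolling-circle flags.

    For L % 3 == 0 each fixed frame is tested on one rotation; otherwise the
    frames cycle and a full 3L traversal visits every codon phase, so the
    three flags coincide.
    """
    S, L = circ.seq, circ.length_nt
    if L % 3 == 0:
        return tuple(
            not any(_is_terminator(_wrapped_codon(S, o)) for o in range(f, L, 3))
            for f in range(3)
        )
    stop_free = not any(_is_terminator(_wrapped_codon(S, o)) for o in range(L))
    return (stop_free, stop_free, stop_free)


def _rotation_has_atg(circ: CircRNARecord, phase: int) -> bool:
    # phase is the junction phase class; for L % 3 == 0 it fixes the frame
    S, L = circ.seq, circ.length_nt
    if L % 3 == 0:
        f = (-phase) % 3
        return any(_wrapped_codon(S, o) == "ATG" for o in range(f, L, 3))
    return any(_wrapped_codon(S, o) == "ATG" for o in range(L))


def _infinite_window(
    circ: CircRNARecord, phase: int, flank: int
) -> BsjOrfWindow:
    """Window with full flanks around a junction of a rolling-circle frame.

    The reading has no stop and a Met recurs every rotation upstream, so the
    first-Met rule never shortens the upstream flank; the window is read
    straight off the unrolled circle by modular indexing.
    """
    S, L = circ.seq, circ.length_nt
    m_half = max(2, math.ceil((3 * flank + 9) / L))
    U = S * (2 * m_half)
    c0 = m_half * L  # junction coordinate in the unroll
    if phase == 0:
        W = flank - 1
        first_codon, last_codon = c0 - 3, c0
        width = 2
    else:
        W = flank
        first_codon = last_codon = c0 - phase
        width = 1
    start = first_codon - 3 * W
    end = last_codon + 3 + 3 * W
    aa = str(Seq(U[start:end]).translate())
    assert "*" not in aa, "stop codon inside a rolling-circle frame"
    return BsjOrfWindow(
        window_id=f"{circ.circ_id}_{phase}",
        source_circ=circ.circ_id,
        frame=phase,
        aa_seq=aa,
        bsj_span=(W + 1, W + width),
        infinite=True,
    )


def build_reference(
    circs: Iterable[CircRNARecord],
    flank: int = DEFAULT_FLANK,
    _force_k: Optional[int] = None,
) -> list[BsjOrfWindow]:
    """Union of trimmed windows over circRNAs, scans and spans.

    At most one window per junction phase class per circRNA (the phase class
    is the ``_0/_1/_2`` window-id suffix); windows identical across circRNAs
    are retained per source.  ``_force_k`` overrides the concatenation factor
    (used to verify the 2x/4x frame-invariance equivalence).
    """
    windows: list[BsjOrfWindow] = []
    for circ in circs:
        per_phase: dict[int, BsjOrfWindow] = {}
        scans = build_scans(circ)
        if _force_k is not None:
            L = circ.length_nt
            seq = circ.seq * _force_k
            bsj = tuple(L * i for i in range(1, _force_k))
            scans = [
                ConcatenatedScan(circ.circ_id, _force_k, seq, bsj, f) for f in range(3)
            ]
        for scan in scans:
            elements = enumerate_elements(scan)
            for span in find_translatable_spans(elements, scan):
                j = span.bsj_list[0]
                phase = (j - scan.start_frame) % 3
                if phase in per_phase:
                    continue
                if span.infinite:
                    if _rotation_has_atg(circ, phase):
                        per_phase[phase] = _infinite_window(circ, phase, flank)
                    continue
                if not (span.upstream_bounded and span.downstream_bounded):
                    continue  # boundary-truncated; this phase recurs fully bounded
                aa, idx, width = translate_span(scan, span)
                per_phase[phase] = trim_window(
                    aa,
                    idx,
                    width,
                    circ_id=circ.circ_id,
                    frame=phase,
                    infinite=False,
                    flank=flank,
                )
        windows.extend(per_phase[p] for p in sorted(per_phase))
    return windows
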