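"""Brute-force window oracle: exhaustive unrolled-circle translation.

An independent re-derivation of the BSJ-ORF window set used to cross-check
the scan-based builder.  The circle is unrolled far enough that, for every
junction phase, a junction occurrence exists with a full reading period of
context on both sides; the nearest stop and the first ATG are then found by
direct codon stepping, with no element lists, span bookkeeping or Biopython
translation involved.  Quadratic-ish in the circle length; intended for
sequences up to a few hundred nt.
"""

from __future__ import annotations

import math

from .io import CircRNARecord

__all__ = ["oracle_windows"]

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def _aa(codon: str) -> str:
    if "N" in codon:
        return "X"
    return _CODON_TABLE[codon]


def oracle_windows(
    circ: CircRNARecord, flank: int = 24
) -> set[tuple[int, str, tuple[int, int], bool]]:
    """Exhaustively derive the trimmed window set of one circRNA.

    Returns tuples ``(phase, aa_seq, bsj_span, infinite)`` where ``phase`` is
    the junction position within its codon (0 = between codons).
    """
    S, L = circ.seq, circ.length_nt
    m_half = max(4, math.ceil((3 * flank + 9) / L) + 1)
    U = S * (2 * m_half)
    c0 = m_half * L  # a junction deep inside the unroll
    # one reading period: L/3 codons for a frame-invariant circle, else L codons
    period = L // 3 if L % 3 == 0 else L
    out: set[tuple[int, str, tuple[int, int], bool]] = set()

    def terminator(c: int) -> bool:
        cod = U[c : c + 3]
        return _aa(cod) in ("*", "X")

    for phase in (0, 1, 2):
        if phase == 0:
            bsj_first, bsj_last = c0 - 3, c0
            width, W = 2, flank - 1
        else:
            bsj_first = bsj_last = c0 - phase
            width, W = 1, flank
        if terminator(bsj_first) or terminator(bsj_last):
            continue  # junction residue is a stop: no ORF covers it
        # nearest stops within one reading period on each side
        s_up = None
        c = bsj_first - 3
        for _ in range(period):
            if terminator(c):
                s_up = c
                break
            c -= 3
        s_dn = None
        c = bsj_last + 3
        for _ in range(period):
            if terminator(c):
                s_dn = c
                break
            c += 3
        if s_up is None:
            # rolling circle: stop-free reading; require an ATG somewhere in it
            has_atg = any(
                U[bsj_first - 3 * t : bsj_first - 3 * t + 3] == "ATG"
                for t in range(period + 1)
            )
            if not has_atg:
                continue
            start = bsj_first - 3 * W
            end = bsj_last + 3 + 3 * W
            aa = "".join(_aa(U[c : c + 3]) for c in range(start, end, 3))
            out.add((phase, aa, (W + 1, W + width), True))
            continue
        # first ATG strictly after the stop and strictly before the junction
        first_atg = None
        for c in range(s_up + 3, bsj_first + 3, 3):
            if U[c : c + 3] == "ATG":
                first_atg = c
                break
        if first_atg is None:
            continue
        start = max(first_atg, bsj_first - 3 * W)
        end = min(s_dn, bsj_last + 3 + 3 * W)
        aa = "".join(_aa(U[c : c + 3]) for c in range(start, end, 3))
        b1 = (bsj_first - start) // 3 + 1
        out.add((phase, aa, (b1, b1 + width - 1), False))
    return out
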