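"""FASTA and TSV input/output with explicit dialect rules.

Two FASTA dialects are read: circRNA spliced sequences (circBase-style,
``hsa_circ_...`` identifiers, the record id is the first whitespace token of
the header) and a canonical proteome (UniProt-style headers accepted but not
required).  One FASTA dialect is written: the concatenated search database in
which every entry carries exactly one ``PE=`` token in its header -- ``PE=1``
for canonical proteins, ``PE=4`` for circRNA BSJ-ORF windows -- so that
group-aware FDR tools can partition the search space.

All tabular data in this package is tab-separated with a mandatory header row.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "PeGroup",
    "CircRNARecord",
    "ProteomeRecord",
    "read_circ_fasta",
    "read_proteome_fasta",
    "write_search_fasta",
]

_NT_OK = set("ACGTN")  # N permitted on read; N-codons terminate ORFs downstream
_AA_OK = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}
_PE_TOKEN = re.compile(r"\bPE=\d+\b")
_WRAP = 60


class PeGroup(str, Enum):
    """Sequence group, mapped to the numeric PE header field on write."""

    PC = "PC"      # canonical protein-coding, PE=1
    CIRC = "CIRC"  # circRNA BSJ-ORF window, PE=4


@dataclass(frozen=True)
class CircRNARecord:
    """One circRNA's spliced sense sequence (linear representation).

    The sequence is the circle cut at the back-splice junction: the BSJ is the
    wrap point between the last and the first nucleotide.
    """

    circ_id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.circ_id:
            raise ValueError("circRNA record with empty identifier")
        if len(self.seq) < 1:
            raise ValueError(f"{self.circ_id}: empty sequence")
        bad = set(self.seq) - _NT_OK
        if bad:
            raise ValueError(
                f"{self.circ_id}: invalid nucleotide(s) {sorted(bad)} "
                "(expected A/C/G/T/N after normalization)"
            )

    @property
    def length_nt(self) -> int:
        return len(self.seq)


@dataclass
class ProteomeRecord:
    """A canonical protein entry; ``pe_group`` wins over any PE= token on write."""

    accession: str
    description: str
    aa_seq: str
    pe_group: PeGroup = PeGroup.PC

    def __post_init__(self) -> None:
        bad = set(self.aa_seq) - _AA_OK
        if bad:
            raise ValueError(
                f"{self.accession}: invalid amino-acid character(s) {sorted(bad)}"
            )


def read_circ_fasta(path: str | Path) -> list[CircRNARecord]:
    """Read circRNA spliced sequences.

    The record id is the first whitespace-delimited header token; sequences
    are uppercased and U is mapped to T.
    """
    records: list[CircRNARecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for header, raw in SimpleFastaParser(handle):
            tokens = header.split()
            if not tokens:
                raise ValueError(f"{path}: FASTA entry with empty header")
            circ_id = tokens[0]
            if circ_id in seen:
                raise ValueError(f"{path}: duplicate circRNA id {circ_id!r}")
            seen.add(circ_id)
            seq = raw.upper().replace("U", "T")
            if not seq:
                raise ValueError(f"{path}: record {circ_id!r} has no sequence")
            records.append(CircRNARecord(circ_id, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def read_proteome_fasta(path: str | Path) -> list[ProteomeRecord]:
    """Read a canonical proteome; every record gets ``pe_group=PC``.

    An empty file yields an empty list (the downstream canonical screen then
    becomes a no-op).  Existing ``PE=`` tokens in descriptions are preserved
    for round-tripping but are overridden on write.
    """
    records: list[ProteomeRecord] = []
    with open(path) as handle:
        for header, raw in SimpleFastaParser(handle):
            parts = header.split(None, 1)
            if not parts:
                raise ValueError(f"{path}: FASTA entry with empty header")
            accession = parts[0]
            description = parts[1] if len(parts) > 1 else ""
            records.append(
                ProteomeRecord(accession, description, raw.upper(), PeGroup.PC)
            )
    return records


def _wrap(seq: str, out: TextIO) -> None:
    for i in range(0, len(seq), _WRAP):
        out.write(seq[i : i + _WRAP])
        out.write("\n")


def _pe_description(description: str, pe: int) -> str:
    if _PE_TOKEN.search(description):
        return _PE_TOKEN.sub(f"PE={pe}", description)
    return (description + f" PE={pe}").strip()


def write_search_fasta(
    windows: Sequence,
    proteome: Iterable[ProteomeRecord],
    path: str | Path,
) -> None:
    """Write the concatenated search database.

    Proteome entries come first with ``PE=1``; then one entry per BSJ-ORF
    window with the header grammar::

        >circ|<window_id>|<window_id> BSJ=<start>-<end> INF=<0|1> PE=4

    where ``BSJ=`` gives the 1-based inclusive window positions of the BSJ
    residues.  Raises on any id collision between windows and proteome
    accessions, or among window ids.
    """
    proteome = list(proteome)
    acc_seen = {p.accession for p in proteome}
    win_seen: set[str] = set()
    for w in windows:
        if w.window_id in win_seen:
            raise ValueError(f"duplicate window id {w.window_id!r}")
        if w.window_id in acc_seen or f"circ|{w.window_id}|{w.window_id}" in acc_seen:
            raise ValueError(
                f"window id {w.window_id!r} collides with a proteome accession"
            )
        win_seen.add(w.window_id)
    with open(path, "w") as out:
        for p in proteome:
            desc = _pe_description(p.description, 1 if p.pe_group is PeGroup.PC else 4)
            out.write(f">{p.accession} {desc}\n")
            _wrap(p.aa_seq, out)
        for w in windows:
            s, e = w.bsj_span
            out.write(
                f">circ|{w.window_id}|{w.window_id} "
                f"BSJ={s}-{e} INF={1 if w.infinite else 0} PE=4\n"
            )
            _wrap(w.aa_seq, out)
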