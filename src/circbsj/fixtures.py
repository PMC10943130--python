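"""Packaged worked examples: published BSJ-peptide tables as test fixtures.

Each fixture row stores a detected circRNA-BSJ peptide together with its
printed BSJ context (``UP- > pre[BSJ]suf < -DOWN``); the trimmed ORF window
and its window-relative BSJ span are reconstructed from that context.  Where
a table truncates a flank, the stored window is the truncated one -- the
fixtures assert on what is printed, nothing more.  Distractor rows carry
peptides that match the windows without touching the BSJ (circRNA-not-BSJ).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .reference import BsjOrfWindow

__all__ = ["FixtureRow", "TableFixture", "FIXTURE_SOURCES", "load_table_fixture"]

FIXTURE_SOURCES = ("TABLE1_T1185B", "TABLE1_MEL1", "TABLE2_LUNG")

_CONTEXT = re.compile(r"^(?P<up>.*)- > (?P<pre>.*)\[(?P<bsj>.+)\](?P<suf>.*) < -(?P<down>.*)$")


@dataclass(frozen=True)
class FixtureRow:
    gene: str
    circ_id: str
    frame: int
    infinite: bool
    peptide: str        # as printed, possibly carrying a modification
    context: str        # bracketed BSJ context string
    window_aa: str      # reconstructed trimmed window
    bsj_span: tuple[int, int]

    @property
    def window_id(self) -> str:
        return f"{self.circ_id}_{self.frame}"


@dataclass(frozen=True)
class TableFixture:
    source: str
    rows: tuple[FixtureRow, ...]
    distractors: tuple[str, ...]

    @property
    def peptides(self) -> list[str]:
        """All fixture peptides: listed BSJ peptides plus distractors."""
        seen: dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.peptide, None)
        for d in self.distractors:
            seen.setdefault(d, None)
        return list(seen)

    def windows(self) -> list[BsjOrfWindow]:
        """Distinct reconstructed windows, one per circRNA_frame id."""
        by_id: dict[str, BsjOrfWindow] = {}
        for r in self.rows:
            w = BsjOrfWindow(
                window_id=r.window_id,
                source_circ=r.circ_id,
                frame=r.frame,
                aa_seq=r.window_aa,
                bsj_span=r.bsj_span,
                infinite=r.infinite,
            )
            prev = by_id.setdefault(r.window_id, w)
            if prev.aa_seq != w.aa_seq or prev.bsj_span != w.bsj_span:
                raise ValueError(
                    f"fixture rows disagree on window {r.window_id}"
                )
        return list(by_id.values())


def _parse_context(context: str) -> tuple[str, tuple[int, int]]:
    m = _CONTEXT.match(context)
    if m is None:
        raise ValueError(f"unparseable BSJ context {context!r}")
    up, pre, bsj, suf, down = m.group("up", "pre", "bsj", "suf", "down")
    window = up + pre + bsj + suf + down
    start = len(up) + len(pre) + 1
    return window, (start, start + len(bsj) - 1)


def load_table_fixture(source: str) -> TableFixture:
    """Load one packaged table fixture by name (see ``FIXTURE_SOURCES``)."""
    if source not in FIXTURE_SOURCES:
        raise KeyError(f"unknown fixture source {source!r}; choose from {FIXTURE_SOURCES}")
    with resources.files("circbsj.data").joinpath("table_fixtures.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    df = df[df["source"] == source]
    rows: list[FixtureRow] = []
    distractors: list[str] = []
    for _, rec in df.iterrows():
        if rec["role"] == "distractor":
            distractors.append(rec["peptide"])
            continue
        window, span = _parse_context(rec["context"])
        rows.append(
            FixtureRow(
                gene=rec["gene"],
                circ_id=rec["circ_id"],
                frame=int(rec["frame"]),
                infinite=rec["infinite"].upper() == "TRUE",
                peptide=rec["peptide"],
                context=rec["context"],
                window_aa=window,
                bsj_span=span,
            )
        )
    return TableFixture(source, tuple(rows), tuple(distractors))
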