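"""Seed-deterministic synthetic data: circRNAs and two-engine PSM tables.

The circRNA generator emulates circBase-style input: uniform random spliced
sequences in a configurable length range, with a configurable fraction of
frame-invariant (length % 3 == 0) circles.  With ``plant_orf`` every circle
is guaranteed a junction-spanning ORF: a within-codon junction whose rolling
reading carries a Met at a requested codon distance upstream and its first
stop beyond a requested distance downstream, so trimmed windows reach the
full flank cap.

The PSM generator emulates the two-engine discovery setting: each target
peptide is truly present with probability pi1; true targets draw scores from
a shifted normal in both engines independently (shared truth, independent
noise), false targets and one decoy per target draw from the null.  Ground
truth is emitted alongside for FDR-calibration experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io import CircRNARecord

__all__ = ["CircSimParams", "PsmSimParams", "simulate_circrnas", "simulate_psms"]

_NT = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass(frozen=True)
class CircSimParams:
    n_circ: int = 200
    length_range: tuple[int, int] = (300, 900)
    frac_len_mod3_zero: float = 0.3
    plant_orf: bool = False
    plant_upstream_aa: int = 40   # Met at least this many codons upstream of the BSJ
    plant_downstream_aa: int = 40  # first stop beyond this many codons downstream
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 9 or hi < lo:
            raise ValueError(f"invalid length range {self.length_range}")
        if not (0.0 <= self.frac_len_mod3_zero <= 1.0):
            raise ValueError("frac_len_mod3_zero must be in [0,1]")
        if self.plant_orf and 3 * (self.plant_upstream_aa + self.plant_downstream_aa + 2) > lo:
            raise ValueError(
                "planted ORF reach exceeds the minimum circRNA length: need "
                f">= {3 * (self.plant_upstream_aa + self.plant_downstream_aa + 2)} nt"
            )


def _pick_length(rng: np.random.Generator, params: CircSimParams) -> int:
    lo, hi = params.length_range
    L = int(rng.integers(lo, hi + 1))
    want_mod3 = rng.random() < params.frac_len_mod3_zero
    if want_mod3:
        L -= L % 3
        if L < lo:
            L += 3
    elif L % 3 == 0:
        L += 1 if L < hi else -1
    return L


def simulate_circrnas(params: CircSimParams) -> list[CircRNARecord]:
    """Generate ``n_circ`` synthetic circRNA records, reproducibly from the seed."""
    rng = np.random.default_rng(params.seed)
    records: list[CircRNARecord] = []
    for i in range(params.n_circ):
        L = _pick_length(rng, params)
        seq = rng.choice(_NT, size=L)
        if params.plant_orf:
            up, down = params.plant_upstream_aa, params.plant_downstream_aa
            phase = int(rng.integers(1, 3))  # within-codon junction (width 1)
            o_b = L - phase  # codon containing the junction starts here

            def put(offset_codon_start: int, codon: str) -> None:
                for t, ch in enumerate(codon):
                    seq[(offset_codon_start + t) % L] = ch

            put(o_b, _NON_STOP_CODONS[int(rng.integers(len(_NON_STOP_CODONS)))])
            for k in range(1, up + 1):
                codon = (
                    "ATG"
                    if k == up
                    else _NON_STOP_CODONS[int(rng.integers(len(_NON_STOP_CODONS)))]
                )
                put(o_b - 3 * k, codon)
            for k in range(1, down + 1):
                put(o_b + 3 * k, _NON_STOP_CODONS[int(rng.integers(len(_NON_STOP_CODONS)))])
            put(o_b + 3 * (down + 1), "TAA")
        records.append(CircRNARecord(f"sim_circ_{i:05d}", "".join(seq)))
    return records


@dataclass(frozen=True)
class PsmSimParams:
    n_pc: int = 20000
    n_circ_group: int = 1000
    pi1: float = 0.5
    true_score_mean: float = 3.0
    true_score_sd: float = 1.0
    null_score_mean: float = 0.0
    null_score_sd: float = 1.0
    n_engines: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi1 <= 1.0):
            raise ValueError("pi1 must be in [0,1]")
        if self.true_score_sd <= 0 or self.null_score_sd <= 0:
            raise ValueError("score standard deviations must be positive")


def simulate_psms(params: PsmSimParams) -> pd.DataFrame:
    """Tidy PSM table over engines with ground truth.

    Columns: peptide, group, engine (``engine_1`` ...), score, is_decoy,
    is_true.  One decoy per target within each group.  The true/false state
    of a target peptide is shared across engines; scores are then drawn
    independently per engine.
    """
    rng = np.random.default_rng(params.seed)
    frames = []
    for group, n in (("PC", params.n_pc), ("CIRC", params.n_circ_group)):
        truth = rng.random(n) < params.pi1
        for e in range(1, params.n_engines + 1):
            t_scores = np.where(
                truth,
                rng.normal(params.true_score_mean, params.true_score_sd, n),
                rng.normal(params.null_score_mean, params.null_score_sd, n),
            )
            d_scores = rng.normal(params.null_score_mean, params.null_score_sd, n)
            frames.append(
                pd.DataFrame(
                    {
                        "peptide": [f"pep_{group}_{i:06d}" for i in range(n)],
                        "group": group,
                        "engine": f"engine_{e}",
                        "score": t_scores,
                        "is_decoy": False,
                        "is_true": truth,
                    }
                )
            )
            frames.append(
                pd.DataFrame(
                    {
                        "peptide": [f"decoy_{group}_{i:06d}" for i in range(n)],
                        "group": group,
                        "engine": f"engine_{e}",
                        "score": d_scores,
                        "is_decoy": True,
                        "is_true": False,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
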