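"""Group-specific target-decoy FDR with two-engine intersection.

Canonical (PC) and circRNA-derived PSMs have different score distributions,
so pooling them underestimates the error in the small non-canonical group.
q-values are therefore computed separately per (engine, group) from the
simple decoy/target count ratio, and a peptide is retained only when it
passes the threshold in both engines.  This implements the published
concept on generic score columns; engine-internal score recalibration is out
of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .io import PeGroup

__all__ = ["FdrConfig", "assign_group", "group_qvalues", "apply_threshold_and_intersect"]

logger = logging.getLogger(__name__)

PSM_COLUMNS = ("peptide", "score", "is_decoy", "group")


@dataclass(frozen=True)
class FdrConfig:
    alpha: float = 0.03
    require_both_engines: bool = True
    decoy_prefix: str = "rev_"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")


def assign_group(window_ids: Iterable[str], proteome_ids: Iterable[str]) -> PeGroup:
    """CIRC iff the peptide matched only circRNA windows; PC on any canonical hit."""
    window_ids = list(window_ids)
    proteome_ids = list(proteome_ids)
    if not window_ids and not proteome_ids:
        raise ValueError("unmapped PSM: no window or proteome matches")
    return PeGroup.PC if proteome_ids else PeGroup.CIRC


def group_qvalues(psms: pd.DataFrame) -> pd.DataFrame:
    """Assign target-decoy q-values within each group of one engine's PSMs.

    At a score threshold s, FDR-hat(s) = #decoys>=s / max(1, #targets>=s);
    q-values are the running minimum of FDR-hat from the permissive end, and
    tied scores share the worse q (with decoys counted before targets at a
    tie).  A group without decoys gets q=0 for all entries with a warning.
    """
    missing = {"peptide", "score", "is_decoy", "group"} - set(psms.columns)
    if missing:
        raise ValueError(f"PSM table is missing column(s) {sorted(missing)}")
    out = psms.copy()
    out["q_value"] = np.nan
    for grp, sub in out.groupby("group", sort=False):
        idx = sub.index
        if not sub["is_decoy"].any():
            logger.warning("group %s has no decoys; q-values set to 0", grp)
            out.loc[idx, "q_value"] = 0.0
            continue
        order = np.lexsort((~sub["is_decoy"].to_numpy(), -sub["score"].to_numpy()))
        scores = sub["score"].to_numpy()[order]
        decoy = sub["is_decoy"].to_numpy()[order]
        cum_d = np.cumsum(decoy)
        cum_t = np.cumsum(~decoy)
        # evaluate counts at the end of each tie block so ties share the worse q
        n = len(scores)
        block_end = np.arange(n)
        for i in range(n - 2, -1, -1):
            if scores[i] == scores[i + 1]:
                block_end[i] = block_end[i + 1]
        fdr = cum_d[block_end] / np.maximum(1, cum_t[block_end])
        q = np.minimum.accumulate(fdr[::-1])[::-1]
        out.loc[idx[order], "q_value"] = q
    return out


def apply_threshold_and_intersect(
    psms_engine_a: pd.DataFrame,
    psms_engine_b: pd.DataFrame,
    cfg: Optional[FdrConfig] = None,
) -> pd.DataFrame:
    """Peptides passing the group-specific threshold, intersected across engines.

    Inputs are per-engine PSM tables with q-values assigned.  A peptide is
    retained when its best target q-value is <= alpha in both engines
    (``require_both_engines``) or in at least one (union mode).  Returns a
    table with one row per retained peptide: peptide, group, q per engine.
    """
    cfg = cfg or FdrConfig()

    def best(df: pd.DataFrame, name: str) -> pd.DataFrame:
        t = df.loc[~df["is_decoy"], ["peptide", "group", "q_value"]]
        return (
            t.groupby(["peptide", "group"], sort=False)["q_value"]
            .min()
            .rename(name)
            .reset_index()
        )

    a = best(psms_engine_a, "q_a")
    b = best(psms_engine_b, "q_b")
    merged = a.merge(b, on=["peptide", "group"], how="outer")
    pass_a = merged["q_a"] <= cfg.alpha
    pass_b = merged["q_b"] <= cfg.alpha
    if cfg.require_both_engines:
        keep = pass_a.fillna(False) & pass_b.fillna(False)
    else:
        keep = pass_a.fillna(False) | pass_b.fillna(False)
    out = merged.loc[keep].reset_index(drop=True)
    return out.sort_values(["group", "peptide"], kind="mergesort").reset_index(drop=True)
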