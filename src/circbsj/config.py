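"""Single source of truth for the pipeline's numeric constants."""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable threshold of the workflow, with its conventional default.

    ``flank_width1``/``flank_width2`` are the residue flanks kept around a
    within-codon / between-codon junction (24/23), giving the 49-aa window
    cap; ``fdr_alpha`` is the group-specific target-decoy threshold;
    ``rank_threshold`` the %rank binder cutoff; the length windows are the
    HLA-I and HLA-II reporting bounds.
    """

    flank_width1: int = 24
    flank_width2: int = 23
    window_cap: int = 49
    fdr_alpha: float = 0.03
    rank_threshold: float = 2.0
    hla1_len: tuple[int, int] = (8, 15)
    hla2_len: tuple[int, int] = (9, 25)
    il_equivalence: bool = False
    contaminant_prefix: str = "CON__"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flank_width2 != self.flank_width1 - 1:
            raise ValueError("flank_width2 must equal flank_width1 - 1")
        if self.window_cap != 2 * self.flank_width1 + 1:
            raise ValueError("window_cap must equal 2*flank_width1 + 1")
        if not (0 < self.fdr_alpha < 1):
            raise ValueError("fdr_alpha must be in (0,1)")
        if self.rank_threshold <= 0:
            raise ValueError("rank_threshold must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hla1_len"] = list(self.hla1_len)
        d["hla2_len"] = list(self.hla2_len)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat YAML document; keyword overrides win over file values."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        for key in ("hla1_len", "hla2_len"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
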