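"""End-to-end composition: build-ref -> search FASTA -> classify -> FDR -> report.

The pipeline is deterministic given its inputs and configuration; outputs are
sorted and written as TSV/JSON so two runs on identical inputs are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import __version__
from .classify import (
    LengthClass,
    annotate_binders,
    canonical_screen,
    classify_peptides,
    length_filter,
    strip_modifications,
)
from .config import PipelineConfig
from .fdr import FdrConfig, apply_threshold_and_intersect, group_qvalues
from .io import PeGroup, read_circ_fasta, read_proteome_fasta, write_search_fasta
from .reference import build_reference
from .specificity import flag_genes

logger = logging.getLogger(__name__)

__all__ = ["read_psm_tsv", "read_tpm_tsv", "run_all"]


def read_psm_tsv(path: str | Path) -> pd.DataFrame:
    """Read a normalized PSM table: peptide, score, is_decoy [, group]."""
    df = pd.read_csv(path, sep="\t")
    missing = {"peptide", "score", "is_decoy"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if df["is_decoy"].dtype == object:
        df["is_decoy"] = df["is_decoy"].astype(str).str.lower().isin(("true", "1", "yes"))
    return df


def read_tpm_tsv(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a genes-by-samples TPM matrix.

    Column headers of the form ``cohort:sample`` carry the cohort label;
    a header without a colon is its own single-sample cohort.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = {c: (c.split(":", 1)[0] if ":" in c else c) for c in df.columns}
    return df, labels


def _assign_groups(
    psms: pd.DataFrame, windows, proteome, cfg: PipelineConfig
) -> pd.DataFrame:
    if "group" in psms.columns:
        return psms
    if psms["is_decoy"].any():
        raise ValueError(
            "PSM table has decoys but no 'group' column; decoy groups cannot "
            "be inferred from sequence"
        )
    peptides = {strip_modifications(p) for p in psms["peptide"]}
    canonical = canonical_screen(peptides, proteome, cfg.il_equivalence)
    window_hay = "|".join(w.aa_seq for w in windows)
    groups = {}
    for pep in peptides:
        if pep in canonical:
            groups[pep] = PeGroup.PC.value
        elif pep in window_hay:
            groups[pep] = PeGroup.CIRC.value
        else:
            raise ValueError(f"unmapped PSM peptide {pep!r}")
    out = psms.copy()
    out["group"] = [groups[strip_modifications(p)] for p in out["peptide"]]
    return out


def run_all(
    config: PipelineConfig,
    circ_fasta: str | Path,
    proteome_fasta: str | Path,
    psms_engine_a: str | Path,
    psms_engine_b: str | Path,
    out_dir: str | Path,
    mode: LengthClass | str = LengthClass.HLA_I,
    ranks_tsv: Optional[str | Path] = None,
    tumor_tpm_tsv: Optional[str | Path] = None,
    normal_tpm_tsv: Optional[str | Path] = None,
) -> dict:
    """Run the whole workflow and write classified/retained/specificity tables.

    Returns the summary dictionary that is also written to ``summary.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mode = LengthClass(mode)

    # an entry-less circRNA FASTA is a legal degenerate input for the pipeline
    # (PC-only analysis), although the reader itself rejects it
    if ">" in Path(circ_fasta).read_text():
        circs = read_circ_fasta(circ_fasta)
    else:
        circs = []
    proteome = read_proteome_fasta(proteome_fasta)
    contaminants = [
        p for p in proteome if p.accession.startswith(config.contaminant_prefix)
    ]
    proteome_clean = [
        p for p in proteome if not p.accession.startswith(config.contaminant_prefix)
    ]

    windows = build_reference(circs, flank=config.flank_width1)
    write_search_fasta(windows, proteome, out / "search.fa")

    fdr_cfg = FdrConfig(alpha=config.fdr_alpha)
    qtabs = []
    for path in (psms_engine_a, psms_engine_b):
        psms = _assign_groups(read_psm_tsv(path), windows, proteome_clean, config)
        qtabs.append(group_qvalues(psms))
    retained = apply_threshold_and_intersect(qtabs[0], qtabs[1], fdr_cfg)
    retained.to_csv(out / "retained.tsv", sep="\t", index=False)

    peptides = length_filter(retained["peptide"].tolist(), mode)
    # contaminant-matching peptides leave the analysis entirely
    if contaminants:
        con_hits = canonical_screen(
            {strip_modifications(p) for p in peptides}, contaminants,
            config.il_equivalence,
        )
        peptides = [p for p in peptides if strip_modifications(p) not in con_hits]
    classified = classify_peptides(
        peptides, windows, proteome_clean, config.il_equivalence
    )

    binders = {}
    if ranks_tsv is not None:
        ranks = pd.read_csv(ranks_tsv, sep="\t")
        binders = annotate_binders([c.sequence for c in classified], ranks)

    rows = []
    win_by_id = {w.window_id: w for w in windows}
    for c in sorted(classified, key=lambda c: (c.group.value, c.sequence)):
        contexts = sorted({ctx for _, _, _, ctx in c.matches if ctx})
        wids = sorted({wid for wid, _, _, _ in c.matches})
        ann = binders.get(c.sequence)
        rows.append(
            {
                "peptide": c.sequence,
                "group": c.group.value,
                "bsj_overlap": c.bsj_overlap,
                "n_bsj_residues": c.n_bsj_residues,
                "window_ids": ",".join(wids),
                "context": ";".join(contexts),
                "infinite_source": any(
                    win_by_id[w].infinite for w in wids if w in win_by_id
                ),
                "is_binder": "" if ann is None or ann.is_binder is None else ann.is_binder,
                "best_allele": "" if ann is None or ann.allele is None else ann.allele,
            }
        )
    classified_df = pd.DataFrame(
        rows,
        columns=[
            "peptide", "group", "bsj_overlap", "n_bsj_residues", "window_ids",
            "context", "infinite_source", "is_binder", "best_allele",
        ],
    )
    classified_df.to_csv(out / "classified.tsv", sep="\t", index=False)

    if tumor_tpm_tsv is not None and normal_tpm_tsv is not None:
        t_df, t_labels = read_tpm_tsv(tumor_tpm_tsv)
        n_df, n_labels = read_tpm_tsv(normal_tpm_tsv)
        flags = flag_genes(t_df, t_labels, n_df, n_labels)
        flags.to_csv(out / "specificity.tsv", sep="\t", index=False)

    n_circ_pep = int((classified_df["group"] == "CIRC").sum())
    n_bsj = int(classified_df["bsj_overlap"].sum()) if len(classified_df) else 0
    summary = {
        "version": __version__,
        "config": config.to_dict(),
        "n_circrnas": len(circs),
        "n_windows": len(windows),
        "n_retained_peptides": int(len(retained)),
        "n_classified_peptides": int(len(classified_df)),
        "n_pc_peptides": int((classified_df["group"] == "PC").sum()),
        "n_circ_peptides": n_circ_pep,
        "n_bsj_peptides": n_bsj,
        "n_not_bsj_peptides": n_circ_pep - n_bsj,
        "n_binders": int(sum(1 for b in binders.values() if b.is_binder)),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run-all summary: %s", summary)
    return summary
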