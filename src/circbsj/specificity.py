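"""Host-gene expression rule for calling cancer-related circRNAs.

Because circRNAs co-exist with their linear counterparts, tumor specificity
is assessed on the host gene: a gene qualifies when its expression reaches at
least 2.5 TPM at the 99th percentile in some tumor cohort while staying at or
below 1 TPM at the 90th percentile in every normal cohort, excluding tissues
with known promiscuous expression (testis, sun-exposed skin).  Percentiles
use the nearest-rank definition (the ceil(p/100*n)-th order statistic), which
is exact on small cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortClass",
    "ExpressionSummary",
    "nearest_rank_percentile",
    "summarize",
    "tumor_specific",
    "flag_genes",
]

TUMOR_TPM_MIN = 2.5
NORMAL_TPM_MAX = 1.0
DEFAULT_EXCLUSION = frozenset({"testis", "sun-exposed skin"})


class CohortClass(str, Enum):
    TUMOR_REF = "TUMOR_REF"    # summarized at the 99th percentile
    NORMAL_REF = "NORMAL_REF"  # summarized at the 90th percentile


PERCENTILE_LEVEL = {CohortClass.TUMOR_REF: 99, CohortClass.NORMAL_REF: 90}


@dataclass(frozen=True)
class ExpressionSummary:
    gene: str
    cohort: str
    cohort_class: CohortClass
    percentile_level: int
    tpm_at_percentile: float
    excluded: bool = False


def nearest_rank_percentile(values: Sequence[float], p: int) -> float:
    """The ceil(p/100 * n)-th order statistic (1-based), no interpolation."""
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if n == 0:
        raise ValueError("empty cohort")
    k = max(1, math.ceil(p / 100 * n))
    return float(arr[k - 1])


def summarize(
    tpm_matrix: pd.DataFrame,
    cohort_labels: Mapping[str, str],
    cohort_class: CohortClass,
    exclusion_list: Iterable[str] = (),
) -> list[ExpressionSummary]:
    """Per gene x cohort percentile summaries of a genes-by-samples TPM matrix."""
    cohort_class = CohortClass(cohort_class)
    level = PERCENTILE_LEVEL[cohort_class]
    excluded = {e.lower() for e in exclusion_list}
    cohorts: dict[str, list[str]] = {}
    for sample, cohort in cohort_labels.items():
        cohorts.setdefault(cohort, []).append(sample)
    out: list[ExpressionSummary] = []
    for cohort, samples in cohorts.items():
        missing = [s for s in samples if s not in tpm_matrix.columns]
        if missing:
            raise ValueError(f"cohort {cohort!r}: sample(s) {missing} not in matrix")
        if not samples:
            raise ValueError(f"cohort {cohort!r} has no samples")
        sub = tpm_matrix[samples].to_numpy(dtype=float)
        k = max(1, math.ceil(level / 100 * sub.shape[1]))
        vals = np.sort(sub, axis=1)[:, k - 1]
        if np.any(vals < 0):
            raise ValueError(f"cohort {cohort!r}: negative TPM values")
        for gene, v in zip(tpm_matrix.index, vals):
            out.append(
                ExpressionSummary(
                    str(gene), cohort, cohort_class, level, float(v),
                    cohort.lower() in excluded,
                )
            )
    return out


def tumor_specific(
    gene: str,
    tumor_summaries: Iterable[ExpressionSummary],
    normal_summaries: Iterable[ExpressionSummary],
    exclusion_list: Iterable[str] = DEFAULT_EXCLUSION,
    tumor_threshold: float = TUMOR_TPM_MIN,
    normal_threshold: float = NORMAL_TPM_MAX,
) -> Optional[bool]:
    """True iff some tumor cohort reaches the tumor threshold and no
    non-excluded normal cohort exceeds the normal cap.

    Returns None (unknown) when the gene is absent from either reference.
    """
    excluded = {e.lower() for e in exclusion_list}
    tumor = [s.tpm_at_percentile for s in tumor_summaries if s.gene == gene]
    normal = [
        s.tpm_at_percentile
        for s in normal_summaries
        if s.gene == gene and s.cohort.lower() not in excluded and not s.excluded
    ]
    if not tumor or not normal:
        return None
    return max(tumor) >= tumor_threshold and max(normal) <= normal_threshold


def flag_genes(
    tumor_tpm: pd.DataFrame,
    tumor_labels: Mapping[str, str],
    normal_tpm: pd.DataFrame,
    normal_labels: Mapping[str, str],
    exclusion_list: Iterable[str] = DEFAULT_EXCLUSION,
) -> pd.DataFrame:
    """Tumor-specificity call per gene; genes missing on one side come out NA."""
    ts = summarize(tumor_tpm, tumor_labels, CohortClass.TUMOR_REF)
    ns = summarize(normal_tpm, normal_labels, CohortClass.NORMAL_REF, exclusion_list)
    genes = sorted(set(map(str, tumor_tpm.index)) | set(map(str, normal_tpm.index)))
    calls = [tumor_specific(g, ts, ns, exclusion_list) for g in genes]
    return pd.DataFrame({"gene": genes, "tumor_specific": calls})
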