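"""Candidate endogenous-reference screening on a discovery TPM matrix.

A three-stage filter cascade identifies miRNAs that are expressed consistently
in both groups and abundant enough for reliable qPCR:

1. exclude miRNAs differentially expressed between groups (P < p_cut) or with
   a pooled mean TPM below ``min_mean_tpm``;
2. exclude miRNAs whose case/control mean-TPM ratio falls outside
   ``[ratio_low, ratio_high]``;
3. rank survivors by coefficient of variation (ascending) and keep the first
   ``top_k`` whose pooled mean TPM exceeds ``min_tpm_for_top``.

The pooled mean over all samples is used for the abundance cutoffs; the ratio
uses group means.  CV is the sample standard deviation (n-1) over all samples
divided by the pooled mean.  Ties in CV break by higher pooled mean, then id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ValidationError
from .diffexpr import DETable

__all__ = ["CandidateSelection", "compute_cv", "candidate_filter"]


def compute_cv(values) -> float:
    """Coefficient of variation: sample SD (n-1 denominator) over the mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValidationError("CV needs at least 2 values")
    mean = arr.mean()
    if mean <= 0:
        raise ValidationError("CV undefined for nonpositive mean")
    return float(arr.std(ddof=1) / mean)


@dataclass
class CandidateSelection:
    """Audit table, ordered shortlist, and stage-wise attrition of the cascade.

    ``table`` holds one row per miRNA (sorted by CV ascending with the tie
    rule applied) with per-stage pass flags; ``selected`` is the final ordered
    shortlist; ``attrition`` records survivor counts after each stage.  An
    empty survivor set is a valid result, not an error.
    """

    table: pd.DataFrame
    selected: list[str]
    attrition: dict[str, int]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="miRNA")


def candidate_filter(
    m: ExpressionMatrix,
    de: DETable,
    p_cut: float = 0.05,
    ratio_low: float = 0.75,
    ratio_high: float = 1.3,
    min_mean_tpm: float = 1.0,
    top_k: int = 8,
    min_tpm_for_top: float = 50.0,
) -> CandidateSelection:
    """Run the candidate-reference filter cascade on a TPM matrix.

    ``de`` must provide a P value for every miRNA in the matrix.  The returned
    shortlist is ordered by ascending CV.
    """
    if m.unit != "tpm":
        raise ValidationError("candidate_filter expects a TPM matrix")
    for thr in (p_cut, ratio_low, ratio_high, min_mean_tpm, min_tpm_for_top):
        if thr <= 0:
            raise ValidationError("thresholds must be positive")
    missing = m.features.difference(de.table.index)
    if len(missing):
        raise ValidationError(f"DE table lacks entries for: {missing.tolist()[:5]}")

    vals = m.values
    case = m.group_values("case")
    ctrl = m.group_values("control")
    pooled_mean = vals.mean(axis=1)
    case_mean = case.mean(axis=1)
    ctrl_mean = ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = case_mean / ctrl_mean
        cv = vals.std(axis=1, ddof=1) / pooled_mean
    cv = cv.where(pooled_mean > 0)
    pvalue = de.table.loc[m.features, "pvalue"]

    pass1 = (pvalue >= p_cut) & (pooled_mean >= min_mean_tpm)
    pass2 = pass1 & ratio.between(ratio_low, ratio_high, inclusive="both").fillna(False)

    table = pd.DataFrame(
        {
            "case_mean": case_mean,
            "control_mean": ctrl_mean,
            "pooled_mean": pooled_mean,
            "ratio": ratio,
            "cv": cv,
            "pvalue": pvalue,
            "pass_stage1": pass1,
            "pass_stage2": pass2,
        }
    )
    # deterministic CV order: ascending CV, ties by higher pooled mean, then id
    table = (
        table.assign(_id=table.index.astype(str))
        .sort_values(
            by=["cv", "pooled_mean", "_id"],
            ascending=[True, False, True],
            kind="mergesort",
            na_position="last",
        )
        .drop(columns="_id")
    )

    survivors = table.index[table["pass_stage2"]]
    abundant = table.loc[survivors, "pooled_mean"] > min_tpm_for_top
    selected = list(survivors[abundant][:top_k])
    table["selected"] = table.index.isin(selected)

    attrition = {
        "input": int(len(table)),
        "stage1_de_and_abundance": int(pass1.sum()),
        "stage2_ratio": int(pass2.sum()),
        "stage3_selected": len(selected),
    }
    return CandidateSelection(table, selected, attrition)
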