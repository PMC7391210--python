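"""Multi-reference-normalized relative expression from qPCR Ct values.

Each target Ct is normalized against the geometric mean of the reference
assays' back-transformed quantities 2^-Ct — equivalently, the arithmetic mean
of the reference Cts:

    dCt_ts = Ct_target,s - mean(Ct_ref,s over references)
    relative expression = 2^-dCt, reported alongside log10(2^-dCt)

The alternative reading (geometric mean of the raw Ct values themselves) is
available behind ``normalizer="ct_geomean"`` and differs negligibly for Cts in
a narrow range.  Amplification efficiency is fixed at 2.

Samples missing any reference Ct are dropped with a logged warning (never
silently imputed); samples missing a target Ct propagate missing values for
that target only.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .containers import CtMatrix, ValidationError

__all__ = ["delta_ct"]

logger = logging.getLogger(__name__)

LOG10_2 = np.log10(2.0)


def delta_ct(
    ct: CtMatrix,
    targets: Sequence[str],
    references: Sequence[str],
    normalizer: str = "quantity_geomean",
) -> pd.DataFrame:
    """Relative expression of ``targets`` normalized to ``references``.

    Returns a long-format DataFrame with one row per (sample, target):
    sample, group, target, delta_ct, rel_expr (2^-dCt), log10_rel_expr,
    references (joined id string).
    """
    targets = list(targets)
    references = list(references)
    if not references:
        raise ValidationError("references must be nonempty")
    overlap = set(targets) & set(references)
    if overlap:
        raise ValidationError(f"targets and references overlap: {sorted(overlap)}")
    missing = [a for a in targets + references if a not in ct.values.index]
    if missing:
        raise ValidationError(f"assays not present in Ct matrix: {missing}")
    if normalizer not in ("quantity_geomean", "ct_geomean"):
        raise ValidationError(f"unknown normalizer {normalizer!r}")

    ref_ct = ct.values.loc[references]
    usable = ref_ct.notna().all(axis=0)
    dropped = list(ref_ct.columns[~usable])
    if dropped:
        logger.warning(
            "dropping %d sample(s) with missing reference Ct: %s", len(dropped), dropped
        )
    ref_ct = ref_ct.loc[:, usable]
    if normalizer == "quantity_geomean":
        # geometric mean of 2^-Ct quantities == arithmetic mean of Cts
        norm = ref_ct.mean(axis=0)
    else:
        norm = pd.Series(_stats.gmean(ref_ct, axis=0), index=ref_ct.columns)

    rows = []
    for target in targets:
        t_ct = ct.values.loc[target, norm.index]
        dct = t_ct - norm
        rel = np.power(2.0, -dct)
        rows.append(
            pd.DataFrame(
                {
                    "sample": norm.index,
                    "group": ct.groups.loc[norm.index].to_numpy(),
                    "target": target,
                    "delta_ct": dct.to_numpy(),
                    "rel_expr": rel.to_numpy(),
                    "log10_rel_expr": (-dct * LOG10_2).to_numpy(),
                    "references": ";".join(references),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
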