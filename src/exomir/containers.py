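"""In-memory containers for expression matrices and qPCR cycle-threshold panels.

Two substrate types run through the whole pipeline:

* :class:`ExpressionMatrix` — feature x sample abundances (raw read counts or
  TPM) with a case/control label per sample.  Substrate of differential
  expression and candidate reference screening.
* :class:`CtMatrix` — assay x sample qPCR cycle-threshold (Ct) values, missing
  readings allowed (undetected wells).  Substrate of stability analysis and
  relative quantification.

Both validate on construction so downstream code can assume well-formed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("case", "control")

#: Present Ct values must fall in this open interval (PCR cycles).
CT_RANGE = (0.0, 45.0)


class ValidationError(ValueError):
    """Raised when input data violates a container invariant."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicated {what}: {dups}")


def _check_groups(values: pd.DataFrame, groups: pd.Series) -> pd.Series:
    groups = groups.astype(str)
    missing = [s for s in values.columns if s not in groups.index]
    if missing:
        raise ValidationError(f"samples without a group label: {missing}")
    groups = groups.loc[values.columns]
    bad = sorted(set(groups) - set(GROUPS))
    if bad:
        raise ValidationError(f"group labels must be in {GROUPS}, got {bad}")
    return groups


@dataclass
class ExpressionMatrix:
    """Feature x sample abundance matrix with group labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with sample ids as columns.  All
        entries must be finite and nonnegative.
    groups
        Series mapping sample id -> ``"case"`` or ``"control"``; must cover
        every sample in ``values``.
    unit
        Either ``"count"`` (raw read counts) or ``"tpm"``.
    """

    values: pd.DataFrame
    groups: pd.Series
    unit: str = "count"

    def __post_init__(self) -> None:
        if self.unit not in ("count", "tpm"):
            raise ValidationError(f"unit must be 'count' or 'tpm', got {self.unit!r}")
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValidationError("expression values must be finite")
        if (arr < 0).any():
            bad = self.values.columns[(arr < 0).any(axis=0)].tolist()
            raise ValidationError(f"negative expression values in samples {bad}")
        self.groups = _check_groups(self.values, self.groups)

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def case_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "case"])

    @property
    def control_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "control"])

    def group_values(self, group: str) -> pd.DataFrame:
        """Sub-matrix restricted to one group's samples."""
        if group not in GROUPS:
            raise ValidationError(f"unknown group {group!r}")
        return self.values.loc[:, self.groups.index[self.groups == group]]


@dataclass
class CtMatrix:
    """Assay x sample qPCR cycle-threshold matrix; NaN marks missing readings.

    A missing (NaN) entry means the assay did not cross threshold within the
    run (undetected), which is distinct from any numeric Ct — the distinction
    matters for the mean-Ct exclusion rule and for quantification.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "assay ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy(dtype=float)
        present = arr[~np.isnan(arr)]
        lo, hi = CT_RANGE
        if present.size and ((present <= lo) | (present >= hi)).any():
            raise ValidationError(
                f"present Ct values must lie in the open interval {CT_RANGE}"
            )
        self.values = self.values.astype(float)
        self.groups = _check_groups(self.values, self.groups)

    @property
    def assays(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def case_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "case"])

    @property
    def control_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "control"])

    def group_values(self, group: str) -> pd.DataFrame:
        if group not in GROUPS:
            raise ValidationError(f"unknown group {group!r}")
        return self.values.loc[:, self.groups.index[self.groups == group]]

    def subset(self, assays: list[str]) -> "CtMatrix":
        """New CtMatrix restricted to the given assays (order preserved)."""
        missing = [a for a in assays if a not in self.values.index]
        if missing:
            raise ValidationError(f"assays not present: {missing}")
        return CtMatrix(self.values.loc[assays].copy(), self.groups.copy())
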