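"""Rank-based group comparisons and ROC/AUC diagnostic evaluation.

Mann-Whitney U and Kruskal-Wallis H with midrank ties, per-group average
ranks (the rank-sum identity sum_g n_g * Rbar_g = N(N+1)/2 holds by
construction), and ROC analysis where the AUC is the Mann-Whitney probability
that a random case scores above a random control (ties count 1/2).  The AUC
standard error uses the Hanley-McNeil distribution-free formula by default,
with the DeLong placement-value variance as an option; the 95% CI is
AUC +- 1.96*SE clipped to [0,1] and the P value tests AUC = 0.5 by a normal
z statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import ValidationError

__all__ = [
    "RankTestResult",
    "RocResult",
    "mann_whitney",
    "kruskal_wallis",
    "roc_auc",
    "ci_from_auc_se",
]

Z_95 = 1.96


@dataclass
class RankTestResult:
    """Rank-test summary: U (two groups) or H (k groups), two-sided P, and
    per-group sizes and average ranks."""

    statistic: float
    pvalue: float
    group_sizes: dict
    average_ranks: dict
    method: str
    exact: bool = False


@dataclass
class RocResult:
    marker: str
    auc: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_case: int
    n_control: int
    se_method: str = "hanley-mcneil"


def _average_ranks(groups: dict[str, np.ndarray]) -> dict[str, float]:
    pooled = np.concatenate(list(groups.values()))
    ranks = stats.rankdata(pooled)
    out = {}
    start = 0
    for name, vals in groups.items():
        out[name] = float(ranks[start : start + len(vals)].mean())
        start += len(vals)
    return out


def mann_whitney(x, y, exact_max_n: int = 12) -> RankTestResult:
    """Two-sided Mann-Whitney test; reports U = min(U1, U2).

    Uses exact enumeration when the combined sample size is at most
    ``exact_max_n`` and there are no ties; otherwise the tie-corrected normal
    approximation without continuity correction (the convention of common
    clinical statistics software).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    use_exact = (x.size + y.size) <= exact_max_n and not has_ties
    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    u1 = float(res.statistic)
    u = min(u1, x.size * y.size - u1)
    return RankTestResult(
        statistic=u,
        pvalue=float(res.pvalue),
        group_sizes={"x": int(x.size), "y": int(y.size)},
        average_ranks=_average_ranks({"x": x, "y": y}),
        method="mann-whitney",
        exact=use_exact,
    )


def kruskal_wallis(*groups) -> RankTestResult:
    """Kruskal-Wallis H with tie correction; P from chi-square with k-1 df."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("kruskal_wallis needs at least 2 groups")
    for i, g in enumerate(arrays):
        if g.size == 0:
            raise ValidationError(f"group {i} is empty")
    if np.ptp(np.concatenate(arrays)) == 0:
        h, p = 0.0, 1.0  # all values identical; H degenerates to 0
    else:
        h, p = stats.kruskal(*arrays)
    named = {f"group{i + 1}": g for i, g in enumerate(arrays)}
    return RankTestResult(
        statistic=float(h),
        pvalue=float(p),
        group_sizes={k: int(v.size) for k, v in named.items()},
        average_ranks=_average_ranks(named),
        method="kruskal-wallis",
    )


def ci_from_auc_se(auc: float, se: float, z: float = Z_95) -> tuple[float, float]:
    """Normal-approximation CI: auc +- z*se, clipped to [0, 1]."""
    if se < 0:
        raise ValidationError("se must be nonnegative")
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def _hanley_mcneil_se(auc: float, n1: int, n2: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc) + (n1 - 1) * (q1 - auc**2) + (n2 - 1) * (q2 - auc**2)
    ) / (n1 * n2)
    return float(np.sqrt(max(var, 0.0)))


def _delong_se(case_scores: np.ndarray, control_scores: np.ndarray, auc: float) -> float:
    # placement values: for each case, fraction of controls it beats (ties 1/2)
    v10 = np.array(
        [
            ((s > control_scores).sum() + 0.5 * (s == control_scores).sum())
            / control_scores.size
            for s in case_scores
        ]
    )
    v01 = np.array(
        [
            ((case_scores > s).sum() + 0.5 * (case_scores == s).sum())
            / case_scores.size
            for s in control_scores
        ]
    )
    var = v10.var(ddof=1) / case_scores.size + v01.var(ddof=1) / control_scores.size
    return float(np.sqrt(max(var, 0.0)))


def roc_auc(
    scores,
    labels,
    direction: str = "case_low",
    marker: str = "",
    se_method: str = "hanley-mcneil",
) -> RocResult:
    """AUC of ``scores`` for separating cases from controls.

    Parameters
    ----------
    scores
        Per-sample marker values (e.g. delta-Ct).
    labels
        Per-sample group labels, ``"case"``/``"control"`` (or booleans, True =
        case).
    direction
        ``"case_low"`` if lower scores indicate cases (the delta-Ct
        orientation: lower dCt = more expression), ``"case_high"`` otherwise.
        Never auto-flipped.
    se_method
        ``"hanley-mcneil"`` (default) or ``"delong"``.

    AUC is the probability a random case outranks a random control, ties
    counting one half — computed from midranks, identical to exhaustive pair
    counting.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind == "b":
        is_case = labels
    else:
        is_case = labels == "case"
    n1 = int(is_case.sum())
    n2 = int((~is_case).sum())
    if n1 == 0 or n2 == 0:
        raise ValidationError("both classes must be present")
    if direction not in ("case_low", "case_high"):
        raise ValidationError(f"unknown direction {direction!r}")
    oriented = -scores if direction == "case_low" else scores

    ranks = stats.rankdata(oriented)
    auc = float((ranks[is_case].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n2))

    if se_method == "hanley-mcneil":
        se = _hanley_mcneil_se(auc, n1, n2)
    elif se_method == "delong":
        se = _delong_se(oriented[is_case], oriented[~is_case], auc)
    else:
        raise ValidationError(f"unknown se_method {se_method!r}")

    if se > 0:
        z = (auc - 0.5) / se
        pvalue = float(2.0 * stats.norm.sf(abs(z)))
    else:
        pvalue = 1.0 if auc == 0.5 else 0.0
    lo, hi = ci_from_auc_se(auc, se)
    return RocResult(
        marker=marker,
        auc=auc,
        se=se,
        ci_low=lo,
        ci_high=hi,
        pvalue=pvalue,
        n_case=n1,
        n_control=n2,
        se_method=se_method,
    )
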