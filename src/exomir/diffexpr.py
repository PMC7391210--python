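"""Count normalization and two-group negative-binomial differential expression.

The test follows the classic NB exact-test approach for small two-group
RNA-seq designs: median-of-ratios size factors, per-gene dispersion estimated
by method of moments on normalized counts (floored at 0 and blended with a
fitted mean-dispersion trend ``a0 + a1/mean`` by taking the maximum), and a
conditional exact test on the split of a gene's total count between the two
groups, with a two-sided P defined as ``min(1, 2 * min(tail probabilities))``.
Numerical equivalence with any historical implementation is not a goal; with
dispersion forced to 0 the test reduces exactly to the conditional binomial
(Poisson-limit) enumeration.

No multiple-testing correction is applied to the screening filter (it operates
on raw P, matching the upstream study design); a Benjamini-Hochberg column is
emitted for information only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, ValidationError

__all__ = [
    "DETable",
    "tpm_normalize",
    "size_factors",
    "nb_test",
    "apply_de_filter",
]

#: pseudocount added to normalized group means when one of them is zero
ZERO_MEAN_PSEUDOCOUNT = 1.0


@dataclass
class DETable:
    """Per-gene differential-expression results plus the thresholds applied.

    ``table`` is indexed by miRNA id with columns: case_mean, control_mean,
    log2FoldChange, pvalue, padj (informational BH), direction (up/down/ns),
    zero_expression (True where the pseudocount was used or both means are 0).
    """

    table: pd.DataFrame
    p_cut: float = 0.05
    lfc_cut: float = 0.5

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="miRNA")


def tpm_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample to transcripts-per-million (column sums of 1e6).

    Mature miRNAs are treated as equal length, so no length normalization is
    applied: TPM_i = count_i / sum(counts) * 1e6 per sample.
    """
    if m.unit != "count":
        raise ValidationError("tpm_normalize expects a count matrix")
    totals = m.values.sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValidationError(f"samples with zero total count: {zero}")
    tpm = m.values / totals * 1e6
    return ExpressionMatrix(tpm, m.groups.copy(), unit="tpm")


def size_factors(m: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios library-size factors.

    factor_j = median over genes (with positive geometric mean across samples)
    of count_ij / geomean_i.
    """
    if m.unit != "count":
        raise ValidationError("size_factors expects a count matrix")
    counts = m.values.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    log_geo = log_counts.mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValidationError(
            "no gene has positive counts in every sample; size factors undefined"
        )
    ratios = counts[usable] / np.exp(log_geo[usable])[:, None]
    factors = np.median(ratios, axis=0)
    if (factors <= 0).any():
        raise ValidationError("nonpositive size factor encountered")
    return pd.Series(factors, index=m.samples, name="size_factor")


def _dispersion_estimates(
    norm: np.ndarray, is_case: np.ndarray, sf: np.ndarray
) -> np.ndarray:
    """Per-gene NB dispersion: within-group method of moments, floored at 0,
    blended with a fitted ``a0 + a1/mean`` trend by taking the maximum."""
    q = norm.mean(axis=1)
    n1 = int(is_case.sum())
    n2 = int((~is_case).sum())
    var_case = norm[:, is_case].var(axis=1, ddof=1)
    var_ctrl = norm[:, ~is_case].var(axis=1, ddof=1)
    pooled = (var_case * (n1 - 1) + var_ctrl * (n2 - 1)) / (n1 + n2 - 2)
    shot = q * np.mean(1.0 / sf)  # expected Poisson noise on the common scale
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = np.where(q > 0, np.clip(pooled - shot, 0.0, None) / q**2, 0.0)
    # trend fit alpha ~ a0 + a1/q over expressed genes
    mask = q > 0
    alpha = mom.copy()
    if mask.sum() >= 3:
        x = np.column_stack([np.ones(mask.sum()), 1.0 / q[mask]])
        coef, *_ = np.linalg.lstsq(x, mom[mask], rcond=None)
        a0, a1 = np.clip(coef, 0.0, None)
        trend = np.where(mask, a0 + a1 / np.where(mask, q, 1.0), 0.0)
        alpha = np.maximum(mom, trend)
    return alpha


def _nb_logpmf(k: np.ndarray, mean: float, var: float) -> np.ndarray:
    """log pmf of an NB (or Poisson when var <= mean) with given mean/variance."""
    if mean <= 0:
        out = np.full_like(np.asarray(k, dtype=float), -np.inf)
        out[np.asarray(k) == 0] = 0.0
        return out
    if var <= mean * (1 + 1e-12):
        return stats.poisson.logpmf(k, mean)
    r = mean**2 / (var - mean)
    p = r / (r + mean)
    return stats.nbinom.logpmf(k, r, p)


def _exact_two_sided_p(
    k_case: int, k_total: int, mu_a: float, var_a: float, mu_b: float, var_b: float
) -> float:
    """Conditional exact two-sided P for the observed case/control split of a
    gene's total count; tails doubled, capped at 1."""
    a = np.arange(k_total + 1)
    logp = _nb_logpmf(a, mu_a, var_a) + _nb_logpmf(k_total - a, mu_b, var_b)
    finite = np.isfinite(logp)
    if not finite.any():
        return 1.0
    w = np.zeros_like(logp)
    w[finite] = np.exp(logp[finite] - logp[finite].max())
    w /= w.sum()
    lower = w[: k_case + 1].sum()
    upper = w[k_case:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def nb_test(
    m: ExpressionMatrix,
    dispersion: float | None = None,
    p_cut: float = 0.05,
    lfc_cut: float = 0.5,
) -> DETable:
    """Two-group NB exact test on a count matrix.

    Parameters
    ----------
    m
        Count matrix with case/control labels; at least two samples per group.
    dispersion
        If given, a fixed NB dispersion alpha used for every gene (0 gives the
        Poisson-limit conditional test); otherwise estimated per gene.

    Returns a :class:`DETable` with log2FC computed on size-factor-normalized
    group means (pseudocount 1 when one mean is zero, flagged), exact
    conditional P values (P = 1 for zero-expression genes), an informational
    BH-adjusted column, and direction calls at the stored thresholds.
    """
    if len(m.case_samples) < 2 or len(m.control_samples) < 2:
        raise ValidationError("nb_test needs at least 2 samples per group")
    sf = size_factors(m)
    counts = m.values.to_numpy(dtype=float)
    sf_arr = sf.to_numpy()
    norm = counts / sf_arr
    is_case = np.array([g == "case" for g in m.groups.loc[m.samples]])

    case_mean = norm[:, is_case].mean(axis=1)
    ctrl_mean = norm[:, ~is_case].mean(axis=1)
    zero_flag = (case_mean == 0) | (ctrl_mean == 0)
    num = np.where(zero_flag, case_mean + ZERO_MEAN_PSEUDOCOUNT, case_mean)
    den = np.where(zero_flag, ctrl_mean + ZERO_MEAN_PSEUDOCOUNT, ctrl_mean)
    log2fc = np.log2(num / den)

    if dispersion is None:
        alpha = _dispersion_estimates(norm, is_case, sf_arr)
    else:
        if dispersion < 0:
            raise ValidationError("dispersion must be nonnegative")
        alpha = np.full(counts.shape[0], float(dispersion))

    q = norm.mean(axis=1)
    s_a = sf_arr[is_case].sum()
    s_b = sf_arr[~is_case].sum()
    s2_a = (sf_arr[is_case] ** 2).sum()
    s2_b = (sf_arr[~is_case] ** 2).sum()

    raw_case = counts[:, is_case].sum(axis=1).round().astype(np.int64)
    raw_ctrl = counts[:, ~is_case].sum(axis=1).round().astype(np.int64)

    pvals = np.ones(counts.shape[0])
    for i in range(counts.shape[0]):
        k_total = int(raw_case[i] + raw_ctrl[i])
        if k_total == 0:
            continue
        mu_a = q[i] * s_a
        mu_b = q[i] * s_b
        var_a = mu_a + alpha[i] * q[i] ** 2 * s2_a
        var_b = mu_b + alpha[i] * q[i] ** 2 * s2_b
        pvals[i] = _exact_two_sided_p(int(raw_case[i]), k_total, mu_a, var_a, mu_b, var_b)

    padj = stats.false_discovery_control(np.clip(pvals, 0.0, 1.0), method="bh")
    direction = np.where(
        (pvals < p_cut) & (log2fc >= lfc_cut),
        "up",
        np.where((pvals < p_cut) & (log2fc <= -lfc_cut), "down", "ns"),
    )
    table = pd.DataFrame(
        {
            "case_mean": case_mean,
            "control_mean": ctrl_mean,
            "log2FoldChange": log2fc,
            "pvalue": pvals,
            "padj": padj,
            "direction": direction,
            "zero_expression": zero_flag,
        },
        index=m.features,
    )
    return DETable(table, p_cut=p_cut, lfc_cut=lfc_cut)


def apply_de_filter(
    t: DETable, p_cut: float = 0.05, lfc_cut: float = 0.5
) -> tuple[list[str], list[str]]:
    """Split a DE table into up/down lists at the screening thresholds.

    Strictly ``P < p_cut``; inclusively ``|log2FC| >= lfc_cut``.
    """
    if p_cut <= 0 or lfc_cut <= 0:
        raise ValidationError("thresholds must be positive")
    tab = t.table
    sig = tab["pvalue"] < p_cut
    up = tab.index[sig & (tab["log2FoldChange"] >= lfc_cut)].tolist()
    down = tab.index[sig & (tab["log2FoldChange"] <= -lfc_cut)].tolist()
    return up, down
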