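"""Reference-gene stability algorithms and RefFinder-style consensus ranking.

Implements the four stability statistics commonly reported for qPCR reference
panels, plus their consensus aggregation:

* **geNorm** — pairwise variation V_jk = sample SD over samples of
  log2(Q_j/Q_k) of relative quantities Q = E^(minCt - Ct); per-gene stability
  M_j = mean of V_jk over partners; stepwise elimination of the max-M gene.
* **NormFinder** — model-based: two-way decomposition of log-scale expression
  into gene, group and gene-x-group (intergroup) terms, bias-corrected
  intragroup variances truncated at zero, intergroup contrasts shrunk toward
  zero by their sampling variance; stability = mean over groups of
  |shrunk contrast| + its standard error.
* **BestKeeper** — per-assay dispersion of raw Ct: SD[+-CP] as the mean
  absolute deviation from the arithmetic mean Ct (the original tool's
  convention; plain sample SD available), CV[%CP] = SD/mean*100, plus Pearson
  correlation of each assay with the per-sample geometric-mean BestKeeper
  index.
* **comparative delta-Ct** — per gene, the arithmetic mean over partners of
  the SD of pairwise Ct differences.

With amplification efficiency E = 2, geNorm's V_jk equals the delta-Ct
method's pairwise SD exactly — a cross-method identity exploited by the test
suite.

Smaller is more stable for all four statistics.  Consensus: competition
ranking (ties share the minimum rank) per method, then the geometric mean of
a gene's four ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CtMatrix, ValidationError

__all__ = [
    "GenormResult",
    "NormFinderResult",
    "PickResult",
    "genorm",
    "normfinder",
    "bestkeeper",
    "delta_ct_method",
    "reffinder_aggregate",
    "exclude_by_ct",
    "pick_references",
    "stability_report",
]

logger = logging.getLogger(__name__)


def _require_complete(values: pd.DataFrame, who: str) -> None:
    if values.isna().any().any():
        bad = values.index[values.isna().any(axis=1)].tolist()
        raise ValidationError(
            f"{who} requires complete Ct data; assays with missing values: {bad}. "
            "Exclude them (exclude_by_ct) or impute explicitly before calling."
        )


def _pairwise_sd(log_expr: pd.DataFrame) -> pd.DataFrame:
    """Symmetric matrix of sample SDs of pairwise differences of rows."""
    genes = log_expr.index
    arr = log_expr.to_numpy()
    k = len(genes)
    out = np.zeros((k, k))
    for j in range(k):
        diffs = arr[j][None, :] - arr  # partner - ... sign irrelevant for SD
        out[j] = diffs.std(axis=1, ddof=1)
    return pd.DataFrame(out, index=genes, columns=genes)


@dataclass
class GenormResult:
    """Stepwise geNorm output.

    ``m_values``: per gene, the M value at the round of its elimination (the
    final two genes share the final-round M — the algorithm cannot separate
    the last pair, so both receive the best rank downstream).
    ``trace``: per round, the remaining gene set and the full-panel M values.
    ``pairwise_v``: optional V(n/n+1) values of the normalization factor as
    genes are added in stability order (diagnostic only; not used to pick the
    number of references).
    """

    m_values: pd.Series
    trace: list[dict] = field(default_factory=list)
    pairwise_v: pd.Series | None = None
    ranking: list[str] = field(default_factory=list)


def genorm(ct: CtMatrix, efficiency: float = 2.0) -> GenormResult:
    """geNorm stability analysis with stepwise elimination.

    Relative quantities Q_ij = efficiency**(minCt_i - Ct_ij); the pairwise
    variation between genes j,k is the sample SD over samples of log2(Q_j/Q_k)
    and M_j is its mean over partners.  Each round removes the gene with the
    highest M and recomputes, down to the final pair.
    """
    values = ct.values
    if len(values) < 3:
        raise ValidationError("genorm needs at least 3 candidate genes")
    if values.shape[1] < 2:
        raise ValidationError("genorm needs at least 2 samples")
    _require_complete(values, "genorm")
    # log2 Q = log2(E) * (minCt - Ct); constant per-gene offsets drop out of SDs
    log_q = np.log2(efficiency) * (values.min(axis=1).to_numpy()[:, None] - values)
    log_q = pd.DataFrame(log_q, index=values.index, columns=values.columns)

    remaining = list(values.index)
    m_values: dict[str, float] = {}
    trace: list[dict] = []
    elimination: list[str] = []
    while len(remaining) >= 2:
        sub = log_q.loc[remaining]
        v = _pairwise_sd(sub)
        m = (v.sum(axis=1)) / (len(remaining) - 1)
        trace.append({"genes": list(remaining), "m": m.to_dict()})
        if len(remaining) == 2:
            for g in remaining:
                m_values[g] = float(m[g])
            break
        # eliminate the least stable gene; deterministic tie-break by id
        worst = m.sort_values(ascending=False, kind="mergesort").index[0]
        ties = m.index[m == m[worst]]
        worst = sorted(ties)[-1] if len(ties) > 1 else worst
        m_values[worst] = float(m[worst])
        elimination.append(worst)
        remaining.remove(worst)

    ranking = list(remaining) + list(reversed(elimination))
    pairwise_v = _genorm_pairwise_v(log_q, ranking)
    return GenormResult(
        m_values=pd.Series(m_values).loc[values.index],
        trace=trace,
        pairwise_v=pairwise_v,
        ranking=ranking,
    )


def _genorm_pairwise_v(log_q: pd.DataFrame, ranking: list[str]) -> pd.Series:
    """V(n/n+1): SD of log2 ratio of normalization factors built from the top
    n vs top n+1 genes in stability order."""
    out = {}
    for n in range(2, len(ranking)):
        nf_n = log_q.loc[ranking[:n]].mean(axis=0)
        nf_n1 = log_q.loc[ranking[: n + 1]].mean(axis=0)
        out[f"V{n}/{n + 1}"] = float((nf_n - nf_n1).std(ddof=1))
    return pd.Series(out, dtype=float)


@dataclass
class NormFinderResult:
    stability: pd.Series
    intergroup_deviation: pd.DataFrame | None = None
    intragroup_variance: pd.DataFrame | None = None
    #: "grouped" for the two-group model; "intragroup-only" fallback
    variant: str = "grouped"


def _two_way_residual_variance(block: np.ndarray) -> np.ndarray:
    """Bias-corrected per-gene residual variances from one group's k x n block.

    Residuals remove gene and sample effects; because the sample-mean step
    mixes genes, the naive per-gene mean square is biased by the other genes'
    variances.  Solving the expectation equations gives
    sigma2_i = (u_i - S/k^2) * k / (k - 2) with u_i the per-gene residual mean
    square and S the bias-corrected total; estimates are truncated at zero.
    """
    k, n = block.shape
    if n < 2:
        raise ValidationError("normfinder needs at least 2 samples per group")
    if k < 3:
        raise ValidationError("normfinder needs at least 3 genes")
    z = block - block.mean(axis=1, keepdims=True) - block.mean(axis=0, keepdims=True) + block.mean()
    u = (z**2).sum(axis=1) / (n - 1)
    total = u.sum() * k / (k - 1)
    sigma2 = (u - total / k**2) * k / (k - 2)
    return np.clip(sigma2, 0.0, None)


def normfinder(ct: CtMatrix, use_groups: bool = True) -> NormFinderResult:
    """Model-based stability values (smaller = more stable).

    Works on log-scale expression (-Ct up to an additive constant).  With two
    groups, the gene x group mean table is decomposed into gene, group and
    interaction terms; the interaction term d_ig (intergroup deviation) is
    shrunk toward zero by its estimated sampling variance and the stability
    value is the mean over groups of |shrunk d_ig| plus its standard error.
    With ``use_groups=False`` (or a single group present) falls back to the
    intragroup-only variant: stability = sqrt of the bias-corrected residual
    variance.
    """
    values = ct.values
    _require_complete(values, "normfinder")
    y = -values  # log2 expression up to an additive per-assay constant
    genes = values.index
    k = len(genes)

    group_names = [g for g in ("case", "control") if (ct.groups == g).any()]
    if not use_groups or len(group_names) < 2:
        if use_groups:
            logger.warning("normfinder: single group present; using intragroup-only variant")
        sigma2 = _two_way_residual_variance(y.to_numpy())
        return NormFinderResult(
            stability=pd.Series(np.sqrt(sigma2), index=genes),
            variant="intragroup-only",
        )

    blocks = {g: y.loc[:, ct.group_values(g).columns].to_numpy() for g in group_names}
    n_g = {g: blocks[g].shape[1] for g in group_names}
    G = len(group_names)

    sigma2 = pd.DataFrame(
        {g: _two_way_residual_variance(blocks[g]) for g in group_names}, index=genes
    )
    means = pd.DataFrame({g: blocks[g].mean(axis=1) for g in group_names}, index=genes)
    # gene x group interaction: remove gene and group main effects
    d = means.sub(means.mean(axis=1), axis=0).sub(means.mean(axis=0), axis=1) + float(
        means.to_numpy().mean()
    )

    # sampling variance of d_ig from the contrast weights ((G-1)/G and -1/G)
    var_d = pd.DataFrame(index=genes, columns=group_names, dtype=float)
    for g in group_names:
        own = ((G - 1) / G) ** 2 * sigma2[g] / n_g[g]
        others = sum(sigma2[h] / n_g[h] for h in group_names if h != g) / G**2
        var_d[g] = own + others

    stab_parts = []
    for g in group_names:
        dg = d[g].to_numpy()
        vg = var_d[g].to_numpy()
        gamma2 = max(0.0, (dg**2).sum() / (k - 1) - vg.mean())
        denom = gamma2 + vg
        with np.errstate(invalid="ignore", divide="ignore"):
            shrunk = np.where(denom > 0, dg * gamma2 / denom, 0.0)
            se = np.sqrt(np.where(denom > 0, gamma2 * vg / denom, 0.0))
        stab_parts.append(np.abs(shrunk) + se)
    stability = pd.Series(np.mean(stab_parts, axis=0), index=genes)
    return NormFinderResult(
        stability=stability,
        intergroup_deviation=d,
        intragroup_variance=sigma2,
        variant="grouped",
    )


def bestkeeper(ct: CtMatrix, use_sample_sd: bool = False) -> pd.DataFrame:
    """BestKeeper descriptive dispersion of raw Ct values.

    Returns a DataFrame with columns ``sd`` (SD[+-CP]: mean absolute deviation
    from the arithmetic mean Ct by default, plain sample SD if
    ``use_sample_sd``), ``cv_pct`` (CV[%CP] = sd/mean*100), ``mean_ct``, and
    the Pearson correlation ``r`` of each assay against the per-sample
    geometric-mean BestKeeper index (NaN when undefined).
    """
    values = ct.values
    if values.shape[1] < 2:
        raise ValidationError("bestkeeper needs at least 2 samples")
    mean_ct = values.mean(axis=1, skipna=True)
    if use_sample_sd:
        sd = values.std(axis=1, ddof=1)
    else:
        sd = (values.sub(mean_ct, axis=0)).abs().mean(axis=1, skipna=True)
    cv_pct = sd / mean_ct * 100.0

    complete = values.dropna(axis=1)
    r = pd.Series(np.nan, index=values.index)
    if complete.shape[1] >= 3:
        index = np.exp(np.log(complete).mean(axis=0))
        for g in values.index:
            x = complete.loc[g]
            if x.std(ddof=1) > 0 and index.std(ddof=1) > 0:
                r[g] = stats.pearsonr(x, index)[0]
    return pd.DataFrame({"sd": sd, "cv_pct": cv_pct, "mean_ct": mean_ct, "r": r})


def delta_ct_method(ct: CtMatrix, min_shared: int = 2) -> pd.Series:
    """Comparative delta-Ct stability: per gene, the mean over partners of the
    sample SD of pairwise Ct differences (pairwise-complete observations)."""
    values = ct.values
    if len(values) < 3:
        raise ValidationError("delta_ct_method needs at least 3 genes")
    if values.shape[1] < 2:
        raise ValidationError("delta_ct_method needs at least 2 samples")
    genes = list(values.index)
    arr = values.to_numpy()
    k = len(genes)
    sds = np.full((k, k), np.nan)
    for j in range(k):
        for l in range(j + 1, k):
            diff = arr[j] - arr[l]
            diff = diff[~np.isnan(diff)]
            if diff.size < min_shared:
                raise ValidationError(
                    f"genes {genes[j]!r} and {genes[l]!r} share fewer than "
                    f"{min_shared} samples with Ct present"
                )
            sds[j, l] = sds[l, j] = diff.std(ddof=1)
    avg = np.nanmean(np.where(np.eye(k, dtype=bool), np.nan, sds), axis=1)
    return pd.Series(avg, index=values.index, name="avg_stdev")


def reffinder_aggregate(statistics: pd.DataFrame) -> pd.DataFrame:
    """Consensus ranking across stability methods (smaller = more stable).

    ``statistics``: genes x methods matrix of stability statistics; every
    method must cover every gene.  Per-method competition ranks (ties share
    the minimum rank) are combined by geometric mean; output is sorted by
    consensus ascending with ties broken by mean rank then gene id.
    """
    if statistics.shape[1] < 2:
        raise ValidationError("consensus needs at least 2 methods")
    if statistics.isna().any().any():
        missing = {
            m: statistics.index[statistics[m].isna()].tolist()
            for m in statistics.columns
            if statistics[m].isna().any()
        }
        raise ValidationError(f"methods with missing statistics per gene: {missing}")
    ranks = statistics.apply(lambda col: stats.rankdata(col, method="min"), axis=0)
    ranks = pd.DataFrame(
        ranks.to_numpy(dtype=float),
        index=statistics.index,
        columns=[f"rank_{c}" for c in statistics.columns],
    )
    consensus = np.exp(np.log(ranks).mean(axis=1))
    out = pd.concat([statistics, ranks], axis=1)
    out["consensus"] = consensus
    out["mean_rank"] = ranks.mean(axis=1)
    out = (
        out.assign(_id=out.index.astype(str))
        .sort_values(by=["consensus", "mean_rank", "_id"], kind="mergesort")
        .drop(columns="_id")
    )
    return out


def exclude_by_ct(ct: CtMatrix, max_mean_ct: float = 33.0) -> tuple[CtMatrix, pd.DataFrame]:
    """Drop assays whose mean Ct exceeds ``max_mean_ct`` (strict >).

    Low-expression assays (late Ct) are unreliable references.  Returns the
    retained matrix and an exclusion log (assay, mean Ct, excluded flag).
    """
    mean_ct = ct.values.mean(axis=1, skipna=True)
    excluded = mean_ct > max_mean_ct
    log = pd.DataFrame({"mean_ct": mean_ct, "excluded": excluded})
    keep = list(ct.values.index[~excluded])
    if not keep:
        raise ValidationError(f"all assays exceed mean Ct {max_mean_ct}")
    for assay in ct.values.index[excluded]:
        logger.info("excluding %s: mean Ct %.2f > %.2f", assay, mean_ct[assay], max_mean_ct)
    return ct.subset(keep), log


@dataclass
class PickResult:
    references: list[str]
    #: per drop round: candidate mean Cts and the member removed
    trail: list[dict] = field(default_factory=list)


def pick_references(
    report: pd.DataFrame,
    ct: CtMatrix,
    n_final: int = 3,
    consensus_top: int = 4,
) -> PickResult:
    """Choose the final reference set from a consensus-ranked report.

    Takes the ``consensus_top`` best genes by consensus rank, then iteratively
    drops the member with the highest mean Ct (lowest expression) until
    ``n_final`` remain.  Ties in mean Ct drop the gene with the worse
    consensus.  ``report`` must be a ``reffinder_aggregate`` output (sorted,
    with a ``consensus`` column).
    """
    if consensus_top < n_final:
        raise ValidationError("consensus_top must be >= n_final")
    if len(report) < n_final:
        raise ValidationError(
            f"only {len(report)} candidates available, need {n_final}"
        )
    chosen = list(report.index[: min(consensus_top, len(report))])
    trail: list[dict] = []
    mean_ct = ct.values.mean(axis=1, skipna=True)
    consensus = report["consensus"]
    while len(chosen) > n_final:
        sub = pd.DataFrame(
            {"mean_ct": mean_ct.loc[chosen], "consensus": consensus.loc[chosen]}
        )
        drop = (
            sub.assign(_id=sub.index.astype(str))
            .sort_values(by=["mean_ct", "consensus", "_id"], ascending=[False, False, True], kind="mergesort")
            .index[0]
        )
        trail.append({"candidates": dict(sub["mean_ct"]), "dropped": drop})
        chosen.remove(drop)
    return PickResult(references=chosen, trail=trail)


def stability_report(
    ct: CtMatrix,
    efficiency: float = 2.0,
    bestkeeper_sample_sd: bool = False,
) -> pd.DataFrame:
    """Run all four stability methods on a Ct panel and aggregate.

    Returns one row per candidate with the four statistics (BestKeeper CV as
    an extra descriptive column), per-method ranks and the consensus
    geometric-mean rank, sorted most-stable first.
    """
    bk = bestkeeper(ct, use_sample_sd=bestkeeper_sample_sd)
    nf = normfinder(ct)
    gn = genorm(ct, efficiency=efficiency)
    dct = delta_ct_method(ct)
    statistics = pd.DataFrame(
        {
            "bestkeeper_sd": bk["sd"],
            "normfinder_stability": nf.stability,
            "genorm_m": gn.m_values,
            "delta_ct_avg_stdev": dct,
        }
    )
    out = reffinder_aggregate(statistics)
    out.insert(1, "bestkeeper_cv_pct", bk["cv_pct"].loc[out.index])
    return out
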