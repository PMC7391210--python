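"""End-to-end orchestration: simulate/load -> differential expression ->
candidate screening -> stability analysis -> reference picking -> relative
quantification -> rank tests and ROC.

A :class:`PipelineConfig` carries every threshold of the analysis with the
screening defaults the pipeline was designed around (P < 0.05,
|log2FC| >= 0.5, mean-TPM ratio in [0.75, 1.3], mean TPM >= 1, top 8 by CV
with TPM > 50, mean Ct <= 33, three final references), plus either file paths
or simulation configs for the discovery count matrix and the Ct panels.
Every run can write its resolved configuration and plain-TSV reports; given
the same config and seed, reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biostats, diffexpr, io, quantify, refselect, stability, synth
from .containers import CtMatrix, ExpressionMatrix, ValidationError

__all__ = [
    "PipelineConfig",
    "DiscoveryResult",
    "ValidationResult",
    "run_discovery",
    "run_validation",
    "run_all",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds, inputs and seed for a full pipeline run."""

    seed: int = 0
    # screening thresholds
    p_cut: float = 0.05
    lfc_cut: float = 0.5
    ratio_low: float = 0.75
    ratio_high: float = 1.3
    min_mean_tpm: float = 1.0
    top_k: int = 8
    min_tpm_for_top: float = 50.0
    max_mean_ct: float = 33.0
    n_refs: int = 3
    consensus_top: int = 4
    # inputs: file paths take precedence over simulation configs
    counts_path: str | None = None
    counts_metadata: str | None = None
    ct_discovery_path: str | None = None
    ct_discovery_metadata: str | None = None
    ct_validation_path: str | None = None
    ct_validation_metadata: str | None = None
    counts_sim: synth.CountSimConfig = field(default_factory=synth.CountSimConfig)
    ct_discovery_sim: synth.CtSimConfig = field(
        default_factory=lambda: synth.CtSimConfig(n_case=7, n_control=7)
    )
    ct_validation_sim: synth.CtSimConfig = field(default_factory=synth.CtSimConfig)

    def resolved_seeds(self) -> dict[str, int]:
        """Derive independent sub-seeds for the three simulated inputs."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        return {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(["counts", "ct_discovery", "ct_validation"], children)
        }

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("counts_sim", synth.CountSimConfig),
            ("ct_discovery_sim", synth.CtSimConfig),
            ("ct_validation_sim", synth.CtSimConfig),
        ):
            if key in d and isinstance(d[key], dict):
                sub_d = dict(d[key])
                for lk in ("reference_assays", "marker_assays"):
                    if lk in sub_d:
                        sub_d[lk] = [tuple(a) for a in sub_d[lk]]
                d[key] = sub(**sub_d)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class DiscoveryResult:
    counts: ExpressionMatrix
    de: diffexpr.DETable
    candidates: refselect.CandidateSelection
    ct: CtMatrix
    ct_exclusions: pd.DataFrame
    stability_report: pd.DataFrame
    references: list[str]
    pick_trail: list[dict]


@dataclass
class ValidationResult:
    ct: CtMatrix
    quant: pd.DataFrame
    rank_tests: pd.DataFrame
    roc: pd.DataFrame


def _load_counts(cfg: PipelineConfig, seed: int) -> ExpressionMatrix:
    if cfg.counts_path:
        if not cfg.counts_metadata:
            raise ValidationError("counts_metadata required with counts_path")
        return io.read_expression(cfg.counts_path, cfg.counts_metadata, unit="count")
    sim_cfg = dataclasses.replace(cfg.counts_sim, seed=seed)
    return synth.simulate_counts(sim_cfg).matrix


def _load_ct(path, metadata, sim_cfg: synth.CtSimConfig, seed: int) -> CtMatrix:
    if path:
        if not metadata:
            raise ValidationError("Ct metadata path required with a Ct path")
        return io.read_ct(path, metadata)
    return synth.simulate_ct(dataclasses.replace(sim_cfg, seed=seed)).ct


def run_discovery(cfg: PipelineConfig, outdir: str | Path | None = None) -> DiscoveryResult:
    """Discovery arm: DE screen, candidate cascade, stability, reference pick.

    Stages run in order (diffexpr -> refselect -> stability -> pick) and any
    stage failure is re-raised annotated with the stage name.  Artifacts are
    written as TSV when ``outdir`` is given.
    """
    seeds = cfg.resolved_seeds()
    stage = "load-counts"
    try:
        counts = _load_counts(cfg, seeds["counts"])
        stage = "diffexpr"
        de = diffexpr.nb_test(counts, p_cut=cfg.p_cut, lfc_cut=cfg.lfc_cut)
        tpm = diffexpr.tpm_normalize(counts)
        stage = "refselect"
        candidates = refselect.candidate_filter(
            tpm,
            de,
            p_cut=cfg.p_cut,
            ratio_low=cfg.ratio_low,
            ratio_high=cfg.ratio_high,
            min_mean_tpm=cfg.min_mean_tpm,
            top_k=cfg.top_k,
            min_tpm_for_top=cfg.min_tpm_for_top,
        )
        if not candidates.selected:
            logger.warning(
                "candidate cascade returned an empty shortlist (attrition: %s)",
                candidates.attrition,
            )
        stage = "stability"
        ct = _load_ct(
            cfg.ct_discovery_path,
            cfg.ct_discovery_metadata,
            cfg.ct_discovery_sim,
            seeds["ct_discovery"],
        )
        ct_kept, excl = stability.exclude_by_ct(ct, max_mean_ct=cfg.max_mean_ct)
        report = stability.stability_report(ct_kept)
        stage = "pick-references"
        picked = stability.pick_references(
            report, ct_kept, n_final=cfg.n_refs, consensus_top=cfg.consensus_top
        )
    except Exception as exc:
        raise RuntimeError(f"discovery failed at stage {stage!r}: {exc}") from exc

    result = DiscoveryResult(
        counts=counts,
        de=de,
        candidates=candidates,
        ct=ct,
        ct_exclusions=excl,
        stability_report=report,
        references=picked.references,
        pick_trail=picked.trail,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(outdir / "resolved_config.yaml")
        de.to_tsv(outdir / "de_table.tsv")
        candidates.to_tsv(outdir / "candidates.tsv")
        excl.to_csv(outdir / "ct_exclusions.tsv", sep="\t", index_label="assay")
        report.to_csv(outdir / "stability_report.tsv", sep="\t", index_label="gene")
        (outdir / "references.txt").write_text("\n".join(picked.references) + "\n")
        _write_discovery_summary(outdir / "summary.txt", cfg, result)
    return result


def _write_discovery_summary(path: Path, cfg: PipelineConfig, r: DiscoveryResult) -> None:
    up, down = diffexpr.apply_de_filter(r.de, cfg.p_cut, cfg.lfc_cut)
    lines = [
        "discovery run summary",
        f"genes tested: {len(r.de.table)}",
        f"DE at P<{cfg.p_cut}, |log2FC|>={cfg.lfc_cut}: {len(up)} up, {len(down)} down",
        f"candidate attrition: {r.candidates.attrition}",
        f"Ct exclusions (mean Ct > {cfg.max_mean_ct}): "
        f"{int(r.ct_exclusions['excluded'].sum())}",
        f"selected references: {', '.join(r.references) if r.references else '(none)'}",
    ]
    path.write_text("\n".join(lines) + "\n")


def run_validation(
    cfg: PipelineConfig,
    references: list[str],
    targets: list[str] | None = None,
    outdir: str | Path | None = None,
) -> ValidationResult:
    """Validation arm: quantify targets against the chosen references in an
    independent Ct cohort, then rank tests on log10 relative expression and
    ROC on delta-Ct per marker (lower delta-Ct = case orientation)."""
    seeds = cfg.resolved_seeds()
    ct = _load_ct(
        cfg.ct_validation_path,
        cfg.ct_validation_metadata,
        cfg.ct_validation_sim,
        seeds["ct_validation"],
    )
    missing = [a for a in references if a not in ct.values.index]
    if missing:
        raise ValidationError(f"reference assay(s) absent from validation panel: {missing}")
    if targets is None:
        targets = [a for a in ct.values.index if a not in references]
    quant = quantify.delta_ct(ct, targets=targets, references=references)

    rank_rows, roc_rows = [], []
    for target in targets:
        sub = quant[quant["target"] == target].dropna(subset=["delta_ct"])
        case = sub.loc[sub["group"] == "case", "log10_rel_expr"].to_numpy()
        ctrl = sub.loc[sub["group"] == "control", "log10_rel_expr"].to_numpy()
        mw = biostats.mann_whitney(case, ctrl)
        rank_rows.append(
            {
                "target": target,
                "n_case": len(case),
                "n_control": len(ctrl),
                "U": mw.statistic,
                "pvalue": mw.pvalue,
                "avg_rank_case": mw.average_ranks["x"],
                "avg_rank_control": mw.average_ranks["y"],
            }
        )
        roc = biostats.roc_auc(
            sub["delta_ct"].to_numpy(),
            sub["group"].to_numpy(),
            direction="case_low",
            marker=target,
        )
        roc_rows.append(
            {
                "marker": target,
                "auc": roc.auc,
                "se": roc.se,
                "pvalue": roc.pvalue,
                "ci_low": roc.ci_low,
                "ci_high": roc.ci_high,
            }
        )
    rank_tests = pd.DataFrame(rank_rows)
    roc_table = pd.DataFrame(roc_rows)

    result = ValidationResult(ct=ct, quant=quant, rank_tests=rank_tests, roc=roc_table)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        quant.to_csv(outdir / "relative_expression.tsv", sep="\t", index=False)
        rank_tests.to_csv(outdir / "rank_tests.tsv", sep="\t", index=False)
        roc_table.to_csv(outdir / "roc.tsv", sep="\t", index=False)
    return result


def run_all(cfg: PipelineConfig, outdir: str | Path | None = None) -> tuple[DiscoveryResult, ValidationResult]:
    """Discovery followed by validation with the discovery-picked references."""
    disc_out = Path(outdir) / "discovery" if outdir is not None else None
    val_out = Path(outdir) / "validation" if outdir is not None else None
    disc = run_discovery(cfg, outdir=disc_out)
    val = run_validation(cfg, references=disc.references, outdir=val_out)
    return disc, val
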