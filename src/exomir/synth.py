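"""Synthetic two-group count matrices and qPCR Ct panels with known planted
structure.

The count generator emulates a small-cohort serum-exosomal miRNA-seq discovery
design: gamma-Poisson (negative binomial, variance = mu + alpha*mu^2) counts
with log-normal per-gene baselines, log-normal library-size factors, a planted
fraction of differentially expressed genes at a fixed |log2FC|, and a block of
planted "reference-like" genes (no group effect, low dispersion, high
abundance).

The Ct generator emulates a qRT-PCR validation cohort: Gaussian Ct readings
around per-assay means, a fixed case-group Ct shift for biomarker assays, and a
detection limit above which a reading is recorded as missing.

Randomness is derived from one seed per config via ``numpy.random.SeedSequence``
stream-splitting: library sizes and each gene/assay get independent child
streams keyed by index, so enlarging the panel never perturbs earlier
genes/assays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CtMatrix, ExpressionMatrix

__all__ = [
    "ConfigError",
    "CountSimConfig",
    "CtSimConfig",
    "CountSimResult",
    "CtSimResult",
    "simulate_counts",
    "simulate_ct",
]


class ConfigError(ValueError):
    """Raised when a simulation config violates its invariants."""


@dataclass
class CountSimConfig:
    """Parameters of the two-group count simulation.

    Defaults mirror the discovery design the package targets: 6 case vs 6
    control samples and 1608 detected miRNAs of which 75 carry a group effect.
    """

    n_case: int = 6
    n_control: int = 6
    n_genes: int = 1608
    de_fraction: float = 75 / 1608
    de_log2fc: float = 1.0
    #: NB dispersion alpha in variance = mu + alpha * mu^2.
    dispersion: float = 0.05
    libsize_log_sd: float = 0.25
    #: log-normal baseline means: log counts ~ N(baseline_log_mean, baseline_log_sd).
    baseline_log_mean: float = 3.5
    baseline_log_sd: float = 1.2
    #: planted stable reference-like genes: no group effect, low dispersion,
    #: high abundance.
    n_stable: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ConfigError("need at least 2 samples per group")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigError("de_fraction must lie in [0, 1]")
        if self.dispersion < 0 or self.libsize_log_sd < 0 or self.baseline_log_sd < 0:
            raise ConfigError("dispersion and SD parameters must be nonnegative")
        if self.n_stable < 0 or self.n_stable > self.n_genes:
            raise ConfigError("n_stable must lie in [0, n_genes]")


@dataclass
class CtSimConfig:
    """Parameters of the qPCR Ct panel simulation.

    ``reference_assays`` are (name, mean Ct, within-group SD) triples with no
    group effect; ``marker_assays`` are (name, control mean Ct, case Ct shift,
    SD) — a negative shift means higher expression in cases.  Defaults mirror
    a 50-case / 25-control validation cohort with three stable reference
    assays and two case-upregulated markers.
    """

    n_case: int = 50
    n_control: int = 25
    reference_assays: list[tuple[str, float, float]] = field(
        default_factory=lambda: [
            ("ref-30a", 26.0, 0.4),
            ("ref-532", 27.0, 0.4),
            ("ref-U6", 26.5, 0.4),
        ]
    )
    marker_assays: list[tuple[str, float, float, float]] = field(
        default_factory=lambda: [
            ("marker-941", 30.0, -1.5, 1.0),
            ("marker-27a", 29.0, -0.7, 1.0),
        ]
    )
    #: Ct readings above this cycle count are recorded as missing.
    detection_limit: float = 38.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ConfigError("need at least 1 sample per group")
        if not self.reference_assays and not self.marker_assays:
            raise ConfigError("at least one assay must be configured")
        names = [a[0] for a in self.reference_assays] + [a[0] for a in self.marker_assays]
        if len(set(names)) != len(names):
            raise ConfigError("assay names must be unique")
        for name, mean, sd in self.reference_assays:
            if not 10.0 <= mean <= 40.0 or sd < 0:
                raise ConfigError(f"reference assay {name}: mean Ct in [10,40], SD >= 0")
        for name, mean, _shift, sd in self.marker_assays:
            if not 10.0 <= mean <= 40.0 or sd < 0:
                raise ConfigError(f"marker assay {name}: mean Ct in [10,40], SD >= 0")


@dataclass
class CountSimResult:
    matrix: ExpressionMatrix
    #: per gene: baseline_mean, planted log2fc (signed; 0 if none), is_de, is_stable
    truth: pd.DataFrame
    #: planted per-sample library-size factors (geometric mean 1)
    size_factors: pd.Series


@dataclass
class CtSimResult:
    ct: CtMatrix
    #: per assay: kind (reference/marker), control mean, case shift, sd
    truth: pd.DataFrame


def _sample_ids(n_case: int, n_control: int) -> tuple[list[str], pd.Series]:
    cases = [f"case_{i + 1:02d}" for i in range(n_case)]
    controls = [f"control_{i + 1:02d}" for i in range(n_control)]
    samples = cases + controls
    groups = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=samples, name="group"
    )
    return samples, groups


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson draw with variance mu + alpha*mu^2 (Poisson when alpha=0)."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(cfg: CountSimConfig) -> CountSimResult:
    """Simulate a two-group NB count matrix with planted DE and stable genes.

    Gene layout: the first ``n_stable`` (after reserving room for DE genes)
    are reference-like, the next ``round(de_fraction * n_genes)`` carry the
    planted effect (sign drawn per gene), the rest are null.  Identical config
    (including seed) yields byte-identical output.
    """
    cfg.validate()
    samples, groups = _sample_ids(cfg.n_case, cfg.n_control)
    n_samples = cfg.n_case + cfg.n_control
    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    n_stable = min(cfg.n_stable, cfg.n_genes - n_de)

    root = np.random.SeedSequence(cfg.seed)
    lib_ss, genes_ss = root.spawn(2)
    lib_rng = np.random.Generator(np.random.PCG64(lib_ss))
    log_factors = lib_rng.normal(0.0, cfg.libsize_log_sd, size=n_samples)
    log_factors -= log_factors.mean()  # geometric mean 1
    factors = np.exp(log_factors)

    gene_streams = genes_ss.spawn(cfg.n_genes)
    is_case = np.array([g == "case" for g in groups.loc[samples]])

    # high-abundance, low-dispersion profile for reference-like genes
    stable_mean = math.exp(cfg.baseline_log_mean + 2.0 * cfg.baseline_log_sd)
    stable_alpha = min(cfg.dispersion, 0.01)

    names, rows = [], []
    base_means = np.empty(cfg.n_genes)
    planted_lfc = np.zeros(cfg.n_genes)
    is_stable = np.zeros(cfg.n_genes, dtype=bool)
    is_de = np.zeros(cfg.n_genes, dtype=bool)

    for i in range(cfg.n_genes):
        rng = np.random.Generator(np.random.PCG64(gene_streams[i]))
        if i < n_stable:
            name = f"stable-{i + 1:04d}"
            base = stable_mean
            alpha = stable_alpha
            lfc = 0.0
            is_stable[i] = True
            rng.normal()  # burn the baseline draw to keep streams aligned
        else:
            base = float(
                np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd))
            )
            alpha = cfg.dispersion
            if i < n_stable + n_de:
                name = f"de-{i - n_stable + 1:04d}"
                sign = 1.0 if rng.random() < 0.5 else -1.0
                lfc = sign * cfg.de_log2fc
                is_de[i] = True
            else:
                name = f"null-{i - n_stable - n_de + 1:04d}"
                lfc = 0.0
        mu = base * factors * np.where(is_case, 2.0 ** lfc, 1.0)
        rows.append(_nb_draw(rng, mu, alpha))
        names.append(name)
        base_means[i] = base
        planted_lfc[i] = lfc

    values = pd.DataFrame(
        np.asarray(rows, dtype=np.int64), index=pd.Index(names, name="feature"),
        columns=samples,
    )
    truth = pd.DataFrame(
        {
            "baseline_mean": base_means,
            "planted_log2fc": planted_lfc,
            "is_de": is_de,
            "is_stable": is_stable,
        },
        index=values.index,
    )
    matrix = ExpressionMatrix(values, groups, unit="count")
    sf = pd.Series(factors, index=samples, name="size_factor")
    return CountSimResult(matrix, truth, sf)


def simulate_ct(cfg: CtSimConfig) -> CtSimResult:
    """Simulate a Ct panel: Gaussian Ct around configured means, case shift for
    marker assays, readings above the detection limit recorded as missing."""
    cfg.validate()
    samples, groups = _sample_ids(cfg.n_case, cfg.n_control)
    is_case = np.array([g == "case" for g in groups.loc[samples]])

    root = np.random.SeedSequence(cfg.seed)
    n_assays = len(cfg.reference_assays) + len(cfg.marker_assays)
    streams = root.spawn(n_assays)

    names, rows, meta = [], [], []
    idx = 0
    for name, mean, sd in cfg.reference_assays:
        rng = np.random.Generator(np.random.PCG64(streams[idx]))
        idx += 1
        ct = rng.normal(mean, sd, size=len(samples)) if sd > 0 else np.full(len(samples), mean)
        names.append(name)
        rows.append(ct)
        meta.append(("reference", mean, 0.0, sd))
    for name, mean, shift, sd in cfg.marker_assays:
        rng = np.random.Generator(np.random.PCG64(streams[idx]))
        idx += 1
        mu = mean + np.where(is_case, shift, 0.0)
        ct = rng.normal(mu, sd) if sd > 0 else mu.astype(float)
        names.append(name)
        rows.append(ct)
        meta.append(("marker", mean, shift, sd))

    values = pd.DataFrame(
        np.asarray(rows), index=pd.Index(names, name="assay"), columns=samples
    )
    values = values.mask(values > cfg.detection_limit)
    truth = pd.DataFrame(
        meta, index=values.index, columns=["kind", "control_mean_ct", "case_shift", "sd"]
    )
    return CtSimResult(CtMatrix(values, groups), truth)
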