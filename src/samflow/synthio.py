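"""Synthetic microarray cohorts with planted differential expression.

Emulates the statistical structure of a summarized, normalized Affymetrix-style
study: a bimodal log2 intensity distribution (an unexpressed low mode plus an
expressed high mode), heterogeneous gene-wise variances, a 2-phenotype x
2-condition design with 7-8 arrays per cell, additive per-array offsets, and a
configurable number of planted differentially expressed (DE) genes. Paired
datasets sharing a tunable fraction of DE effects support cross-dataset
concordance experiments. Every output is reproducible from the config seed and
accompanied by a ground-truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .ingest import ExpressionMatrix

TRUTH_COLUMNS = ["probeset_id", "true_effect", "is_de", "is_low", "gene_sd"]


def _default_group_sizes() -> dict[str, int]:
    # aged unimpaired/impaired x spatial/non-spatial, one cell reduced by the
    # excluded QC outlier array
    return {"AU-S": 8, "AU-NS": 8, "AI-S": 8, "AI-NS": 7}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic cohort.

    Defaults mirror the emulated study design: ~31k probesets, ~40% of genes in
    a low (unexpressed) intensity mode at log2 ~2 with the expressed mode at
    log2 ~8, gene SDs drawn from a scaled inverse-chi-square family, and DE
    planted between the two phenotypes at 2 gene-SD.
    """

    n_genes: int = 31000
    group_sizes: Mapping[str, int] = field(default_factory=_default_group_sizes)
    frac_low_expressed: float = 0.4
    low_mode_mean: float = 2.0
    high_mode_mean: float = 8.0
    mode_spread: float = 0.8  # per-gene baseline scatter within each mode
    gene_sd_shape: float = 4.0  # inverse-chi-square df; smaller = heavier tail
    gene_sd_scale: float = 0.25  # typical per-gene SD, log2 units
    n_de: int = 300
    effect_size: float = 2.0
    effect_in_sd_units: bool = True  # effect = effect_size * gene_sd
    de_up_fraction: float = 0.5  # fraction of planted effects up in de_phenotype
    de_phenotype: str = "AU"
    array_effect_sd: float = 0.1
    cross_dataset_share: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if not self.group_sizes:
            raise ConfigError("group_sizes must be non-empty")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ConfigError(f"group {g!r} has {n} arrays; need >= 2")
        for name in ("frac_low_expressed", "de_up_fraction", "cross_dataset_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.n_de < 0 or self.n_de > self.n_genes:
            raise ConfigError("n_de must lie in [0, n_genes]")
        if self.gene_sd_shape <= 0 or self.gene_sd_scale <= 0:
            raise ConfigError("gene_sd_shape and gene_sd_scale must be positive")
        if self.array_effect_sd < 0:
            raise ConfigError("array_effect_sd must be non-negative")
        phenos = {g.split("-")[0] for g in self.group_sizes}
        if self.n_de > 0 and self.de_phenotype not in phenos:
            raise ConfigError(
                f"de_phenotype {self.de_phenotype!r} not among group phenotypes {sorted(phenos)}"
            )


@dataclass
class GeneModel:
    """Per-gene generative parameters shared across paired datasets."""

    probeset_ids: pd.Index
    baseline_mean: np.ndarray
    gene_sd: np.ndarray
    is_low: np.ndarray


def _probeset_ids(n: int) -> pd.Index:
    return pd.Index([f"ps{i:06d}_at" for i in range(n)], name="probeset_id")


def _draw_gene_model(config: SimConfig, rng: np.random.Generator) -> GeneModel:
    is_low = rng.random(config.n_genes) < config.frac_low_expressed
    mode = np.where(is_low, config.low_mode_mean, config.high_mode_mean)
    baseline = mode + rng.normal(0.0, config.mode_spread, config.n_genes)
    # scaled inverse-chi-square: sd^2 = scale^2 * df / chi2(df)
    chi2 = rng.chisquare(config.gene_sd_shape, config.n_genes)
    gene_sd = config.gene_sd_scale * np.sqrt(config.gene_sd_shape / chi2)
    return GeneModel(_probeset_ids(config.n_genes), baseline, gene_sd, is_low)


def _draw_effects(
    config: SimConfig,
    model: GeneModel,
    rng: np.random.Generator,
    forced: dict[int, float] | None = None,
    n_extra: int | None = None,
) -> np.ndarray:
    """Per-gene log2 effect vector; DE planted among expressed genes only.

    ``forced`` maps gene index -> effect for genes shared with a paired
    dataset; ``n_extra`` further effects are drawn from the remaining
    expressed genes.
    """
    effects = np.zeros(config.n_genes)
    forced = forced or {}
    for idx, eff in forced.items():
        effects[idx] = eff
    n_extra = config.n_de - len(forced) if n_extra is None else n_extra
    high = np.flatnonzero(~model.is_low)
    pool = np.setdiff1d(high, np.fromiter(forced, dtype=int, count=len(forced)))
    if n_extra > len(pool):
        raise ConfigError(
            f"cannot plant {config.n_de} DE genes: only {len(high)} expressed genes"
        )
    if n_extra > 0:
        chosen = rng.choice(pool, size=n_extra, replace=False)
        sign = np.where(rng.random(n_extra) < config.de_up_fraction, 1.0, -1.0)
        mag = config.effect_size * (
            model.gene_sd[chosen] if config.effect_in_sd_units else 1.0
        )
        effects[chosen] = sign * mag
    return effects


def _sample_matrix(
    config: SimConfig,
    model: GeneModel,
    effects: np.ndarray,
    rng: np.random.Generator,
    sample_prefix: str = "",
) -> ExpressionMatrix:
    sample_ids, phenotypes, conditions = [], [], []
    for group, size in config.group_sizes.items():
        pheno, _, cond = group.partition("-")
        for k in range(1, size + 1):
            sample_ids.append(f"{sample_prefix}{group}_{k}")
            phenotypes.append(pheno)
            conditions.append(cond or "NA")
    n_samples = len(sample_ids)
    target = np.array([p == config.de_phenotype for p in phenotypes])
    means = model.baseline_mean[:, None] + effects[:, None] * target[None, :]
    offsets = rng.normal(0.0, config.array_effect_sd, n_samples) if config.array_effect_sd > 0 else np.zeros(n_samples)
    noise = rng.normal(0.0, 1.0, (config.n_genes, n_samples)) * model.gene_sd[:, None]
    values = pd.DataFrame(
        means + offsets[None, :] + noise,
        index=model.probeset_ids,
        columns=pd.Index(sample_ids, name="sample_id"),
    )
    samples = pd.DataFrame(
        {"phenotype": phenotypes, "condition": conditions},
        index=values.columns,
    )
    return ExpressionMatrix(values, samples)


def _truth_frame(model: GeneModel, effects: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probeset_id": model.probeset_ids,
            "true_effect": effects,
            "is_de": effects != 0.0,
            "is_low": model.is_low,
            "gene_sd": model.gene_sd,
        }
    )


def generate_cohort(config: SimConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate one cohort; returns the matrix and its ground-truth table.

    The truth table has one row per probeset with the planted log2 effect
    (positive = up in ``de_phenotype``), DE and low-mode flags, and the
    generating gene SD. Identical configs (including seed) give bit-identical
    output: independent RNG streams for gene structure, effects and noise are
    spawned from the config seed.
    """
    config.validate()
    rng_struct, rng_eff, rng_noise = _spawn(config.seed, 3)
    model = _draw_gene_model(config, rng_struct)
    effects = _draw_effects(config, model, rng_eff)
    matrix = _sample_matrix(config, model, effects, rng_noise)
    return matrix, _truth_frame(model, effects)


def generate_paired_datasets(
    config: SimConfig,
) -> tuple[
    tuple[ExpressionMatrix, pd.DataFrame],
    tuple[ExpressionMatrix, pd.DataFrame],
    list[str],
]:
    """Two cohorts over the same probesets sharing part of their DE effects.

    Exactly ``round(cross_dataset_share * n_de)`` DE genes are forced common to
    both datasets with identical (equal-signed) effects; each dataset's
    remaining DE genes are drawn independently, so additional chance overlap is
    possible. Gene baselines, SDs and low-mode flags are shared (same
    platform/biology); arrays and noise are independent. Returns the two
    (matrix, truth) pairs plus the forced-shared probeset IDs.
    """
    config.validate()
    rng_struct, rng_shared, rng_a_eff, rng_a, rng_b_eff, rng_b = _spawn(config.seed, 6)
    model = _draw_gene_model(config, rng_struct)

    n_shared = int(round(config.cross_dataset_share * config.n_de))
    high = np.flatnonzero(~model.is_low)
    if n_shared > len(high):
        raise ConfigError("too few expressed genes for the shared DE set")
    shared_idx = rng_shared.choice(high, size=n_shared, replace=False)
    sign = np.where(rng_shared.random(n_shared) < config.de_up_fraction, 1.0, -1.0)
    mag = config.effect_size * (
        model.gene_sd[shared_idx] if config.effect_in_sd_units else 1.0
    )
    forced = dict(zip(shared_idx.tolist(), (sign * mag).tolist()))

    eff_a = _draw_effects(config, model, rng_a_eff, forced=forced)
    eff_b = _draw_effects(config, model, rng_b_eff, forced=forced)
    mat_a = _sample_matrix(config, model, eff_a, rng_a, sample_prefix="a:")
    mat_b = _sample_matrix(config, model, eff_b, rng_b, sample_prefix="b:")
    shared_ids = sorted(model.probeset_ids[i] for i in forced)
    return (mat_a, _truth_frame(model, eff_a)), (mat_b, _truth_frame(model, eff_b)), shared_ids


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write a truth table as TSV with the fixed column order of TRUTH_COLUMNS."""
    truth[TRUTH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t")
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"truth file missing columns {missing}")
    return df[TRUTH_COLUMNS]


def config_with(config: SimConfig, **updates) -> SimConfig:
    """Functional update of a frozen SimConfig."""
    return replace(config, **updates)
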