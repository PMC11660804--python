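"""Synthetic count, covariate, and phenotype generation with known ground truth.

Emulates a bulk-RNA association study of roughly a hundred samples and ten
thousand genes: negative-binomial read counts around gene-specific lognormal
means scaled by per-sample lognormal library-size factors, and phenotypes
generated from the same mixed model the analysis assumes,

    y = C beta + sum_causal w_i b_i + sum_all z_i u_i + e,

with u_i ~ N(0, sigma_o^2/m) drawn on the standardized CPM of the simulated
counts themselves (so the polygenic assumption W u is exactly satisfiable),
e ~ N(0, sigma_e^2), sex/season fixed effects, and occasional additive
phenotype outliers large enough for the MAD filter to catch. The "truth"
(causal genes, effects, variance components, injected outliers) is recorded
separately and is never consumed by analysis stages.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .preprocess import (
    CountMatrix,
    PhenotypeTable,
    cpm,
    filter_expressed,
    standardize,
    tmm_normalize,
)

__all__ = ["SimConfig", "TruthTable", "simulate_counts", "simulate_phenotypes"]

SEX_LEVELS = ("F", "M")
SEASON_LEVELS = ("S1", "S2", "S3")

#: nb_dispersion sentinel for the Poisson limit (variance = mean).
POISSON_LIMIT = 0.0


class ConfigError(ValueError):
    """A SimConfig field is out of range; the message names the field."""


@dataclass
class SimConfig:
    """Generative parameters. Defaults emulate the target study scale:
    ~115 samples, ~10k genes, a couple of causal genes, a moderate polygenic
    background (sigma_o^2/(sigma_o^2+sigma_e^2) = 0.4), lognormal library
    sizes and gene means, and a small additive-outlier contamination."""

    n_samples: int = 115
    n_genes: int = 10000
    n_causal: int = 2
    causal_effect_sd: float = 1.0
    polygenic_var_frac: float = 0.4
    residual_var: float = 1.0
    libsize_log_sd: float = 0.5
    nb_dispersion: float = 0.1
    mean_log_expr_sd: float = 1.5
    base_mean: float = 50.0
    sex_effect: float = 0.5
    season_effects: tuple = (0.0, 0.25, -0.25)
    outlier_rate: float = 0.02
    outlier_scale: float = 6.0
    traits: tuple = ("T1",)
    causal_effects: tuple | None = None
    seed: int = 0

    def validate(self) -> None:
        def positive(name):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive (got {getattr(self, name)})")

        def non_negative(name):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative (got {getattr(self, name)})")

        for name in ("n_samples", "n_genes", "residual_var", "mean_log_expr_sd", "base_mean",
                     "outlier_scale"):
            positive(name)
        for name in ("n_causal", "causal_effect_sd", "libsize_log_sd", "nb_dispersion"):
            non_negative(name)
        if self.n_causal > self.n_genes:
            raise ConfigError(f"n_causal ({self.n_causal}) exceeds n_genes ({self.n_genes})")
        if not 0.0 <= self.polygenic_var_frac < 1.0:
            raise ConfigError(
                f"polygenic_var_frac must lie in [0, 1) (got {self.polygenic_var_frac})"
            )
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ConfigError(f"outlier_rate must lie in [0, 1] (got {self.outlier_rate})")
        if len(self.season_effects) != 3:
            raise ConfigError("season_effects must have exactly 3 entries")
        if self.causal_effects is not None and len(self.causal_effects) != self.n_causal:
            raise ConfigError(
                f"causal_effects has {len(self.causal_effects)} entries but n_causal is {self.n_causal}"
            )
        if len(self.traits) == 0:
            raise ConfigError("traits must name at least one trait")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["season_effects"] = list(self.season_effects)
        d["traits"] = list(self.traits)
        if self.causal_effects is not None:
            d["causal_effects"] = list(self.causal_effects)
        return d


@dataclass
class TruthTable:
    """Ground truth per simulated trait; written separately, never read by analysis."""

    causal_gene_ids: dict = field(default_factory=dict)
    causal_effects: dict = field(default_factory=dict)
    polygenic_gene_ids: list = field(default_factory=list)
    polygenic_effects: dict = field(default_factory=dict)
    true_sigma_o2: dict = field(default_factory=dict)
    true_sigma_e2: dict = field(default_factory=dict)
    outlier_sample_ids: dict = field(default_factory=dict)


def simulate_counts(config: SimConfig) -> CountMatrix:
    """Negative-binomial gene x sample counts, reproducible from the seed.

    Gene means are lognormal around ``base_mean`` (sd of log =
    ``mean_log_expr_sd``); per-sample library-size factors are lognormal
    (sd of log = ``libsize_log_sd``); counts are NB with variance
    mu + nb_dispersion * mu^2 (Poisson at the 0 sentinel).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    m, n = config.n_genes, config.n_samples
    gene_means = config.base_mean * np.exp(rng.normal(0.0, config.mean_log_expr_sd, size=m))
    lib_factors = np.exp(rng.normal(0.0, config.libsize_log_sd, size=n))
    mu = gene_means[:, None] * lib_factors[None, :]
    if config.nb_dispersion == POISSON_LIMIT:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / config.nb_dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
    width = len(str(m))
    gene_ids = np.array([f"G{i:0{width}d}" for i in range(1, m + 1)], dtype=object)
    swidth = len(str(n))
    sample_ids = np.array([f"S{j:0{swidth}d}" for j in range(1, n + 1)], dtype=object)
    return CountMatrix(gene_ids=gene_ids, sample_ids=sample_ids, counts=counts.astype(np.int64))


def simulate_phenotypes(counts: CountMatrix, config: SimConfig):
    """Phenotypes from the analysis model itself, plus the ground-truth record.

    The expressed-gene filter, TMM/CPM normalization, and per-gene
    standardization applied here are the same operations the analysis uses,
    so the polygenic term is exactly of the assumed form. Each trait draws
    its own causal set, polygenic effects, residuals, and outliers.

    Returns ``(PhenotypeTable, TruthTable)``.
    """
    config.validate()
    mask = filter_expressed(counts)
    sub = counts.subset_genes(mask)
    if config.n_causal > sub.n_genes:
        raise ConfigError(
            f"n_causal ({config.n_causal}) exceeds the {sub.n_genes} genes passing the expression filter"
        )
    factors = tmm_normalize(sub)
    Z, _, _, kept = standardize(cpm(sub, factors))
    gene_ids = sub.gene_ids[kept]
    m_eff, n = Z.shape
    if config.n_causal > m_eff:
        raise ConfigError(
            f"n_causal ({config.n_causal}) exceeds the {m_eff} standardizable filtered genes"
        )

    cov_rng = np.random.default_rng([config.seed, 1])
    sex_idx = cov_rng.integers(0, 2, size=n)
    season_idx = cov_rng.integers(0, 3, size=n)
    sex = np.array([SEX_LEVELS[i] for i in sex_idx], dtype=object)
    season = np.array([SEASON_LEVELS[i] for i in season_idx], dtype=object)
    fixed = config.sex_effect * (sex_idx == 1) + np.asarray(config.season_effects)[season_idx]

    f = config.polygenic_var_frac
    sigma_e2 = config.residual_var
    sigma_o2 = f / (1.0 - f) * sigma_e2

    truth = TruthTable(polygenic_gene_ids=list(gene_ids))
    data = pd.DataFrame({"sex": sex, "season": season}, index=pd.Index(counts.sample_ids, name="sample_id"))
    for ti, trait in enumerate(config.traits):
        rng = np.random.default_rng([config.seed, 2, ti])
        causal_idx = np.sort(rng.choice(m_eff, size=config.n_causal, replace=False))
        if config.causal_effects is not None:
            b = np.asarray(config.causal_effects, dtype=float)
        else:
            b = rng.normal(0.0, config.causal_effect_sd, size=config.n_causal)
        u = rng.normal(0.0, np.sqrt(sigma_o2 / m_eff), size=m_eff) if sigma_o2 > 0 else np.zeros(m_eff)
        e = rng.normal(0.0, np.sqrt(sigma_e2), size=n)
        y = fixed + Z[causal_idx].T @ b + Z.T @ u + e
        out_flags = rng.random(n) < config.outlier_rate
        if out_flags.any():
            signs = rng.choice([-1.0, 1.0], size=int(out_flags.sum()))
            y = y.copy()
            y[out_flags] += signs * config.outlier_scale * y.std()
        data[trait] = y
        truth.causal_gene_ids[trait] = list(gene_ids[causal_idx])
        truth.causal_effects[trait] = b.copy()
        truth.polygenic_effects[trait] = u.copy()
        truth.true_sigma_o2[trait] = float(sigma_o2)
        truth.true_sigma_e2[trait] = float(sigma_e2)
        truth.outlier_sample_ids[trait] = list(np.asarray(counts.sample_ids)[out_flags])

    pheno = PhenotypeTable(
        data=data, traits=list(config.traits), covariates=["sex", "season"]
    )
    return pheno, truth
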