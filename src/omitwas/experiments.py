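"""Simulation-study harnesses built on the public pipeline operations.

Each study simulates data with known ground truth, runs the full per-trait
analysis (QC, normalization, ORM, REML, target-excluded scan), and measures
one operating characteristic: null calibration (genomic inflation and type-I
error), variance-fraction recovery, or planted-causal ranking power. Seeds
are derived per replicate from a base seed, so every study is reproducible.
"""
from __future__ import annotations

import numpy as np

from .mlm import run_trait
from .multiplicity import genomic_inflation, pick_candidates, bh_adjust
from .synth import SimConfig, simulate_counts, simulate_phenotypes

__all__ = ["null_calibration_study", "recovery_study", "power_study"]


def _run_one(sim: SimConfig, trait: str = "T1"):
    counts = simulate_counts(sim)
    pheno, truth = simulate_phenotypes(counts, sim)
    res = run_trait(trait, counts, pheno)
    return res, truth


def null_calibration_study(
    n_seeds: int = 20,
    n_samples: int = 200,
    n_genes: int = 2000,
    polygenic_var_frac: float = 0.4,
    base_seed: int = 0,
) -> dict:
    """No causal genes, well-specified polygenic background.

    Returns per-seed genomic inflation factors and the pooled fraction of raw
    p-values below 0.05 across all genes and replicates.
    """
    lambdas = []
    n_sig = 0
    n_tests = 0
    for r in range(n_seeds):
        sim = SimConfig(
            n_samples=n_samples, n_genes=n_genes, n_causal=0,
            polygenic_var_frac=polygenic_var_frac, outlier_rate=0.0,
            seed=base_seed + r,
        )
        res, _ = _run_one(sim)
        p = res.table.loc[res.table["ok"], "p"].to_numpy()
        lambdas.append(genomic_inflation(p).lam)
        n_sig += int((p < 0.05).sum())
        n_tests += p.size
    return {
        "lambdas": np.asarray(lambdas),
        "mean_lambda": float(np.mean(lambdas)),
        "type1_rate": n_sig / n_tests,
        "n_tests": n_tests,
    }


def recovery_study(
    n_seeds: int = 20,
    n_samples: int = 300,
    n_genes: int = 1000,
    polygenic_var_frac: float = 0.5,
    base_seed: int = 0,
) -> dict:
    """REML recovery of the polygenic variance fraction sigma_o^2/(sigma_o^2+sigma_e^2).

    This is a property of the REML fit, so the estimate is taken on the
    simulated samples directly (no outliers are injected, and the robust
    outlier rule is not applied: clipping the tails of a clean normal
    phenotype truncates the variance and would confound the measurement;
    that truncation effect is documented in the methods note).
    """
    from .mlm import build_design, reml_fit
    from .orm import compute_orm
    from .preprocess import cpm, filter_expressed, standardize, tmm_normalize

    ratios = []
    for r in range(n_seeds):
        sim = SimConfig(
            n_samples=n_samples, n_genes=n_genes, n_causal=0,
            polygenic_var_frac=polygenic_var_frac, outlier_rate=0.0,
            seed=base_seed + r,
        )
        counts = simulate_counts(sim)
        pheno, _ = simulate_phenotypes(counts, sim)
        sub = counts.subset_genes(filter_expressed(counts))
        Z, _, _, _ = standardize(cpm(sub, tmm_normalize(sub)))
        y = pheno.data["T1"].to_numpy(dtype=float)
        X = build_design(pheno.data, ["sex", "season"])
        vc = reml_fit(y, X, compute_orm(Z, check_psd=False))
        ratios.append(vc.ratio)
    return {
        "ratios": np.asarray(ratios),
        "mean_ratio": float(np.mean(ratios)),
        "true_fraction": polygenic_var_frac,
    }


def power_study(
    n_seeds: int = 20,
    n_samples: int = 200,
    n_genes: int = 1000,
    effect_sd_units: float = 1.5,
    polygenic_var_frac: float = 0.4,
    top_k: int = 20,
    base_seed: int = 0,
) -> dict:
    """Ranking power for a single planted causal gene.

    The planted effect is ``effect_sd_units`` phenotype standard deviations
    (relative to the baseline SD sqrt(sigma_o^2 + sigma_e^2)) per SD of the
    gene's expression. Counts a replicate as a hit if the causal gene lands
    in the top-k lowest-p candidate list.
    """
    sigma_e2 = 1.0
    f = polygenic_var_frac
    sigma_o2 = f / (1.0 - f) * sigma_e2
    effect = effect_sd_units * np.sqrt(sigma_o2 + sigma_e2)
    hits = 0
    ranks = []
    for r in range(n_seeds):
        sim = SimConfig(
            n_samples=n_samples, n_genes=n_genes, n_causal=1,
            causal_effects=(effect,), polygenic_var_frac=f,
            residual_var=sigma_e2, outlier_rate=0.0, seed=base_seed + r,
        )
        res, truth = _run_one(sim)
        causal_id = truth.causal_gene_ids["T1"][0]
        tab = res.table[res.table["ok"]].copy()
        adj, sig = bh_adjust(tab["p"].to_numpy())
        tab["p_adj"] = adj
        cand = pick_candidates(tab, k=top_k)
        in_top = causal_id in set(cand.top_k["gene_id"])
        hits += int(in_top)
        order = tab.sort_values(["p", "gene_id"], kind="mergesort")["gene_id"].tolist()
        ranks.append(order.index(causal_id) + 1 if causal_id in order else np.inf)
    return {
        "hits": hits,
        "n_seeds": n_seeds,
        "hit_rate": hits / n_seeds,
        "ranks": np.asarray(ranks, dtype=float),
        "effect": effect,
    }
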