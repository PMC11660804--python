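"""Genomic-inflation diagnostics, FDR adjustment, candidate calling, and
phenotypic correlations.

The genomic inflation factor is the classic GWAS diagnostic transplanted to
expression association: each raw p-value is mapped back to a 1-df chi-square
statistic and lambda is the ratio of the observed median to the null median
of chi-square(1) (~0.4549). Lambda near 1 indicates no systematic
miscalibration or stratification.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CHI2_1_MEDIAN",
    "InflationReport",
    "CandidateSet",
    "genomic_inflation",
    "bh_adjust",
    "pick_candidates",
    "phenotype_correlations",
]

#: Median of the chi-square distribution with 1 degree of freedom. The exact
#: value is used as the lambda denominator (its 4-decimal rounding is the
#: conventional 0.4549).
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class InflationReport:
    lam: float
    ci_low: float
    ci_high: float
    n_tests: int
    qq_expected: np.ndarray  # -log10 expected quantiles, ascending
    qq_observed: np.ndarray  # matched -log10 observed p


@dataclass
class CandidateSet:
    trait: str
    significant: pd.DataFrame  # adjusted p < alpha, ascending p
    top_k: pd.DataFrame        # k lowest raw p, ascending (gene_id tie-break)
    alpha: float
    k: int


def _check_pvals(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return p


def genomic_inflation(
    pvals, conf: float = 0.95, ci_method: str = "order_stat", n_boot: int = 1000, seed: int = 0
) -> InflationReport:
    """Genomic inflation factor lambda with a confidence interval.

    Each p is converted to its 1-df chi-square via the upper-tail inverse;
    lambda = median(chi2) / median of the null chi-square(1). The default CI
    is the distribution-free binomial order-statistic interval for the
    median, each endpoint divided by the null median; ``ci_method='bootstrap'``
    resamples the statistic vector instead.
    """
    p = _check_pvals(pvals)
    n = p.size
    chi = stats.chi2.isf(p, 1)
    lam = float(np.median(chi) / CHI2_1_MEDIAN)
    srt = np.sort(chi)
    alpha = 1.0 - conf
    if ci_method == "order_stat":
        lo_rank = int(stats.binom.ppf(alpha / 2, n, 0.5))       # P(X < lo_rank) <= alpha/2
        hi_rank = int(stats.binom.ppf(1 - alpha / 2, n, 0.5)) + 1
        lo_rank = max(lo_rank, 1)
        hi_rank = min(hi_rank, n)
        ci_low = float(srt[lo_rank - 1] / CHI2_1_MEDIAN)
        ci_high = float(srt[hi_rank - 1] / CHI2_1_MEDIAN)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        meds = np.median(chi[idx], axis=1) / CHI2_1_MEDIAN
        ci_low = float(np.quantile(meds, alpha / 2))
        ci_high = float(np.quantile(meds, 1 - alpha / 2))
    else:
        raise ValueError(f"unknown ci method {ci_method!r}")
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)[::-1]  # ascending
    observed = -np.log10(np.sort(p))[::-1]
    return InflationReport(
        lam=lam, ci_low=ci_low, ci_high=ci_high, n_tests=n,
        qq_expected=expected, qq_observed=observed,
    )


def bh_adjust(pvals, alpha: float = 0.05, method: str = "bh"):
    """FDR-adjusted p-values (Benjamini-Hochberg step-up; 'by' for the
    Benjamini-Yekutieli variant) and strict ``adjusted p < alpha`` calls,
    mapped back to the input order."""
    p = _check_pvals(pvals)
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown FDR method {method!r}")
    _, adj, _, _ = multipletests(p, alpha=alpha, method=sm_method)
    return adj, adj < alpha


def pick_candidates(assoc: pd.DataFrame, k: int = 20, alpha: float = 0.05, trait: str = "") -> CandidateSet:
    """Significant genes (FDR-adjusted p < alpha) and the k lowest-raw-p genes.

    Genes with unusable statistics (NaN p) are excluded; ties in p break
    lexicographically on gene_id so the selection is deterministic.
    """
    if len(assoc) == 0:
        raise ValueError("empty association table")
    df = assoc.copy()
    df = df[np.isfinite(df["p"].to_numpy(dtype=float))]
    if len(df) == 0:
        raise ValueError("no testable gene in the association table")
    if "p_adj" not in df.columns:
        adj, sig = bh_adjust(df["p"].to_numpy(), alpha=alpha)
        df["p_adj"] = adj
        df["significant"] = sig
    else:
        df["significant"] = df["p_adj"].to_numpy() < alpha
    df = df.sort_values(["p", "gene_id"], kind="mergesort").reset_index(drop=True)
    return CandidateSet(
        trait=trait,
        significant=df[df["significant"]].reset_index(drop=True),
        top_k=df.head(min(k, len(df))).reset_index(drop=True),
        alpha=alpha,
        k=k,
    )


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def phenotype_correlations(pheno) -> pd.DataFrame:
    """Pairwise Pearson correlations among traits with significance stars.

    Uses pairwise-complete observations and the two-sided t-test per pair.
    Returns a long-format frame (trait1, trait2, n, r, p, stars) over all
    unordered pairs including the diagonal; a pair with a constant trait or
    fewer than 3 complete cases gets NaN r.
    """
    traits = list(pheno.traits)
    rows = []
    for i, t1 in enumerate(traits):
        for t2 in traits[i:]:
            v1 = pheno.data[t1].to_numpy(dtype=float)
            v2 = pheno.data[t2].to_numpy(dtype=float)
            ok = ~np.isnan(v1) & ~np.isnan(v2)
            n = int(ok.sum())
            if t1 == t2:
                r, p = (1.0, 0.0) if n >= 3 and np.std(v1[ok]) > 0 else (np.nan, np.nan)
            elif n < 3 or np.std(v1[ok]) == 0 or np.std(v2[ok]) == 0:
                r, p = np.nan, np.nan
            else:
                res = stats.pearsonr(v1[ok], v2[ok])
                r, p = float(res.statistic), float(res.pvalue)
            rows.append((t1, t2, n, r, p, _stars(p) if t1 != t2 else ""))
    return pd.DataFrame(rows, columns=["trait1", "trait2", "n", "r", "p", "stars"])
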