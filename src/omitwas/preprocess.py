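"""Count normalization, expressed-gene filtering, and phenotype quality control.

Expression preprocessing follows the standard bulk-RNA workflow for
between-sample comparability: trimmed-mean-of-M-values (TMM) scaling factors,
counts-per-million (CPM) on the effective library sizes, a presence filter
for effectively expressed genes, and per-gene standardization of the retained
expression matrix. Phenotypes are quality-controlled per trait with a robust
median +/- k*MAD rule (unscaled MAD).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "PhenotypeTable",
    "tmm_normalize",
    "cpm",
    "filter_expressed",
    "mad_filter",
    "standardize",
    "qc_phenotypes",
    "build_expression",
]


@dataclass
class CountMatrix:
    """Raw integer read counts, genes x samples."""

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x samples matrix")
        m, n = self.counts.shape
        if len(self.gene_ids) != m or len(self.sample_ids) != n:
            raise ValueError(
                f"dimension mismatch: counts is {m}x{n} but "
                f"{len(self.gene_ids)} gene ids / {len(self.sample_ids)} sample ids"
            )
        if len(set(self.gene_ids)) != m:
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample identifiers")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, mask) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(self.gene_ids[mask], self.sample_ids, self.counts[mask])

    def subset_samples(self, mask) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(self.gene_ids, self.sample_ids[mask], self.counts[:, mask])


@dataclass
class ExpressionMatrix:
    """Normalized CPM and its per-gene standardized form for the filtered gene set.

    ``standardized`` has per-gene mean 0 and population (1/n) variance 1;
    ``norm_factors`` have geometric mean 1.
    """

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    cpm: np.ndarray
    standardized: np.ndarray
    norm_factors: np.ndarray
    gene_means: np.ndarray
    gene_vars: np.ndarray


@dataclass
class PhenotypeTable:
    """Per-sample trait values and categorical covariates.

    ``data`` is indexed by sample id, with covariate columns plus one numeric
    column per trait (NaN = missing). ``masks`` holds the per-trait retained
    sample masks after QC (filled in by :func:`qc_phenotypes`).
    """

    data: pd.DataFrame
    traits: list
    covariates: list
    masks: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c in list(self.covariates) + list(self.traits):
            if c not in self.data.columns:
                raise ValueError(f"phenotype table is missing column {c!r}")

    @property
    def sample_ids(self) -> np.ndarray:
        return np.asarray(self.data.index, dtype=object)

    @property
    def n_samples(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair(obs, ref, lib_obs, lib_ref, trim_m, trim_a):
    """Pairwise TMM factor of one sample against the reference.

    Weighted trimmed mean of M-values: genes with a zero count in either
    sample drop out pairwise, M- and A-values are trimmed at ``trim_m`` and
    ``trim_a`` respectively, and the surviving log-ratios are averaged with
    inverse asymptotic-variance (delta-method binomial) weights.
    """
    obs = np.asarray(obs, dtype=float)
    ref = np.asarray(ref, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2((obs / lib_obs) / (ref / lib_ref))
        a = 0.5 * np.log2((obs / lib_obs) * (ref / lib_ref))
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    keep = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
    m, a, v = m[keep], a[keep], v[keep]
    if m.size == 0:
        warnings.warn(
            "sample shares no co-expressed gene with the reference; factor set to 1",
            RuntimeWarning,
            stacklevel=3,
        )
        return 1.0
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep2.any():
        warnings.warn("TMM trimming removed all genes; factor set to 1", RuntimeWarning, stacklevel=3)
        return 1.0
    f = np.sum(m[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    return float(2.0 ** f)


def tmm_normalize(counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05) -> np.ndarray:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean upper-quartile fraction across samples.
    """
    x = counts.counts.astype(float)
    lib = x.sum(axis=0)
    if counts.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    if np.any(lib <= 0):
        raise ValueError("every sample must have a positive total count")
    uq = np.quantile(x, 0.75, axis=0) / lib
    if np.median(uq) < 1e-20:
        ref = int(np.argmax(np.sqrt(x).sum(axis=0)))
    else:
        ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array(
        [
            _tmm_pair(x[:, j], x[:, ref], lib[j], lib[ref], trim_m, trim_a)
            for j in range(counts.n_samples)
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def cpm(counts: CountMatrix, norm_factors) -> np.ndarray:
    """Counts per million on effective library sizes: c/(libsize*factor)*1e6."""
    f = np.asarray(norm_factors, dtype=float)
    if np.any(f <= 0):
        raise ValueError("normalization factors must be positive")
    lib = counts.counts.sum(axis=0).astype(float)
    if np.any(lib == 0):
        raise ValueError("zero library size")
    return counts.counts / (lib * f)[None, :] * 1e6


def filter_expressed(counts: CountMatrix, min_count: int = 2, min_frac: float = 0.30) -> np.ndarray:
    """Mask of effectively expressed genes.

    A gene is retained iff it has count >= ``min_count`` in strictly more than
    ``min_frac`` of the samples.
    """
    n_present = (counts.counts >= min_count).sum(axis=1)
    return n_present > min_frac * counts.n_samples


def mad_filter(values, k: float = 3.5) -> np.ndarray:
    """Retained mask under the median +/- k*MAD outlier rule.

    MAD is the unscaled median absolute deviation (no 1.4826 consistency
    factor). Missing (NaN) values are not retained and do not contribute to
    the median; a zero MAD (e.g. constant vector) retains every non-missing
    value.
    """
    v = np.asarray(values, dtype=float)
    obs = ~np.isnan(v)
    if obs.sum() < 3:
        raise ValueError("mad_filter needs at least 3 non-missing values")
    med = np.median(v[obs])
    mad = np.median(np.abs(v[obs] - med))
    if mad == 0:
        return obs
    lo, hi = med - k * mad, med + k * mad
    with np.errstate(invalid="ignore"):
        return obs & (v >= lo) & (v <= hi)


def standardize(values: np.ndarray, ddof: int = 0):
    """Standardize each gene (row) to mean 0 and variance 1.

    Uses the population (1/n) variance by default so that the mean diagonal of
    the downstream relationship matrix is exactly 1. Zero-variance genes are
    dropped with a warning, never propagated as NaN.

    Returns ``(standardized, gene_means, gene_vars, kept_mask)`` where the
    first three are restricted to the kept genes.
    """
    x = np.asarray(values, dtype=float)
    mu = x.mean(axis=1)
    var = x.var(axis=1, ddof=ddof)
    kept = var > 0
    n_dropped = int((~kept).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} zero-variance gene(s) before standardization", RuntimeWarning)
    z = (x[kept] - mu[kept, None]) / np.sqrt(var[kept, None])
    return z, mu[kept], var[kept], kept


def build_expression(
    counts: CountMatrix,
    min_count: int = 2,
    min_frac: float = 0.30,
    log_cpm: bool = False,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ddof: int = 0,
) -> ExpressionMatrix:
    """Filter, TMM-normalize, CPM-transform, and standardize a count matrix."""
    mask = filter_expressed(counts, min_count=min_count, min_frac=min_frac)
    sub = counts.subset_genes(mask)
    if sub.n_genes == 0:
        raise ValueError("no gene passed the expressed-gene filter")
    factors = tmm_normalize(sub, trim_m=trim_m, trim_a=trim_a)
    expr = cpm(sub, factors)
    if log_cpm:
        expr = np.log2(expr + 1.0)
    z, mu, var, kept = standardize(expr, ddof=ddof)
    return ExpressionMatrix(
        gene_ids=sub.gene_ids[kept],
        sample_ids=sub.sample_ids,
        cpm=expr[kept],
        standardized=z,
        norm_factors=factors,
        gene_means=mu,
        gene_vars=var,
    )


def qc_phenotypes(pheno: PhenotypeTable, k: float = 3.5) -> dict:
    """Per-trait outlier removal by the median +/- k*MAD rule.

    Fills ``pheno.masks`` with one retained-sample mask per trait (missing
    trait values and missing covariates are also excluded) and returns a QC
    report dict: per trait, the number of samples removed as outliers and the
    retained N.
    """
    report = {}
    cov_ok = np.ones(pheno.n_samples, dtype=bool)
    for c in pheno.covariates:
        cov_ok &= pheno.data[c].notna().to_numpy()
    for t in pheno.traits:
        v = pheno.data[t].to_numpy(dtype=float)
        retained = mad_filter(v, k=k)
        n_outliers = int((~retained & ~np.isnan(v)).sum())
        mask = retained & cov_ok
        pheno.masks[t] = mask
        report[t] = {
            "n_total": int(pheno.n_samples),
            "n_missing": int(np.isnan(v).sum()),
            "n_outliers_removed": n_outliers,
            "n_retained": int(mask.sum()),
        }
    return report
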