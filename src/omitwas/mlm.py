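"""Per-gene mixed-linear-model association on the omics relationship matrix.

Model for a trait y over n samples:

    y = w_i b_i + C beta + W u + e,   u ~ N(0, O sigma_o^2),  e ~ N(0, I sigma_e^2)

where w_i is the standardized expression of the tested gene (fixed effect),
C the selected fixed-effect design (intercept, sex, season), and the random
polygenic term W u has covariance proportional to the ORM built from all
genes. To avoid fitting the target gene as both fixed and random effect, the
polygenic component excludes it: the covariance of the random part becomes
sigma_o^2 * O_minus_i, obtained by an exact rank-one downdate of O.

Variance components are estimated once per trait by REML on the full ORM
(eigendecomposition + 1-D profile search over the variance ratio) and reused
for every gene with a Woodbury rank-one correction (mode
``global_reml_plus_downdate``); re-estimating them per gene
(``per_gene_reml``) is available for verification.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, f as f_dist

from .orm import ORM, compute_orm, downdate
from .preprocess import (
    CountMatrix,
    PhenotypeTable,
    cpm,
    filter_expressed,
    qc_phenotypes,
    standardize,
    tmm_normalize,
)

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "TraitResult",
    "select_fixed_effects",
    "reml_fit",
    "test_gene",
    "gls_scan",
    "run_trait",
]

RATIO_LOG_BOUNDS = (np.log(1e-6), np.log(1e6))
FLAT_TOL = 1e-8
MIN_SAMPLES = 30


@dataclass
class ModelSpec:
    trait: str
    candidates: list
    selected: list
    retained_mask: np.ndarray | None = None
    exclusion_mode: str = "target_only"  # or "none"
    vc_mode: str = "global_reml_plus_downdate"  # or "per_gene_reml"
    elimination_pvalues: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not set(self.selected) <= set(self.candidates):
            raise ValueError("selected fixed effects must be a subset of the candidates")


@dataclass
class VarianceComponents:
    sigma_o2: float
    sigma_e2: float
    reml_loglik: float
    converged: bool
    n_iter: int
    flat_likelihood: bool = False

    @property
    def ratio(self) -> float:
        """Polygenic fraction sigma_o^2 / (sigma_o^2 + sigma_e^2)."""
        tot = self.sigma_o2 + self.sigma_e2
        return self.sigma_o2 / tot if tot > 0 else np.nan


@dataclass
class TraitResult:
    trait: str
    table: pd.DataFrame
    model: ModelSpec
    vc: VarianceComponents
    n_samples: int
    m_genes: int


# ---------------------------------------------------------------------------
# Fixed-effect selection (backward elimination on OLS)
# ---------------------------------------------------------------------------

def _dummy_block(values) -> np.ndarray:
    """Treatment-coded dummy columns for one categorical factor (first level ref)."""
    d = pd.get_dummies(pd.Categorical(values), drop_first=True, dtype=float)
    return d.to_numpy()


def _ols_rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def select_fixed_effects(y, factors: dict, alpha: float = 0.05) -> tuple[list, dict]:
    """Backward elimination of categorical fixed effects by OLS partial F-tests.

    ``factors`` maps factor name -> per-sample categorical values. Each factor
    is tested as a whole block (a 3-level factor is 2 dummy columns tested
    jointly). At every step the factor with the largest partial-F p-value is
    dropped if that p-value is not below ``alpha``; the intercept is never
    dropped. Returns the selected factor names (in input order) and the final
    per-factor p-values (for the survivors, from the last fit in which each
    was tested).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    names = list(factors)
    blocks = {}
    for name in names:
        vals = np.asarray(factors[name])
        if len(pd.unique(vals)) < 2:
            raise ValueError(f"factor {name!r} has fewer than 2 observed levels")
        blocks[name] = _dummy_block(vals)

    remaining = list(names)
    pvalues: dict = {}
    while remaining:
        X_full = np.column_stack([np.ones(n)] + [blocks[f] for f in remaining])
        p_full = X_full.shape[1]
        rss_full, rank_full = _ols_rss(y, X_full)
        if rank_full < p_full:
            # name the first factor whose block adds no rank beyond the
            # columns that precede it
            cum = np.ones((n, 1))
            for name in remaining:
                wider = np.column_stack([cum, blocks[name]])
                if np.linalg.matrix_rank(wider) < cum.shape[1] + blocks[name].shape[1]:
                    raise ValueError(f"design is collinear: factor {name!r} is aliased")
                cum = wider
            raise ValueError("design is collinear after dummy coding")
        df_resid = n - p_full
        step_p = {}
        for name in remaining:
            X_red = np.column_stack(
                [np.ones(n)] + [blocks[f] for f in remaining if f != name]
            )
            rss_red, _ = _ols_rss(y, X_red)
            q = blocks[name].shape[1]
            if rss_full <= 0:
                step_p[name] = 0.0
                continue
            F = (rss_red - rss_full) / q / (rss_full / df_resid)
            step_p[name] = float(f_dist.sf(F, q, df_resid))
        worst = max(remaining, key=lambda f: step_p[f])
        if step_p[worst] < alpha:
            pvalues = step_p
            break
        remaining.remove(worst)
        pvalues = step_p
    selected = [f for f in names if f in remaining]
    return selected, {f: pvalues.get(f, np.nan) for f in names}


def build_design(pheno_df: pd.DataFrame, selected: list) -> np.ndarray:
    """Intercept plus treatment-coded dummies for the selected factors."""
    n = len(pheno_df)
    cols = [np.ones(n)]
    for name in selected:
        cols.append(_dummy_block(pheno_df[name].to_numpy()))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# REML variance components
# ---------------------------------------------------------------------------

def _reml_criterion(log_gamma: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
    """Profiled (over sigma_e^2) negative restricted log-likelihood, up to a constant.

    gamma = sigma_o^2 / sigma_e^2; V = sigma_e^2 (gamma O + I) is diagonal in
    the eigenbasis of O with weights lam = gamma d + 1.
    """
    n, p = Xt.shape
    lam = np.exp(log_gamma) * d + 1.0
    Xw = Xt / lam[:, None]
    G = Xt.T @ Xw
    rhs = Xw.T @ yt
    beta = np.linalg.solve(G, rhs)
    resid = yt - Xt @ beta
    rss = float(resid @ (resid / lam))
    sign, logdet_G = np.linalg.slogdet(G)
    if sign <= 0 or rss <= 0:
        return np.inf, np.nan, beta
    crit = (n - p) * np.log(rss / (n - p)) + float(np.sum(np.log(lam))) + logdet_G + (n - p)
    return crit, rss / (n - p), beta


def reml_fit(y, X, O: np.ndarray | ORM, *, flat_tol: float = FLAT_TOL) -> VarianceComponents:
    """REML variance components of y ~ N(X beta, sigma_o^2 O + sigma_e^2 I).

    One eigendecomposition of O rotates the model to independent errors; the
    restricted likelihood is then profiled analytically over the total
    variance and maximized over the log variance ratio by bounded scalar
    search. A boundary optimum clamps sigma_o^2 to 0; a ratio likelihood that
    is flat to within ``flat_tol`` (e.g. O ~ I, where the two components are
    not separately identifiable) is reported as sigma_o^2 = 0 with a warning.
    """
    Om = O.O if isinstance(O, ORM) else np.asarray(O, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.size != n:
        raise ValueError("y and X have inconsistent sample counts")
    if n < p + 2:
        raise ValueError("too few samples for the fixed-effect design")
    d, U = np.linalg.eigh(Om)
    if d[0] < -1e-8:
        raise ValueError(f"O is not positive semi-definite (min eigenvalue {d[0]:.3g})")
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    res = minimize_scalar(
        lambda lg: _reml_criterion(lg, d, yt, Xt)[0],
        bounds=RATIO_LOG_BOUNDS,
        method="bounded",
        options={"xatol": 1e-8},
    )
    crit_opt, sige2_opt, _ = _reml_criterion(res.x, d, yt, Xt)
    # gamma -> 0 limit: ordinary least squares (lam = 1)
    crit_null, sige2_null, _ = _reml_criterion(-np.inf, d, yt, Xt)

    flat = abs(crit_null - crit_opt) < flat_tol
    at_lower = res.x <= RATIO_LOG_BOUNDS[0] + 1e-6
    if flat or at_lower or crit_null <= crit_opt:
        if flat:
            warnings.warn(
                "restricted likelihood is flat in the variance ratio "
                "(O is near-identity); reporting sigma_o^2 = 0",
                RuntimeWarning,
            )
        return VarianceComponents(
            sigma_o2=0.0,
            sigma_e2=sige2_null,
            reml_loglik=-0.5 * crit_null,
            converged=True,
            n_iter=int(res.nfev),
            flat_likelihood=flat,
        )
    gamma = float(np.exp(res.x))
    at_upper = res.x >= RATIO_LOG_BOUNDS[1] - 1e-6
    if at_upper:
        warnings.warn("REML variance ratio hit the upper search bound", RuntimeWarning)
    return VarianceComponents(
        sigma_o2=gamma * sige2_opt,
        sigma_e2=sige2_opt,
        reml_loglik=-0.5 * crit_opt,
        converged=bool(res.success) and not at_upper,
        n_iter=int(res.nfev),
    )


# ---------------------------------------------------------------------------
# Per-gene association
# ---------------------------------------------------------------------------

def _dense_gls(y: np.ndarray, M: np.ndarray, V: np.ndarray):
    """GLS of y on design M under cov V; returns (beta, cov_beta)."""
    L = cho_factor(V, lower=True)
    ViM = cho_solve(L, M)
    Viy = cho_solve(L, y)
    G = M.T @ ViM
    cov = np.linalg.inv(G)
    beta = cov @ (M.T @ Viy)
    return beta, cov


def _wald(b: float, se: float):
    chisq = (b / se) ** 2
    return chisq, float(chi2.sf(chisq, 1))


def test_gene(
    y,
    X,
    orm: ORM,
    gene,
    vc: VarianceComponents | None = None,
    *,
    vc_mode: str = "global_reml_plus_downdate",
    exclude_target: bool = True,
):
    """Association test of one gene: explicit (dense) reference path.

    The gene's standardized expression w_i joins the fixed design; the
    polygenic covariance uses the exactly downdated ORM when
    ``exclude_target``. Under ``global_reml_plus_downdate`` the supplied
    ``vc`` (one REML on the full ORM) is reused; under ``per_gene_reml`` the
    components are re-estimated by REML on the downdated ORM.

    Returns ``(b, se, chisq, p)``; a target collinear with the fixed design
    yields NaNs rather than an exception.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    i = orm.gene_index(gene)
    w = orm.Z[i]
    if exclude_target:
        sub = downdate(orm, i)
        O_use = sub.O
    else:
        O_use = orm.O
    M = np.column_stack([X, w])
    if np.linalg.matrix_rank(M, tol=1e-8) < M.shape[1]:
        return np.nan, np.nan, np.nan, np.nan
    if vc_mode == "per_gene_reml":
        vc_use = reml_fit(y, X, O_use)
    elif vc_mode == "global_reml_plus_downdate":
        if vc is None:
            raise ValueError("global vc mode needs precomputed variance components")
        vc_use = vc
    else:
        raise ValueError(f"unknown vc mode {vc_mode!r}")
    n = y.size
    V = vc_use.sigma_o2 * O_use + vc_use.sigma_e2 * np.eye(n)
    beta, cov = _dense_gls(y, M, V)
    b = float(beta[-1])
    se = float(np.sqrt(cov[-1, -1]))
    chisq, p = _wald(b, se)
    return b, se, chisq, p


def gls_scan(
    y,
    X,
    orm: ORM,
    vc: VarianceComponents,
    *,
    exclude_target: bool = True,
    cond_max: float = 1e12,
) -> pd.DataFrame:
    """Woodbury-accelerated scan of every gene in the ORM.

    With global variance components the target-excluded covariance is

        V_minus_i = (sigma_o^2 m/(m-1)) O + sigma_e^2 I - (sigma_o^2/(m-1)) z_i z_i'

    whose inverse follows from the eigendecomposition of O (shared across
    genes) plus a rank-one Sherman-Morrison correction, so each gene costs
    O(n p) after one O(n^3) setup. Genes whose expression is collinear with
    the fixed design get NaN statistics and ``ok = False``.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    m = orm.m
    so2, se2 = vc.sigma_o2, vc.sigma_e2
    if exclude_target and m > 1:
        a_scale = so2 * m / (m - 1)
        c = so2 / (m - 1)
    else:
        a_scale = so2
        c = 0.0
    d, U = np.linalg.eigh(orm.O)
    d = np.clip(d, 0.0, None)
    D = a_scale * d + se2
    iD = 1.0 / D
    yt = U.T @ y
    Xt = U.T @ X
    Zt = orm.Z @ U  # rotated gene vectors, m x n
    XtiD = Xt * iD[:, None]
    G_xx = Xt.T @ XtiD
    g_xy = XtiD.T @ yt
    ZiD = Zt * iD[None, :]
    Uu = ZiD @ Xt          # z' A^-1 X per gene
    tvec = ZiD @ yt        # z' A^-1 y per gene
    svec = np.einsum("ij,ij->i", Zt, ZiD)  # z' A^-1 z per gene

    out = np.empty((m, 4))
    ok = np.ones(m, dtype=bool)
    Nmat = np.empty((p + 1, p + 1))
    rhs = np.empty(p + 1)
    for i in range(m):
        s = svec[i]
        u = Uu[i]
        t = tvec[i]
        if c > 0:
            denom = 1.0 - c * s
            if denom <= 1e-12:
                ok[i] = False
                out[i] = np.nan
                continue
            k = c / denom
        else:
            k = 0.0
        Nmat[:p, :p] = G_xx + k * np.outer(u, u)
        Nmat[:p, p] = (1.0 + k * s) * u
        Nmat[p, :p] = Nmat[:p, p]
        Nmat[p, p] = s + k * s * s
        rhs[:p] = g_xy + (k * t) * u
        rhs[p] = (1.0 + k * s) * t
        try:
            cov = np.linalg.inv(Nmat)
        except np.linalg.LinAlgError:
            ok[i] = False
            out[i] = np.nan
            continue
        if np.linalg.cond(Nmat) > cond_max or cov[p, p] <= 0:
            ok[i] = False
            out[i] = np.nan
            continue
        beta = cov @ rhs
        b = beta[p]
        se = np.sqrt(cov[p, p])
        chisq = (b / se) ** 2
        out[i] = (b, se, chisq, chi2.sf(chisq, 1))
    return pd.DataFrame(
        {
            "gene_id": orm.gene_ids,
            "beta": out[:, 0],
            "se": out[:, 1],
            "chisq": out[:, 2],
            "p": out[:, 3],
            "ok": ok,
        }
    )


# ---------------------------------------------------------------------------
# Trait-level orchestration
# ---------------------------------------------------------------------------

def run_trait(
    trait: str,
    counts: CountMatrix,
    pheno: PhenotypeTable,
    *,
    min_count: int = 2,
    min_frac: float = 0.30,
    mad_k: float = 3.5,
    log_cpm: bool = False,
    candidates=("sex", "season"),
    alpha_fixed: float = 0.05,
    vc_mode: str = "global_reml_plus_downdate",
    exclude_target: bool = True,
    min_samples: int = MIN_SAMPLES,
) -> TraitResult:
    """End-to-end association scan for one trait.

    Applies the trait's QC mask (median +/- mad_k*MAD plus complete
    covariates), selects fixed effects by OLS backward elimination, rebuilds
    TMM/CPM/standardization and the ORM on the retained samples so the
    standardization is internally consistent, estimates variance components
    once by REML, and Wald-tests every gene with the target excluded from the
    polygenic term. Fully deterministic: no randomness anywhere.
    """
    if trait not in pheno.traits:
        raise ValueError(f"unknown trait {trait!r}")
    if trait not in pheno.masks:
        qc_phenotypes(pheno, k=mad_k)
    order = {sid: j for j, sid in enumerate(pheno.sample_ids)}
    missing = [s for s in counts.sample_ids if s not in order]
    if missing:
        raise ValueError(f"samples missing from the phenotype table: {missing[:5]}")
    pheno_aligned = pheno.data.loc[list(counts.sample_ids)]
    mask_full = np.array([pheno.masks[trait][order[s]] for s in counts.sample_ids])
    n_keep = int(mask_full.sum())
    if n_keep < min_samples:
        raise ValueError(
            f"trait {trait!r} retains only {n_keep} samples after QC "
            f"(minimum {min_samples}); refusing to fit"
        )
    gene_mask = filter_expressed(counts, min_count=min_count, min_frac=min_frac)
    sub = counts.subset_genes(gene_mask).subset_samples(mask_full)
    factors = tmm_normalize(sub)
    expr = cpm(sub, factors)
    if log_cpm:
        expr = np.log2(expr + 1.0)
    Z, _, _, kept = standardize(expr)
    the_orm = compute_orm(Z, gene_ids=sub.gene_ids[kept], sample_ids=sub.sample_ids)

    ph = pheno_aligned.loc[mask_full]
    y = ph[trait].to_numpy(dtype=float)
    usable = [
        c for c in candidates if c in ph.columns and len(pd.unique(ph[c].to_numpy())) >= 2
    ]
    selected, elim_p = select_fixed_effects(y, {c: ph[c].to_numpy() for c in usable}, alpha=alpha_fixed)
    X = build_design(ph, selected)

    vc = reml_fit(y, X, the_orm)
    if vc_mode == "global_reml_plus_downdate":
        table = gls_scan(y, X, the_orm, vc, exclude_target=exclude_target)
    elif vc_mode == "per_gene_reml":
        rows = []
        for g in the_orm.gene_ids:
            b, se, chisq, p = test_gene(
                y, X, the_orm, g, vc_mode="per_gene_reml", exclude_target=exclude_target
            )
            rows.append((g, b, se, chisq, p, np.isfinite(p)))
        table = pd.DataFrame(rows, columns=["gene_id", "beta", "se", "chisq", "p", "ok"])
    else:
        raise ValueError(f"unknown vc mode {vc_mode!r}")

    model = ModelSpec(
        trait=trait,
        candidates=list(usable),
        selected=selected,
        retained_mask=mask_full,
        exclusion_mode="target_only" if exclude_target else "none",
        vc_mode=vc_mode,
        elimination_pvalues=elim_p,
    )
    return TraitResult(
        trait=trait,
        table=table,
        model=model,
        vc=vc,
        n_samples=n_keep,
        m_genes=the_orm.m,
    )
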