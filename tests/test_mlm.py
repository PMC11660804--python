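"""Mixed-model association: fixed-effect selection, REML, and per-gene tests."""
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.stats import chi2, f as f_dist

import statsmodels.api as sm

from omitwas.mlm import (
    build_design,
    gls_scan,
    reml_fit,
    run_trait,
    select_fixed_effects,
    test_gene as single_gene_test,
)
from omitwas.orm import compute_orm, downdate
from omitwas.synth import SimConfig, simulate_counts, simulate_phenotypes

from conftest import random_standardized


# ---------------------------------------------------------------------------
# Backward elimination of fixed effects
# ---------------------------------------------------------------------------

class TestSelectFixedEffects:
    def test_overwhelming_sex_effect_retained_season_dropped(self):
        n = 200
        retained_sex = retained_season = 0
        for s in range(100):
            r = np.random.default_rng(s)
            sex = r.integers(0, 2, n)
            season = r.integers(0, 3, n)
            y = 5.0 * sex + r.normal(size=n)
            sel, _ = select_fixed_effects(y, {"sex": sex, "season": season})
            retained_sex += "sex" in sel
            retained_season += "season" in sel
        assert retained_sex >= 95
        assert retained_season <= 20  # null factor kept only at ~type-I rate

    def test_null_factor_retained_at_type_one_rate(self):
        n = 200
        kept = 0
        for s in range(400):
            r = np.random.default_rng(10_000 + s)
            sex = r.integers(0, 2, n)
            y = r.normal(size=n)
            sel, _ = select_fixed_effects(y, {"sex": sex})
            kept += "sex" in sel
        assert 0.01 <= kept / 400 <= 0.10

    def test_threshold_boundary(self):
        """Construct partial-F p-values of exactly 0.049 and 0.051 by scaling
        a single factor's effect; retention must flip across 0.05."""
        n = 60
        r = np.random.default_rng(5)
        sex = np.array([0, 1] * (n // 2))
        noise = r.normal(size=n)

        def pval(a):
            y = a * sex + noise
            X1 = np.column_stack([np.ones(n), sex])
            b1, res1, *_ = np.linalg.lstsq(X1, y, rcond=None)
            rss1 = float(((y - X1 @ b1) ** 2).sum())
            rss0 = float(((y - y.mean()) ** 2).sum())
            F = (rss0 - rss1) / (rss1 / (n - 2))
            return f_dist.sf(F, 1, n - 2)

        for target, expect_kept in [(0.049, True), (0.051, False)]:
            a = brentq(lambda a: pval(a) - target, 1e-6, 10.0)
            sel, pv = select_fixed_effects(a * sex + noise, {"sex": sex})
            assert ("sex" in sel) is expect_kept
            assert pv["sex"] == pytest.approx(target, abs=1e-9)

    def test_collinear_factor_raises_naming_it(self):
        n = 40
        sex = np.array([0, 1] * (n // 2))
        with pytest.raises(ValueError, match="twin"):
            select_fixed_effects(np.random.default_rng(0).normal(size=n),
                                 {"sex": sex, "twin": sex})

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            select_fixed_effects(np.zeros(10), {"sex": np.zeros(10)})


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

class TestReml:
    def test_identity_orm_reports_zero_polygenic_with_warning(self):
        r = np.random.default_rng(1)
        y = r.normal(size=50)
        X = np.ones((50, 1))
        with pytest.warns(RuntimeWarning, match="flat"):
            vc = reml_fit(y, X, np.eye(50))
        assert vc.sigma_o2 == 0.0
        assert vc.flat_likelihood
        assert vc.sigma_e2 == pytest.approx(np.var(y, ddof=1), rel=1e-6)

    def test_permuting_y_against_orm_kills_the_ratio(self):
        """Destroying the y-O covariance match should drive sigma_o^2 ~ 0."""
        r = np.random.default_rng(2)
        n, m = 100, 300
        Z = random_standardized(m, n, seed=3)
        orm = compute_orm(Z)
        u = r.normal(0, np.sqrt(1.0 / m), m)
        y = Z.T @ u + r.normal(0, 0.7, n)
        X = np.ones((n, 1))
        base = reml_fit(y, X, orm).ratio
        perm_ratios = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in range(20):
                yp = np.random.default_rng(100 + s).permutation(y)
                perm_ratios.append(reml_fit(yp, X, orm).ratio)
        assert np.median(perm_ratios) < 0.1
        assert base > np.median(perm_ratios)

    def test_known_variance_recovery_on_synthetic_gaussian(self):
        """Direct check on an O with strong structure: y drawn from
        N(0, s_o*O + s_e*I) recovers the ratio within Monte-Carlo slack."""
        n = 150
        r = np.random.default_rng(4)
        B = r.normal(size=(n, 10)) / np.sqrt(10)
        O = B @ B.T
        O *= n / np.trace(O)
        L = np.linalg.cholesky(O + 1e-10 * np.eye(n))
        ratios = []
        for s in range(10):
            rs = np.random.default_rng(50 + s)
            y = L @ rs.normal(size=n) * 1.0 + rs.normal(0, 1.0, n)  # so2 = se2 = 1
            ratios.append(reml_fit(y, np.ones((n, 1)), O).ratio)
        assert np.mean(ratios) == pytest.approx(0.5, abs=0.1)


# ---------------------------------------------------------------------------
# Per-gene tests
# ---------------------------------------------------------------------------

class TestTestGene:
    def _toy(self, n=8, m=6, seed=0):
        Z = random_standardized(m, n, seed=seed)
        orm = compute_orm(Z)
        r = np.random.default_rng(seed + 100)
        X = np.column_stack([np.ones(n), r.integers(0, 2, n)])
        y = r.normal(size=n)
        return y, X, orm

    def test_matches_hand_coded_gls_with_fixed_v(self):
        """n=8 toy with V fixed and known: explicit-inverse GLS oracle."""
        from omitwas.mlm import VarianceComponents

        y, X, orm = self._toy()
        vc = VarianceComponents(0.8, 0.5, 0.0, True, 0)
        for i in range(orm.m):
            b, se, chisq, p = single_gene_test(y, X, orm, i, vc)
            O_sub = downdate(orm, i).O
            V = 0.8 * O_sub + 0.5 * np.eye(8)
            M = np.column_stack([X, orm.Z[i]])
            Vi = np.linalg.inv(V)
            C = np.linalg.inv(M.T @ Vi @ M)
            beta = C @ M.T @ Vi @ y
            assert b == pytest.approx(beta[-1], abs=1e-10)
            assert se == pytest.approx(np.sqrt(C[-1, -1]), abs=1e-10)
            assert chisq == pytest.approx((beta[-1] / np.sqrt(C[-1, -1])) ** 2, abs=1e-8)

    def test_zero_polygenic_reduces_to_ols_partial_t(self):
        from omitwas.mlm import VarianceComponents

        y, X, orm = self._toy(n=40, m=10, seed=2)
        for i in range(orm.m):
            ols = sm.OLS(y, np.column_stack([X, orm.Z[i]])).fit()
            # with sigma_e^2 fixed at the OLS residual variance the GLS point
            # estimate and SE coincide with OLS, so p = chi2.sf(t^2, 1)
            vc = VarianceComponents(0.0, float(ols.mse_resid), 0.0, True, 0)
            _, _, _, p = single_gene_test(y, X, orm, i, vc)
            t = ols.tvalues[-1]
            assert p == pytest.approx(chi2.sf(t ** 2, 1), abs=1e-8)

    def test_woodbury_scan_matches_dense_path(self):
        from omitwas.mlm import VarianceComponents

        y, X, orm = self._toy(n=30, m=50, seed=3)
        vc = VarianceComponents(0.6, 0.9, 0.0, True, 0)
        tab = gls_scan(y, X, orm, vc, exclude_target=True)
        for i in range(orm.m):
            b, se, chisq, p = single_gene_test(y, X, orm, i, vc)
            row = tab.iloc[i]
            assert row["beta"] == pytest.approx(b, abs=1e-8)
            assert row["se"] == pytest.approx(se, abs=1e-8)
            assert row["p"] == pytest.approx(p, abs=1e-8)

    def test_exclusion_mode_changes_result_and_matches_recompute(self):
        """With few genes the target dominates the polygenic term, so
        exclusion and non-exclusion must differ; exclusion must equal the
        explicitly recomputed leave-one-out ORM."""
        from omitwas.mlm import VarianceComponents

        y, X, orm = self._toy(n=25, m=5, seed=4)
        vc = VarianceComponents(1.5, 0.5, 0.0, True, 0)
        i = 2
        b_ex, se_ex, _, p_ex = single_gene_test(y, X, orm, i, vc, exclude_target=True)
        b_in, se_in, _, p_in = single_gene_test(y, X, orm, i, vc, exclude_target=False)
        assert p_ex != pytest.approx(p_in, abs=1e-12)
        keep = np.ones(5, dtype=bool)
        keep[i] = False
        O_direct = compute_orm(orm.Z[keep]).O
        V = 1.5 * O_direct + 0.5 * np.eye(25)
        M = np.column_stack([X, orm.Z[i]])
        Vi = np.linalg.inv(V)
        C = np.linalg.inv(M.T @ Vi @ M)
        beta = C @ M.T @ Vi @ y
        assert b_ex == pytest.approx(beta[-1], abs=1e-10)
        assert se_ex == pytest.approx(np.sqrt(C[-1, -1]), abs=1e-10)

    def test_collinear_target_flagged_not_crashed(self):
        from omitwas.mlm import VarianceComponents

        n = 12
        sex = np.array([0, 1] * (n // 2), dtype=float)
        w = (sex - sex.mean()) / sex.std()
        Z = np.vstack([w, random_standardized(3, n, seed=5)])
        orm = compute_orm(Z)
        X = np.column_stack([np.ones(n), sex])
        y = np.random.default_rng(0).normal(size=n)
        vc = VarianceComponents(0.5, 0.5, 0.0, True, 0)
        b, se, chisq, p = single_gene_test(y, X, orm, 0, vc)
        assert np.isnan(p)
        tab = gls_scan(y, X, orm, vc)
        assert not tab.loc[0, "ok"]


# ---------------------------------------------------------------------------
# Trait orchestration
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_study():
    sim = SimConfig(n_samples=80, n_genes=400, n_causal=1, causal_effects=(2.0,),
                    polygenic_var_frac=0.3, outlier_rate=0.05, seed=42)
    counts = simulate_counts(sim)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pheno, truth = simulate_phenotypes(counts, sim)
    return sim, counts, pheno, truth


class TestRunTrait:
    def test_deterministic_reruns_identical(self, small_study):
        _, counts, pheno, _ = small_study
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = run_trait("T1", counts, pheno)
            r2 = run_trait("T1", counts, pheno)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        assert r1.vc.sigma_o2 == r2.vc.sigma_o2

    def test_sample_bookkeeping_matches_qc_mask(self, small_study):
        _, counts, pheno, _ = small_study
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_trait("T1", counts, pheno)
        assert res.n_samples == int(pheno.masks["T1"].sum())
        assert res.n_samples < counts.n_samples  # outliers were removed

    def test_injected_outliers_are_caught_by_qc(self, small_study):
        _, counts, pheno, truth = small_study
        removed = set(np.asarray(counts.sample_ids)[~pheno.masks["T1"]])
        injected = set(truth.outlier_sample_ids["T1"])
        assert injected  # the fixture seeded some outliers
        assert len(injected & removed) / len(injected) >= 0.8

    def test_refuses_under_30_samples(self, small_study):
        _, counts, pheno, _ = small_study
        tiny_c = counts.subset_samples(np.arange(20))
        tiny_p = type(pheno)(data=pheno.data.iloc[:20].copy(),
                             traits=pheno.traits, covariates=pheno.covariates)
        with pytest.raises(ValueError, match="retains only"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                run_trait("T1", tiny_c, tiny_p)

    def test_unknown_trait_rejected(self, small_study):
        _, counts, pheno, _ = small_study
        with pytest.raises(ValueError, match="unknown trait"):
            run_trait("nope", counts, pheno)

    def test_planted_strong_gene_is_top_ranked(self, small_study):
        _, counts, pheno, truth = small_study
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_trait("T1", counts, pheno)
        causal = truth.causal_gene_ids["T1"][0]
        tab = res.table[res.table["ok"]].sort_values("p")
        assert causal in set(tab.head(5)["gene_id"])
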