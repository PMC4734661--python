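import numpy as np
import pytest
from scipy import stats

from farmscan import CovariateSet, Phenotype, build_design, scan_genome
from farmscan.fem import NOT_ESTIMABLE, P_FLOOR, substitute_pvalues
from farmscan.fem import test_marker as fit_marker

from conftest import random_genotypes


def ols_oracle(y, exog):
    """Normal-equations least squares: coefficients, se, t, two-sided P."""
    exog = np.asarray(exog, float)
    n, p = exog.shape
    xtx = exog.T @ exog
    beta = np.linalg.solve(xtx, exog.T @ y)
    resid = y - exog @ beta
    df = n - p
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(np.linalg.inv(xtx)) * sigma2)
    t = beta / se
    pv = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, t, pv


class TestBuildDesign:
    def test_intercept_only(self, small_genotypes):
        ctx = build_design(small_genotypes)
        assert ctx.design.shape == (20, 1)
        assert ctx.n_pseudo == 0

    def test_constant_covariate_dropped(self, small_genotypes):
        cov = CovariateSet(
            np.ones((20, 1)), ["const"], list(small_genotypes.sample_ids)
        )
        with pytest.warns(UserWarning, match="rank-deficient"):
            ctx = build_design(small_genotypes, covariates=cov)
        assert ctx.design.shape[1] == 1
        assert ctx.dropped_covariates == ["const"]

    def test_rank_matches_oracle(self, rng):
        for _ in range(10):
            ds = random_genotypes(rng, 20, 10)
            cov_vals = rng.standard_normal((20, 2))
            cov_vals[:, 1] = cov_vals[:, 0] * 2  # force a dependence
            cov = CovariateSet(cov_vals, ["a", "b"], list(ds.sample_ids))
            with pytest.warns(UserWarning):
                ctx = build_design(ds, pseudo_indices=[1, 3], covariates=cov)
            full = np.column_stack(
                [np.ones(20), cov_vals, ds.dosages[:, [1, 3]]]
            )
            assert ctx.design.shape[1] == np.linalg.matrix_rank(full)

    def test_duplicate_pseudo_dropped_and_logged(self, small_genotypes):
        ctx = build_design(small_genotypes, pseudo_indices=[2, 2])
        assert ctx.dropped_pseudo == [2]
        np.testing.assert_array_equal(ctx.pseudo_markers, [2])

    def test_no_residual_df_fatal(self, rng):
        ds = random_genotypes(rng, 4, 6)
        cov = CovariateSet(
            rng.standard_normal((4, 2)), ["a", "b"], list(ds.sample_ids)
        )
        with pytest.raises(ValueError, match="degrees of freedom"):
            build_design(ds, pseudo_indices=[0], covariates=cov)


class TestTestMarker:
    def test_constant_marker_sentinel(self, small_genotypes, gaussian_phenotype):
        ctx = build_design(small_genotypes)
        out = fit_marker(ctx, gaussian_phenotype, np.ones(20))
        assert out == NOT_ESTIMABLE

    def test_against_normal_equations_oracle(self, rng):
        ds = random_genotypes(rng, 6, 2)
        ctx = build_design(ds)
        y = np.arange(1.0, 7.0)
        g = np.array([0.0, 0, 1, 1, 2, 2])
        out = fit_marker(ctx, y, g)
        beta, se, t, pv = ols_oracle(y, np.column_stack([np.ones(6), g]))
        assert out.effect == pytest.approx(beta[1], rel=1e-10)
        assert out.se == pytest.approx(se[1], rel=1e-10)
        assert out.t_stat == pytest.approx(t[1], rel=1e-10)
        assert out.p_value == pytest.approx(pv[1], rel=1e-10)

    def test_perfect_fit_reports_floor(self, rng):
        ds = random_genotypes(rng, 10, 2)
        ctx = build_design(ds)
        g = ds.dosages[:, 1].copy()
        g[0] += 1  # ensure non-constant even under unlucky draws
        y = 2.0 * g
        out = fit_marker(ctx, y, g)
        assert out.perfect_fit
        assert out.p_value == P_FLOOR

    def test_nonfinite_dosage_fatal(self, small_genotypes, gaussian_phenotype):
        ctx = build_design(small_genotypes)
        g = small_genotypes.dosages[:, 0].copy()
        g[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_marker(ctx, gaussian_phenotype, g)

    def test_orthogonal_covariate_leaves_effect_unchanged(self, rng):
        n = 24
        g = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
        cov_raw = rng.standard_normal(n)
        base = np.column_stack([np.ones(n), g])
        q, _ = np.linalg.qr(base)
        cov_vec = cov_raw - q @ (q.T @ cov_raw)  # exactly orthogonal
        y = rng.standard_normal(n)
        ds = random_genotypes(rng, n, 2)
        ctx0 = build_design(ds)
        cov = CovariateSet(cov_vec[:, None], ["c"], list(ds.sample_ids))
        ctx1 = build_design(ds, covariates=cov)
        assert fit_marker(ctx0, y, g).effect == pytest.approx(
            fit_marker(ctx1, y, g).effect, rel=1e-10
        )


class TestScanGenome:
    def test_matches_independent_regressions(self, rng):
        ds = random_genotypes(rng, 20, 50)
        y = rng.standard_normal(20)
        ctx = build_design(ds)
        scan = scan_genome(ctx, y, ds)
        for j in range(ds.n_markers):
            g = ds.dosages[:, j]
            if np.ptp(g) == 0:
                assert np.isnan(scan.p_value[j])
                continue
            beta, se, t, pv = ols_oracle(y, np.column_stack([np.ones(20), g]))
            assert scan.effect[j] == pytest.approx(beta[1], rel=1e-10)
            assert scan.se[j] == pytest.approx(se[1], rel=1e-10)
            assert scan.p_value[j] == pytest.approx(pv[1], rel=1e-10)

    def test_pseudo_markers_carry_sentinel(self, ld_genotypes, rng):
        y = rng.standard_normal(ld_genotypes.n_samples)
        ctx = build_design(ld_genotypes, pseudo_indices=[5, 40, 200])
        scan = scan_genome(ctx, y, ld_genotypes)
        assert int(np.isnan(scan.p_value[scan.is_pseudo_qtn]).sum()) == 3
        assert scan.is_pseudo_qtn.sum() == 3

    def test_null_rejection_rate_binomial(self):
        rng = np.random.default_rng(99)
        ds = random_genotypes(rng, 40, 5000, chromosomes=5)
        y = rng.standard_normal(40)
        ctx = build_design(ds)
        scan = scan_genome(ctx, y, ds)
        ok = np.isfinite(scan.p_value)
        frac = (scan.p_value[ok] <= 0.05).mean()
        half_width = 1.96 * np.sqrt(0.05 * 0.95 / ok.sum())
        assert abs(frac - 0.05) <= half_width * 1.5  # markers share one y

    def test_with_pseudo_matches_oracle(self, rng):
        ds = random_genotypes(rng, 30, 40)
        y = rng.standard_normal(30)
        pseudo = [3, 17]
        ctx = build_design(ds, pseudo_indices=pseudo)
        scan = scan_genome(ctx, y, ds)
        base = np.column_stack([np.ones(30), ds.dosages[:, pseudo]])
        for j in range(ds.n_markers):
            if not np.isfinite(scan.p_value[j]):
                continue
            exog = np.column_stack([base, ds.dosages[:, j]])
            beta, se, _, pv = ols_oracle(y, exog)
            assert scan.effect[j] == pytest.approx(beta[-1], rel=1e-8)
            assert scan.p_value[j] == pytest.approx(pv[-1], rel=1e-8)


class TestSubstitution:
    def _scan(self, rng, pseudo, collect="full", n=30, m=40):
        ds = random_genotypes(rng, n, m)
        y = rng.standard_normal(n)
        ctx = build_design(ds, pseudo_indices=pseudo)
        return ds, y, ctx, scan_genome(ctx, y, ds, collect=collect)

    def test_min_matches_bruteforce_refits(self, rng):
        ds, y, ctx, scan = self._scan(rng, [3, 17])
        sub = substitute_pvalues(scan, ctx.pseudo_markers, "min")
        base = np.column_stack([np.ones(30), ds.dosages[:, [3, 17]]])
        recorded = {3: [], 17: []}
        for j in range(ds.n_markers):
            if not np.isfinite(scan.p_value[j]):
                continue
            exog = np.column_stack([base, ds.dosages[:, j]])
            _, _, _, pv = ols_oracle(y, exog)
            recorded[3].append(pv[1])
            recorded[17].append(pv[2])
        assert sub.p_value[3] == pytest.approx(min(recorded[3]), rel=1e-8)
        assert sub.p_value[17] == pytest.approx(min(recorded[17]), rel=1e-8)

    @pytest.mark.parametrize("method", ["min", "mean", "median", "max"])
    def test_summary_methods_against_full_matrix(self, rng, method):
        ds, y, ctx, scan = self._scan(rng, [0, 9])
        sub = substitute_pvalues(scan, ctx.pseudo_markers, method)
        agg = {"min": np.nanmin, "mean": np.nanmean,
               "median": np.nanmedian, "max": np.nanmax}[method]
        for k, idx in enumerate(scan.pseudo_indices):
            expected = agg(scan.pseudo_stats[method])  # sanity: finite
            assert np.isfinite(expected)
            assert sub.p_value[idx] == scan.pseudo_stats[method][k]

    def test_onsite_matches_covariate_only_fit(self, rng):
        ds, y, ctx, scan = self._scan(rng, [3, 17])
        sub = substitute_pvalues(scan, ctx.pseudo_markers, "onsite")
        exog = np.column_stack([np.ones(30), ds.dosages[:, [3, 17]]])
        _, _, _, pv = ols_oracle(y, exog)
        assert sub.p_value[3] == pytest.approx(pv[1], rel=1e-8)
        assert sub.p_value[17] == pytest.approx(pv[2], rel=1e-8)

    def test_min_below_all_recorded(self, rng):
        ds, y, ctx, scan = self._scan(rng, [1, 2, 8])
        sub = substitute_pvalues(scan, ctx.pseudo_markers, "min")
        base = np.column_stack([np.ones(30), ds.dosages[:, [1, 2, 8]]])
        for j in range(ds.n_markers):
            if not np.isfinite(scan.p_value[j]):
                continue
            exog = np.column_stack([base, ds.dosages[:, j]])
            _, _, _, pv = ols_oracle(y, exog)
            assert sub.p_value[1] <= pv[1] + 1e-12
            assert sub.p_value[2] <= pv[2] + 1e-12
            assert sub.p_value[8] <= pv[3] + 1e-12

    def test_single_marker_all_methods_agree(self, rng):
        ds = random_genotypes(rng, 20, 2)
        y = rng.standard_normal(20)
        ctx = build_design(ds, pseudo_indices=[0])
        scan = scan_genome(ctx, y, ds, collect="full")
        values = {
            m: substitute_pvalues(scan, ctx.pseudo_markers, m).p_value[0]
            for m in ("min", "mean", "median", "max")
        }
        assert len({round(v, 15) for v in values.values()}) == 1

    def test_empty_pseudo_identity(self, rng):
        ds = random_genotypes(rng, 20, 10)
        y = rng.standard_normal(20)
        ctx = build_design(ds)
        scan = scan_genome(ctx, y, ds)
        sub = substitute_pvalues(scan, [], "min")
        np.testing.assert_array_equal(sub.p_value, scan.p_value)

    def test_unknown_method_fatal(self, rng):
        ds, y, ctx, scan = self._scan(rng, [3])
        with pytest.raises(ValueError, match="unknown substitution"):
            substitute_pvalues(scan, ctx.pseudo_markers, "geometric")


class TestNullUniformity:
    def test_ks_statistic_across_replicates(self):
        """Permuted-phenotype nulls give uniform P values (KS at 1%)."""
        rng = np.random.default_rng(2024)
        passed = 0
        reps = 100
        ds = random_genotypes(rng, 60, 800, chromosomes=4)
        ctx = build_design(ds)
        for _ in range(reps):
            y = rng.standard_normal(60)
            scan = scan_genome(ctx, y, ds)
            p = scan.p_value[np.isfinite(scan.p_value)]
            if stats.kstest(p, "uniform").pvalue > 0.01:
                passed += 1
        assert passed >= 95
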