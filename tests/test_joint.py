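import numpy as np
import pytest

from splicecor.joint import (cauchy_combination, correlation_test,
                             estimate_rho, joint_score)
from splicecor.null_model import fit_null

from conftest import draw_instance


def dense_joint_oracle(y, x, kernel, fit, rho):
    """Literal dense-matrix evaluation of the joint quadratic form."""
    n = y.size
    V = fit.sigma_u2 * kernel.matrix + fit.sigma_e2 * np.eye(n)
    Vi = np.linalg.inv(V)
    D = np.diag(x)
    K_rho = (1 - rho) * np.ones((n, n)) + rho * kernel.matrix
    r = fit.residuals
    return float(r @ Vi @ D @ K_rho @ D @ Vi @ r)


class TestJointScore:
    def test_matches_dense_oracle_per_rho(self):
        y, x, Z, kernel = draw_instance(seed=31, n=20, beta1=0.2,
                                        sigma_Int2=0.4, sigma_u2=0.3)
        fit = fit_null(y, None, Z, kernel)
        result = joint_score(y, x, fit, kernel)
        for rho, q, _ in result.per_rho:
            oracle = dense_joint_oracle(y, x, kernel, fit, rho)
            assert q == pytest.approx(oracle, abs=1e-10 * max(1.0, oracle))

    def test_rho_zero_equals_gls_correlation_test(self):
        """At rho = 0 the joint statistic is the squared GLS z for the
        slope, so its p-value equals the correlation test with the same V."""
        for seed in range(10):
            y, x, Z, kernel = draw_instance(seed=40 + seed, n=80,
                                            beta1=0.2, sigma_u2=0.5)
            fit = fit_null(y, None, Z, kernel)
            p0 = joint_score(y, x, fit, kernel).per_rho[0][2]
            ct = correlation_test(y, x, Z, mode="gls_kernel", null_fit=fit)
            assert p0 == pytest.approx(ct.p_value, abs=1e-6)

    def test_zero_x_degenerate(self):
        y, x, Z, kernel = draw_instance(seed=32)
        fit = fit_null(y, None, Z, kernel)
        res = joint_score(y, np.zeros_like(x), fit, kernel)
        assert res.p_combined == 1.0
        assert "x_identically_zero" in res.flags

    def test_combined_p_bounded_by_bonferroni_of_min(self):
        y, x, Z, kernel = draw_instance(seed=33, n=60, sigma_Int2=0.5)
        fit = fit_null(y, None, Z, kernel)
        res = joint_score(y, x, fit, kernel)
        pmin = min(p for _, _, p in res.per_rho)
        assert res.p_combined <= pmin * len(res.per_rho) + 1e-12

    def test_rho_star_concentrates_by_signal_type(self):
        """Fixed-effect-only signal drives the grid argmin to 0; pure
        interaction signal drives it to 1 (majority of replicates)."""
        at_zero = at_one = 0
        reps = 30
        for seed in range(reps):
            y, x, Z, kernel = draw_instance(seed=500 + seed, n=200,
                                            beta1=0.6, sigma_Int2=0.0)
            fit = fit_null(y, None, Z, kernel)
            if joint_score(y, x, fit, kernel).rho_star <= 0.2:
                at_zero += 1
            y, x, Z, kernel = draw_instance(seed=700 + seed, n=200,
                                            beta1=0.0, sigma_Int2=1.0)
            fit = fit_null(y, None, Z, kernel)
            if joint_score(y, x, fit, kernel).rho_star >= 0.8:
                at_one += 1
        assert at_zero > reps / 2
        assert at_one > reps / 2


class TestCauchyCombination:
    def test_single_p_identity(self):
        for p in (0.9, 0.05, 1e-6):
            assert cauchy_combination([p]) == pytest.approx(p, rel=1e-6)

    def test_tiny_p_dominates(self):
        assert cauchy_combination([1e-12, 0.5, 0.5]) < 1e-10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cauchy_combination([])


class TestEstimateRho:
    def test_boundary_null(self):
        rhos = []
        for seed in range(25):
            y, x, Z, kernel = draw_instance(seed=800 + seed, n=400,
                                            beta1=0.4, sigma_Int2=0.0)
            rhos.append(estimate_rho(y, x, Z, kernel).rho_hat)
        assert np.median(rhos) <= 0.05

    def test_pure_interaction(self):
        rhos = []
        for seed in range(25):
            y, x, Z, kernel = draw_instance(seed=900 + seed, n=400,
                                            beta1=0.0, sigma_Int2=0.6)
            rhos.append(estimate_rho(y, x, Z, kernel).rho_hat)
        assert np.median(rhos) >= 0.9

    def test_no_x_signal_gives_zero_rho(self):
        """Response built from covariates alone: both slope variances end
        at (numerically) zero and rho defaults to 0."""
        rng = np.random.default_rng(5)
        n = 100
        from splicecor.kernel import build_kernel
        kernel = build_kernel(rng.dirichlet(np.ones(3), size=n).T)
        x = rng.standard_normal(n)
        Z = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = Z @ np.array([0.3, 0.3]) + 0.05 * rng.standard_normal(n)
        est = estimate_rho(y, x, Z, kernel)
        assert est.rho_hat == 0.0
        assert est.sigma_Int2 <= 1e-4
        assert est.sigma_X2 <= 1e-4

    def test_exactly_degenerate_flagged(self):
        """A near-constant response pushes every slope variance to the
        snapped-zero boundary; rho is then defined as 0 and flagged."""
        rng = np.random.default_rng(6)
        n = 60
        from splicecor.kernel import build_kernel
        kernel = build_kernel(rng.dirichlet(np.ones(3), size=n).T)
        x = rng.standard_normal(n)
        Z = np.ones((n, 1))
        y = 1e-6 * rng.standard_normal(n)
        est = estimate_rho(y, x, Z, kernel)
        assert est.rho_hat == 0.0
        assert "zero_total_effect_variance" in est.flags


class TestCorrelationTest:
    def test_statistic_matches_closed_form_t(self):
        """Simple regression on a 10-point instance: the Wald statistic is
        the classical t statistic, checked against its textbook formula."""
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        y = np.array([1.2, 1.9, 3.2, 3.8, 5.1, 6.2, 6.8, 8.1, 8.9, 10.2])
        Z = np.ones((10, 1))
        res = correlation_test(y, x, Z, mode="ols")
        xc = x - x.mean()
        yc = y - y.mean()
        bhat = float(xc @ yc) / float(xc @ xc)
        resid = yc - bhat * xc
        s2 = float(resid @ resid) / (10 - 2)
        t_stat = bhat / np.sqrt(s2 / float(xc @ xc))
        assert res.Q == pytest.approx(t_stat, abs=1e-10)

    def test_null_calibration(self):
        """Rejection near nominal under independence (normal reference)."""
        rng = np.random.default_rng(12)
        n = 150
        hits = 0
        reps = 1000
        for _ in range(reps):
            x = rng.standard_normal(n)
            Z = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
            y = Z @ np.array([0.5, 0.3, 0.3]) + rng.standard_normal(n)
            if correlation_test(y, x, Z).p_value < 0.05:
                hits += 1
        assert 0.03 <= hits / reps <= 0.07

    def test_gls_with_zero_random_intercept_equals_ols(self):
        y, x, Z, kernel = draw_instance(seed=60, n=100, sigma_u2=0.0)
        p_ols = correlation_test(y, x, Z, mode="ols").p_value
        res = correlation_test(y, x, Z, mode="gls_kernel", kernel=kernel)
        from splicecor.null_model import fit_null as _fit
        if _fit(y, x, Z, kernel).sigma_u2 == 0.0:
            assert res.p_value == pytest.approx(p_ols, abs=1e-10)
        else:  # ML picked a tiny positive ridge; p still effectively OLS
            assert res.p_value == pytest.approx(p_ols, abs=1e-4)

    def test_unknown_mode_rejected(self):
        y, x, Z, _ = draw_instance(seed=61, n=30)
        with pytest.raises(ValueError):
            correlation_test(y, x, Z, mode="ridge")


def test_rho_larger_for_pairs_significant_in_both_tests():
    """On a mixed cohort, pairs flagged by both the joint and the
    interaction test carry most of their effect in the random slope, so
    their median rho exceeds that of pairs the joint test alone finds."""
    import splicecor as sc
    cfg = sc.SimulationConfig(n_samples=150, seed=88, sigma_Int2=0.8,
                              beta1=0.5)
    cohort = sc.simulate_cohort(cfg, n_genes=10, signal_fraction=0.2)
    expr = sc.ExpressionTable(list(cohort.expression.index),
                              list(cohort.expression.columns),
                              cohort.expression.to_numpy())
    ier = sc.IERTable(list(cohort.ier.index),
                      dict(zip(cohort.gene_map.intron_id,
                               cohort.gene_map.gene_id)),
                      list(cohort.ier.columns), cohort.ier.to_numpy())
    cov = sc.CovariateTable(
        list(cohort.covariates.index),
        ["intercept"] + list(cohort.covariates.columns),
        np.column_stack([np.ones(len(cohort.covariates)),
                         cohort.covariates.to_numpy()]))
    expr, ier, cov = sc.center_and_align(expr, ier, cov)
    table = sc.scan_pairs(expr, ier, cov)
    sig_joint = sc.stratified_fdr(table, q=0.05, p_col="p_joint")
    sig_int = sc.stratified_fdr(table, q=0.05, p_col="p_interaction")
    both = table[sig_joint & sig_int]["rho_hat"].dropna()
    joint_only = table[sig_joint & ~sig_int]["rho_hat"].dropna()
    assert len(both) > 0 and len(joint_only) > 0
    assert np.median(both) > np.median(joint_only)
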