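"""Joint association test for fixed plus splicing-random TE-TE effects.

Rewriting the mixed model as ``y = diag(x)(beta1 1 + b2) + Z gamma + u
+ eps`` shows the total effect of the predictor gene is the random vector
``beta1 1 + b2`` with covariance

    sigma^2 [ (1 - rho) 1 1^T + rho Sigma ],    rho = sInt2 / (sInt2 + sX2),

so ``rho`` is the proportion of the predictor's contribution attributable
to splicing-induced inter-sample variation (rho = 0: a single shared slope;
rho = 1: purely isoform-composition-driven).  The joint test uses the
quadratic score statistic

    Q(rho) = r^T V^{-1} diag(x) [ (1-rho) 1 1^T + rho Sigma ] diag(x) V^{-1} r

under the null model that excludes x entirely (both the fixed and the
random slope are under test; the null has covariates and the
kernel-structured random intercept only).  Since the true ``rho`` is
unknown, ``Q(rho)`` is evaluated on a grid and the grid p-values are
aggregated by the Cauchy combination rule, which is valid under arbitrary
dependence.  ``rho`` itself is separately estimated from the full
four-variance-component ML fit.

At ``rho = 0`` the statistic reduces to the squared GLS z-statistic for the
slope of x with covariance V — the joint test then coincides with the
standard correlation test adjusting for covariates and IERs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .kernel import SampleKernel
from .null_model import (NullModelFit, fit_full_variance_components,
                         fit_null, _prepare_design)
from .interaction import (TestResult, WeightSource,
                          score_test_quadratic)

logger = logging.getLogger(__name__)

DEFAULT_RHO_GRID = tuple(np.round(np.linspace(0.0, 1.0, 11), 1))


@dataclass
class RhoEstimate:
    """Splicing share of the predictor's total effect variance (ML-based)."""

    rho_hat: float
    sigma_X2: float
    sigma_Int2: float
    flags: list[str] = field(default_factory=list)

    @property
    def total_sigma2(self) -> float:
        return self.sigma_X2 + self.sigma_Int2


@dataclass
class JointTestResult:
    p_combined: float
    per_rho: list[tuple[float, float, float]]   # (rho, Q(rho), p(rho))
    rho_star: float                             # grid argmin of p
    rho_estimate: RhoEstimate | None = None
    flags: list[str] = field(default_factory=list)


def cauchy_combination(p_values) -> float:
    """Aggregate dependent p-values via the Cauchy combination rule."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    p = np.clip(p, 1e-300, 1.0)
    # tan((0.5 - p) pi) is numerically unstable for tiny p; use 1/(p pi)
    small = p < 1e-15
    t = np.empty_like(p)
    t[~small] = np.tan((0.5 - p[~small]) * np.pi)
    t[small] = 1.0 / (p[small] * np.pi)
    stat = float(np.mean(t))
    if stat > 1e15:
        return float(1.0 / (stat * np.pi))
    return float(np.clip(0.5 - np.arctan(stat) / np.pi, 0.0, 1.0))


def joint_score(y, x, null_fit_assoc: NullModelFit, kernel: SampleKernel,
                rho_grid=DEFAULT_RHO_GRID, method: str = "auto"
                ) -> JointTestResult:
    """Joint score test of fixed and splicing-random slope of x on y.

    ``null_fit_assoc`` must be a :func:`~splicecor.null_model.fit_null`
    result with ``x=None`` (design = covariates only) on the same kernel.
    """
    x = np.asarray(x, dtype=float).ravel()
    if np.all(x == 0):
        return JointTestResult(p_combined=1.0, per_rho=[], rho_star=0.0,
                               flags=["x_identically_zero"])
    F = kernel.factor()
    per_rho: list[tuple[float, float, float]] = []
    flags: list[str] = []
    for rho in rho_grid:
        rho = float(rho)
        cols = []
        if rho < 1.0:
            cols.append(np.sqrt(1.0 - rho) * x[:, None])   # diag(x) 1
        if rho > 0.0:
            cols.append(np.sqrt(rho) * (x[:, None] * F))   # diag(x) U L^1/2
        B = np.column_stack(cols)
        res = score_test_quadratic(null_fit_assoc, B, WeightSource.projected,
                                   method=method)
        flags.extend(res.flags)
        per_rho.append((rho, res.Q, res.p_value))
    p_combined = cauchy_combination([p for _, _, p in per_rho])
    rho_star = min(per_rho, key=lambda t: (t[2], t[0]))[0]
    return JointTestResult(p_combined=p_combined, per_rho=per_rho,
                           rho_star=rho_star, flags=sorted(set(flags)))


def estimate_rho(y, x, Z, kernel: SampleKernel) -> RhoEstimate:
    """ML estimate of the splicing share rho = sInt2 / (sInt2 + sX2).

    When both slope variances sit at (or within numerical dust of) the
    zero boundary the ratio is undefined; rho is then reported as 0 with a
    ``zero_total_effect_variance`` flag.  "Dust" is judged relative to the
    fitted nuisance variances, so the check is scale-invariant.
    """
    fit = fit_full_variance_components(y, x, Z, kernel)
    flags = [] if fit.converged else ["full_model_nonconvergence"]
    total = fit.sigma_Int2 + fit.sigma_X2
    floor = 1e-6 * (fit.sigma_u2 + fit.sigma_e2)
    if not np.isfinite(total) or total <= floor:
        return RhoEstimate(rho_hat=0.0, sigma_X2=max(fit.sigma_X2, 0.0),
                           sigma_Int2=max(fit.sigma_Int2, 0.0),
                           flags=flags + ["zero_total_effect_variance"])
    return RhoEstimate(rho_hat=fit.sigma_Int2 / total,
                       sigma_X2=fit.sigma_X2, sigma_Int2=fit.sigma_Int2,
                       flags=flags)


def correlation_test(y, x, Z, mode: str = "ols",
                     kernel: SampleKernel | None = None,
                     null_fit: NullModelFit | None = None) -> TestResult:
    """Standard TE-TE correlation (main-effect) test adjusting for covariates.

    Modes
    -----
    ``ols``
        Wald test of the x coefficient in ``y ~ x + Z``; the statistic is
        the classical t-statistic, referred to the standard normal (the
        large-sample reference shared by the score tests).
    ``gls_kernel``
        As above but generalized least squares under the fitted
        random-intercept model ``V = sigma_u^2 Sigma + sigma_e^2 I`` —
        "adjusting for covariates and IERs".  When ``null_fit`` (an
        x-excluded null fit) is supplied, the score form
        ``z = x^T P y / sqrt(x^T P x)`` with that fixed V is used, which is
        algebraically identical to the joint test at rho = 0.
    """
    if mode not in ("ols", "gls_kernel"):
        raise ValueError(f"unknown mode {mode!r}")
    y, x, Z, M = _prepare_design(y, x, Z)
    n = y.size

    if mode == "gls_kernel" and null_fit is not None:
        # score form with plug-in V from the x-excluded null
        px = null_fit.p_apply(x)
        num = float(x @ null_fit.v_inv_apply(null_fit.residuals))
        den = float(x @ px)
        if den <= 0:
            return TestResult(Q=0.0, p_value=1.0, method="degenerate",
                              weights_used=None, flags=["degenerate_score"])
        z = num / np.sqrt(den)
        return TestResult(Q=z, p_value=float(2.0 * norm.sf(abs(z))),
                          method="gls_score", weights_used=None)

    if mode == "gls_kernel":
        if kernel is None:
            raise ValueError("gls_kernel mode requires a kernel")
        nf = fit_null(y, x, Z, kernel)
        vinv_m = nf.v_inv_apply(M)
        gram_inv = np.linalg.inv(M.T @ vinv_m)
        r = nf.residuals
        scale = float(r @ nf.v_inv_apply(r)) / (n - M.shape[1])
        se = np.sqrt(scale * gram_inv[0, 0])
        z = nf.beta1_hat / se
    else:
        coef, rss_arr, *_ = np.linalg.lstsq(M, y, rcond=None)
        r = y - M @ coef
        rss = float(r @ r)
        sigma2 = rss / (n - M.shape[1])
        gram_inv = np.linalg.inv(M.T @ M)
        se = np.sqrt(sigma2 * gram_inv[0, 0])
        z = float(coef[0]) / se
    return TestResult(Q=float(z), p_value=float(2.0 * norm.sf(abs(z))),
                      method=mode, weights_used=None)
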