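"""Maximum-likelihood fits of the splicing-aware linear mixed model.

The generative model for a directed gene pair (predictor X, response Y) is

    y = x beta1 + diag(x) b2 + Z gamma + u + eps,

with random slope ``b2 ~ N(0, sigma_Int^2 Sigma)``, random intercept
``u ~ N(0, sigma_u^2 Sigma)`` and noise ``eps ~ N(0, sigma_e^2 I)``, where
``Sigma`` is the predictor gene's splicing kernel.  Two fits are provided:

* :func:`fit_null` — the null model of the interaction test
  (``sigma_Int^2 = 0``): fixed effects plus a kernel-structured random
  intercept.  The variance ratio ``delta = sigma_u^2 / sigma_e^2`` is
  profiled by 1-D bounded optimization; every other quantity has a closed
  form given ``delta``.  With the low-rank kernel factor ``Sigma = U L U^T``
  (rank r <= number of introns) all solves are O(n r) — this is what makes
  per-predictor caching cheap in the genome scan.
* :func:`fit_full_variance_components` — the four-component model of the
  joint test's variance decomposition, ``V = sigma_X^2 x x^T
  + sigma_Int^2 diag(x) Sigma diag(x) + sigma_u^2 Sigma + sigma_e^2 I``,
  fitted by quasi-Newton on log-variances with multiple starts, using a
  Woodbury identity on the rank-(2r+1) structure of the first three terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .kernel import SampleKernel

logger = logging.getLogger(__name__)

_LOG_DELTA_LO, _LOG_DELTA_HI = np.log(1e-6), np.log(1e6)
_COLLINEARITY_R2 = 1.0 - 1e-10


class CollinearityError(ValueError):
    """Predictor expression is (numerically) collinear with the covariates."""


@dataclass
class NullModelFit:
    """ML fit of the no-random-slope model; input to both score tests.

    ``V = sigma_u2 * Sigma + sigma_e2 * I`` is held through the kernel's
    low-rank eigenbasis; :meth:`v_inv_apply` and :meth:`p_apply` provide the
    ``V^{-1}`` and projected-``V^{-1}`` actions the score statistics need.
    """

    sigma_u2: float
    sigma_e2: float
    beta1_hat: float | None
    gamma_hat: np.ndarray
    residuals: np.ndarray
    loglik: float
    kernel: SampleKernel
    design: np.ndarray          # M = [x, Z] (or Z when x is excluded)
    _vinv_design: np.ndarray = field(repr=False, default=None)
    _gram_chol: tuple = field(repr=False, default=None)

    @property
    def n_samples(self) -> int:
        return self.design.shape[0]

    @property
    def delta(self) -> float:
        return self.sigma_u2 / self.sigma_e2

    def V(self) -> np.ndarray:
        """Dense estimated covariance (for diagnostics and small-n checks)."""
        n = self.n_samples
        return self.sigma_u2 * self.kernel.matrix + self.sigma_e2 * np.eye(n)

    def v_inv_apply(self, v: np.ndarray) -> np.ndarray:
        """``V^{-1} v`` through the rank-r eigenbasis of the kernel."""
        u = self.kernel.eigenvectors
        lam = self.kernel.nonzero_eigenvalues
        d = self.delta * lam / (self.delta * lam + 1.0)
        proj = u.T @ v
        return (v - u @ (d[:, None] * proj if v.ndim == 2 else d * proj)) \
            / self.sigma_e2

    def p_apply(self, v: np.ndarray) -> np.ndarray:
        """Apply ``P = V^{-1} - V^{-1} M (M^T V^{-1} M)^{-1} M^T V^{-1}``."""
        v = np.asarray(v, dtype=float)
        vi = self.v_inv_apply(v)
        coef = cho_solve(self._gram_chol, self.design.T @ vi)
        return vi - self._vinv_design @ coef


def _prepare_design(y, x, Z):
    y = np.asarray(y, dtype=float).ravel()
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if x is None:
        return y, None, Z, Z
    x = np.asarray(x, dtype=float).ravel()
    # collinearity screen: R^2 of x regressed on Z
    zq, _ = np.linalg.qr(Z)
    x_fit = zq @ (zq.T @ x)
    ss_tot = float(x @ x)
    if ss_tot == 0 or float(x_fit @ x_fit) / ss_tot > _COLLINEARITY_R2:
        raise CollinearityError("predictor x is collinear with covariates Z")
    return y, x, Z, np.column_stack([x, Z])


def _profiled_ml(kernel, y, M):
    """Closure evaluating the delta-profiled ML pieces (see fit_null)."""
    u = kernel.eigenvectors
    lam = kernel.nonzero_eigenvalues
    n = y.size
    uy, uM = u.T @ y, u.T @ M

    def pieces(delta: float):
        d = delta * lam / (delta * lam + 1.0)
        # (I + delta Sigma)^{-1} actions via the low-rank eigenbasis
        Ay = y - u @ (d * uy)
        AM = M - u @ (d[:, None] * uM)
        coef = np.linalg.solve(M.T @ AM, M.T @ Ay)
        r = y - M @ coef
        # r^T (I + delta Sigma)^{-1} r, using GLS orthogonality
        rss = float(y @ Ay) - float(coef @ (M.T @ Ay))
        sigma_e2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma_e2)
                     + np.sum(np.log(delta * lam + 1.0)) + n)
        return ll, coef, r, sigma_e2

    return pieces


def fit_null(y, x, Z, kernel: SampleKernel) -> NullModelFit:
    """ML fit of ``y = x beta1 + Z gamma + u + eps`` with ``u ~ N(0, su2 Sigma)``.

    Pass ``x=None`` for the joint test's null (covariates and random
    intercept only).  The variance ratio ``delta = sigma_u^2/sigma_e^2`` is
    profiled on a log grid over ``[1e-6, 1e6]`` followed by bounded scalar
    minimization (tolerance 1e-8); a boundary fit at ``delta = 0`` is always
    compared, so ``sigma_u^2 = 0`` is returned when the OLS submodel wins.
    """
    y, x, Z, M = _prepare_design(y, x, Z)
    n = y.size
    if M.shape[1] >= n:
        raise ValueError("more fixed effects than samples")
    pieces = _profiled_ml(kernel, y, M)

    # coarse log-grid warm start guards against local optima of the profile
    grid = np.linspace(_LOG_DELTA_LO, _LOG_DELTA_HI, 25)
    lls = np.array([pieces(np.exp(t))[0] for t in grid])
    j = int(np.argmax(lls))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, grid.size - 1)]
    res = optimize.minimize_scalar(lambda t: -pieces(np.exp(t))[0],
                                   bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    if not np.isfinite(res.fun):
        raise RuntimeError(
            f"non-finite profile likelihood at delta={np.exp(res.x):.3g} "
            f"(n={n}, p={M.shape[1]})")
    delta = float(np.exp(res.x))
    ll, coef, r, sigma_e2 = pieces(delta)
    ll0, coef0, r0, sigma_e2_0 = pieces(0.0)
    if ll0 >= ll:  # boundary estimate sigma_u^2 = 0
        delta, ll, coef, r, sigma_e2 = 0.0, ll0, coef0, r0, sigma_e2_0

    fit = NullModelFit(
        sigma_u2=delta * sigma_e2,
        sigma_e2=sigma_e2,
        beta1_hat=None if x is None else float(coef[0]),
        gamma_hat=coef if x is None else coef[1:],
        residuals=r,
        loglik=ll,
        kernel=kernel,
        design=M,
    )
    fit._vinv_design = fit.v_inv_apply(M)
    fit._gram_chol = cho_factor(M.T @ fit._vinv_design)
    return fit


@dataclass
class FullVarianceComponents:
    """ML estimates of the four-variance-component model (joint-test scale)."""

    sigma_X2: float
    sigma_Int2: float
    sigma_u2: float
    sigma_e2: float
    loglik: float
    converged: bool

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.sigma_X2, self.sigma_Int2, self.sigma_u2, self.sigma_e2)


def fit_full_variance_components(y, x, Z, kernel: SampleKernel,
                                 n_starts: int = 3) -> FullVarianceComponents:
    """ML over ``V = sX2 x x^T + sInt2 D Sigma D + su2 Sigma + se2 I``.

    ``D = diag(x)``.  Fixed effects are the covariates ``Z`` only (the slope
    of x, fixed plus random, is absorbed into the first two variance
    components).  Optimization is L-BFGS-B on log-variances from
    ``n_starts`` starting points; non-convergence is flagged on the result,
    not raised, so a genome scan can continue past a pathological pair.
    """
    y, x, Z, _ = _prepare_design(y, x, Z)
    n = y.size
    F = kernel.factor()                      # n x r, F F^T = Sigma
    L = np.column_stack([F, x, x[:, None] * F])
    r = F.shape[1]
    m = L.shape[1]                           # 2r + 1
    block = np.concatenate([np.zeros(r, dtype=int) + 2,      # sigma_u2
                            np.array([0]),                   # sigma_X2
                            np.zeros(r, dtype=int) + 1])     # sigma_Int2

    G = L.T @ L
    LtZ = L.T @ Z
    Lty = (L.T @ y)[:, None]
    ZtZ = Z.T @ Z
    Zty = (Z.T @ y)[:, None]
    yty = np.array([[float(y @ y)]])
    vary = float(np.var(y)) or 1.0

    def neg_loglik(phi: np.ndarray) -> float:
        sig = np.exp(phi)                    # (sX2, sInt2, su2, se2)
        se2 = sig[3]
        a = np.sqrt(sig[block])              # length m
        C = se2 * np.eye(m) + (a[:, None] * G) * a[None, :]
        try:
            cf = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            return np.inf
        logdet = (n - m) * np.log(se2) + 2.0 * np.sum(np.log(np.diag(cf)))

        def vinv_bilinear(LtA, LtB, AtB):
            # A^T V^{-1} B = (A^T B - (S L^T A)^T C^{-1} (S L^T B)) / se2
            va = solve_triangular(cf, a[:, None] * LtA, lower=True)
            vb = solve_triangular(cf, a[:, None] * LtB, lower=True)
            return (AtB - va.T @ vb) / se2

        ZVZ = vinv_bilinear(LtZ, LtZ, ZtZ)
        ZVy = vinv_bilinear(LtZ, Lty, Zty).ravel()
        yVy = vinv_bilinear(Lty, Lty, yty).item()
        try:
            gamma = np.linalg.solve(ZVZ, ZVy)
        except np.linalg.LinAlgError:
            return np.inf
        quad = yVy - float(gamma @ ZVy)
        return 0.5 * (n * np.log(2 * np.pi) + logdet + quad)

    starts = [
        np.log(np.array([0.25, 0.25, 0.25, 0.5]) * vary),
        np.log(np.array([1e-3, 1e-3, 1e-3, 1.0]) * vary),
        np.log(np.array([1.0, 1e-3, 0.25, 0.25]) * vary),
    ][:n_starts]
    bounds = [(np.log(vary) - 25.0, np.log(vary) + 6.0)] * 4

    best, best_val, converged = None, np.inf, False
    for s in starts:
        res = optimize.minimize(neg_loglik, s, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": 200, "ftol": 1e-12})
        if res.fun < best_val:
            best, best_val = res.x, res.fun
            converged = bool(res.success)
    if best is None or not np.isfinite(best_val):
        return FullVarianceComponents(np.nan, np.nan, np.nan, np.nan,
                                      -np.inf, False)
    sig = np.exp(best)
    # log-parametrized variances cannot reach 0 exactly; snap the floor
    sig[:3] = np.where(sig[:3] < 1e-8 * vary, 0.0, sig[:3])
    return FullVarianceComponents(sigma_X2=float(sig[0]),
                                  sigma_Int2=float(sig[1]),
                                  sigma_u2=float(sig[2]),
                                  sigma_e2=float(sig[3]),
                                  loglik=-best_val,
                                  converged=converged)
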