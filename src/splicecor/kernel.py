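"""Sample-sample covariance kernels built from a gene's splicing composition.

The central object is the n x n positive semi-definite matrix ``Sigma``
describing how similar two samples are in the isoform composition of one
gene, measured through its intron excision ratios (IERs).  ``Sigma`` is the
assumed covariance structure (up to a scalar variance component) of the
per-sample random slope and random intercept in the mixed model: samples
with similar splicing profiles are modelled as having similar gene-gene
regression coefficients.

Construction: the intron x sample IER block is transposed to sample x
intron, each intron column is standardized to mean 0 / variance 1 (constant
introns carry no between-sample information and are dropped), and the Gram
matrix ``Sigma = W W^T / k`` is formed and rescaled so that
``trace(Sigma) = n``.  The trace normalization puts the variance components
``sigma_u^2`` and ``sigma_Int^2`` on a per-sample scale that is comparable
across genes with different numbers of introns.

The same Gram construction applies verbatim to an arbitrary covariate block
(e.g. environmental exposures), which is how the model generalizes beyond
splicing; :func:`kernel_from_covariates` exposes that route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: eigenvalues below this fraction of the largest are truncated to exactly 0;
#: shared with the score-test mixture weights.
EIGENVALUE_RTOL = 1e-8


class DegenerateKernelError(ValueError):
    """All introns (or covariates) are constant across samples."""


@dataclass
class SampleKernel:
    """An n x n PSD sample-similarity matrix with cached eigendecomposition.

    Attributes
    ----------
    matrix:
        Dense ``(n, n)`` symmetric PSD matrix, trace-normalized to ``n``.
    eigenvalues:
        Length-``n`` vector, descending, clipped at 0; entries below
        ``EIGENVALUE_RTOL * max`` are exactly 0.
    eigenvectors:
        ``(n, r)`` orthonormal columns spanning the non-null eigenspace
        (``r`` = number of strictly positive eigenvalues).  The null space
        is implicit.
    k_introns:
        Number of source introns/covariates retained after dropping
        zero-variance columns.
    """

    matrix: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    k_introns: int

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return int(np.count_nonzero(self.eigenvalues))

    @property
    def nonzero_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[: self.rank]

    def factor(self) -> np.ndarray:
        """``(n, r)`` matrix ``F = U_r diag(sqrt(lambda_r))`` with ``F F^T = Sigma``
        (up to eigenvalue truncation).  Used both to draw random effects with
        covariance proportional to ``Sigma`` and to factor score-test kernels.
        """
        return self.eigenvectors * np.sqrt(self.nonzero_eigenvalues)

    def reconstruct(self) -> np.ndarray:
        """Rebuild the dense matrix from the cached eigendecomposition."""
        f = self.factor()
        return f @ f.T


def _gram_kernel(block: np.ndarray, standardize: bool, what: str) -> SampleKernel:
    block = np.asarray(block, dtype=float)
    if block.ndim != 2:
        raise ValueError(f"{what} block must be 2-D, got shape {block.shape}")
    k_in, n = block.shape
    if n < 2:
        raise ValueError(f"need at least 2 samples, got {n}")
    if not np.all(np.isfinite(block)):
        raise ValueError(f"{what} block contains missing/non-finite values; "
                         "impute before building a kernel")

    w = block.T.copy()  # sample x intron
    w -= w.mean(axis=0)
    sd = w.std(axis=0)
    keep = sd > 1e-12
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.warning("dropping %d zero-variance %s column(s) of %d",
                       n_dropped, what, k_in)
    if not np.any(keep):
        raise DegenerateKernelError(
            f"all {k_in} {what} columns are constant across samples")
    w = w[:, keep]
    if standardize:
        w = w / w.std(axis=0)
    k = w.shape[1]

    sigma = w @ w.T / k
    tr = np.trace(sigma)
    if tr <= 0:
        raise DegenerateKernelError(f"{what} kernel has non-positive trace")
    sigma *= n / tr

    # Eigendecomposition through the thin SVD of the (rescaled) factor:
    # exact for the Gram construction and O(n k^2) instead of O(n^3).
    u, s, _ = np.linalg.svd(w * np.sqrt(n / (tr * k)), full_matrices=False)
    lam = s ** 2
    lam[lam < EIGENVALUE_RTOL * lam[0]] = 0.0
    r = int(np.count_nonzero(lam))
    eigenvalues = np.zeros(n)
    eigenvalues[:r] = lam[:r]
    return SampleKernel(matrix=sigma, eigenvalues=eigenvalues,
                        eigenvectors=u[:, :r], k_introns=k)


def build_kernel(ier_block: np.ndarray, standardize: bool = True) -> SampleKernel:
    """Build the splicing kernel from a gene's intron x sample IER block.

    Parameters
    ----------
    ier_block:
        ``(k, n)`` matrix of intron excision ratios, no missing values,
        ``k >= 2`` introns and ``n >= 10`` samples.
    standardize:
        Standardize introns to unit variance before forming the Gram matrix
        (default).  ``False`` gives a raw-covariance kernel for sensitivity
        analysis.

    Notes
    -----
    Introns of one cluster are linearly dependent (their ratios sum to 1 per
    sample); the Gram construction tolerates the resulting rank deficiency,
    so no intron is dropped for collinearity.
    """
    ier_block = np.asarray(ier_block, dtype=float)
    if ier_block.shape[0] < 2:
        raise ValueError(
            f"need at least 2 introns to build a splicing kernel, got "
            f"{ier_block.shape[0]}")
    return _gram_kernel(ier_block, standardize, "intron")


def kernel_from_covariates(covariate_block: np.ndarray,
                           standardize: bool = True) -> SampleKernel:
    """Sample-similarity kernel from an arbitrary covariate x sample block.

    Identical construction to :func:`build_kernel`; the number of covariates
    may greatly exceed the number of samples (the kernel is n x n either way).
    """
    return _gram_kernel(covariate_block, standardize, "covariate")
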