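"""Exponential spatial kernel: construction, Cholesky factorisation, whitening.

The column covariance of the data matrix is modelled as ``Sigma = tau * K(S; phi)``
where ``K[j, j'] = exp(-||s_j - s_j'|| / phi)`` is the exponential correlation
kernel over the pixel coordinates ``S``, ``tau > 0`` is the marginal variance
and ``phi > 0`` the correlation scale, expressed in the same (raw) units as the
coordinates — no internal rescaling is ever applied, so the meaning of ``phi``
is exactly the one of the input coordinate file.

Every ``Sigma^{-1}``-product in the package is computed through triangular
solves against the lower Cholesky factor ``L`` (``Sigma = L L^T``); an explicit
inverse is never materialised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cholesky, solve_triangular
from scipy.spatial.distance import pdist, squareform

#: jitter added to the correlation diagonal on a failed factorisation
#: (duplicate pixels in raster exports make the matrix numerically singular)
JITTER = 1e-8


def validate_coords(coords: np.ndarray) -> np.ndarray:
    """Validate and return a (p, 2) float array of planar pixel coordinates."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError(f"coordinates must be a (p, 2) array, got shape {coords.shape}")
    if coords.shape[0] < 1:
        raise ValueError("at least one pixel coordinate is required")
    if not np.all(np.isfinite(coords)):
        raise ValueError("pixel coordinates must be finite")
    return coords


def build_correlation(coords: np.ndarray, phi: float) -> np.ndarray:
    """Exponential correlation matrix ``K[j, j'] = exp(-||s_j - s_j'|| / phi)``.

    Parameters
    ----------
    coords
        (p, 2) planar pixel coordinates, one row per column of the data matrix.
    phi
        Positive kernel scale, in coordinate units.

    Returns
    -------
    (p, p) symmetric matrix with unit diagonal and entries in (0, 1].
    """
    coords = validate_coords(coords)
    if not np.isfinite(phi) or phi <= 0:
        raise ValueError(f"kernel scale phi must be a positive finite real, got {phi!r}")
    p = coords.shape[0]
    if p == 1:
        return np.ones((1, 1))
    dist = squareform(pdist(coords))
    return np.exp(-dist / phi)


@dataclass(frozen=True)
class SpatialKernel:
    """Factored spatial covariance ``Sigma = tau * K(S; phi)``.

    Stores the Cholesky factor of the *correlation* matrix so that changing
    ``tau`` (as the fitting loop does at every iteration) is a rescaling,
    not a refactorisation: ``chol(Sigma) = sqrt(tau) * chol(K)``.
    """

    phi: float
    tau: float
    correlation: np.ndarray
    chol_corr: np.ndarray  # lower Cholesky factor of the correlation matrix

    @property
    def p(self) -> int:
        return self.correlation.shape[0]

    @property
    def chol_lower(self) -> np.ndarray:
        """Lower-triangular L with ``L L^T = tau * K``."""
        return np.sqrt(self.tau) * self.chol_corr

    @property
    def log_det_corr(self) -> float:
        return 2.0 * float(np.sum(np.log(np.diag(self.chol_corr))))

    @property
    def log_det_sigma(self) -> float:
        """log|Sigma| = p log tau + log|K|."""
        return self.p * float(np.log(self.tau)) + self.log_det_corr

    def with_tau(self, tau: float) -> "SpatialKernel":
        """Same correlation structure, new marginal variance."""
        if not np.isfinite(tau) or tau <= 0:
            raise ValueError(f"marginal variance tau must be positive, got {tau!r}")
        return SpatialKernel(self.phi, float(tau), self.correlation, self.chol_corr)

    @classmethod
    def identity(cls, p: int, tau: float = 1.0) -> "SpatialKernel":
        """Kernel with identity correlation (no spatial dependence)."""
        eye = np.eye(p)
        return cls(phi=float("nan"), tau=float(tau), correlation=eye, chol_corr=eye.copy())


def factor(correlation: np.ndarray, tau: float, phi: float = float("nan")) -> SpatialKernel:
    """Cholesky-factor ``Sigma = tau * correlation`` into a :class:`SpatialKernel`.

    A failed factorisation (numerically non-positive-definite input, e.g.
    duplicated pixel coordinates) is retried once after adding ``JITTER`` to
    the diagonal; a second failure raises.
    """
    correlation = np.asarray(correlation, dtype=float)
    if correlation.ndim != 2 or correlation.shape[0] != correlation.shape[1]:
        raise ValueError("correlation must be a square matrix")
    if not np.allclose(correlation, correlation.T, atol=1e-10):
        raise ValueError("correlation must be symmetric")
    if not np.isfinite(tau) or tau <= 0:
        raise ValueError(f"marginal variance tau must be positive, got {tau!r}")
    try:
        chol_corr = cholesky(correlation, lower=True)
    except LinAlgError:
        warnings.warn(
            "correlation matrix is numerically singular; retrying the Cholesky "
            f"factorisation with {JITTER:g} diagonal jitter",
            RuntimeWarning,
            stacklevel=2,
        )
        jittered = correlation + JITTER * np.eye(correlation.shape[0])
        try:
            chol_corr = cholesky(jittered, lower=True)
        except LinAlgError as exc:  # pragma: no cover - pathological input
            raise ValueError("correlation matrix is not positive definite even after jitter") from exc
        correlation = jittered
    return SpatialKernel(phi=float(phi), tau=float(tau), correlation=correlation, chol_corr=chol_corr)


def build_kernel(coords: np.ndarray, phi: float, tau: float = 1.0) -> SpatialKernel:
    """Convenience: correlation from coordinates, then factorisation."""
    return factor(build_correlation(coords, phi), tau, phi=phi)


def whiten_columns(X: np.ndarray, kernel: SpatialKernel) -> np.ndarray:
    """Column-whitened data ``X_tilde = X (L^{-1})^T`` via a triangular solve.

    Satisfies ``X_tilde @ L.T == X`` to numerical tolerance.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != kernel.p:
        raise ValueError(f"X must have {kernel.p} columns to match the kernel, got shape {X.shape}")
    return solve_triangular(kernel.chol_lower, X.T, lower=True).T


def whiten_indicator(G_dense: np.ndarray, kernel: SpatialKernel) -> np.ndarray:
    """Whitened column-indicator ``G_tilde = L^{-1} G`` via a triangular solve."""
    G_dense = np.asarray(G_dense, dtype=float)
    if G_dense.ndim != 2 or G_dense.shape[0] != kernel.p:
        raise ValueError(f"G must have {kernel.p} rows to match the kernel, got shape {G_dense.shape}")
    return solve_triangular(kernel.chol_lower, G_dense, lower=True)


def sigma_solve(A: np.ndarray, kernel: SpatialKernel) -> np.ndarray:
    """``Sigma^{-1} A`` as two triangular solves against ``L``."""
    L = kernel.chol_lower
    return solve_triangular(L.T, solve_triangular(L, A, lower=True), lower=False)
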