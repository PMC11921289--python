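"""Trifactorization state and the alternating update steps.

The model approximates an n x p expression matrix X by ``F mu G^T`` where
F (n x K) and G (p x R) are hard cluster-indicator matrices and mu (K x R)
holds the cocluster centroids; mu is real-valued (semi-NMTF), so X may contain
negative entries (e.g. log-transformed, centred abundances). Spatial
correlation among the p pixels enters through the column covariance
``Sigma = tau * K(S; phi)`` and the loss is the squared Frobenius norm of the
column-whitened residual,

    loss = || (X - F mu G^T) (L^{-1})^T ||_F^2
         = tr[ (X - F mu G^T) Sigma^{-1} (X - F mu G^T)^T ],

the negative log-kernel of a matrix-variate Gaussian with identity row
covariance and column covariance Sigma. The update steps:

* centroids   — generalised-least-squares block means (exact minimiser in mu);
* rows        — independent nearest-whitened-centroid assignment, or its
                stochastic-EM variant drawing labels from a softmax of the
                per-row criteria;
* columns     — exact sequential coordinate descent on the full loss, a fast
                per-column approximation that ignores Sigma, or the
                stochastic-EM draw from full-loss softmax weights;
* tau         — closed-form minimiser of the penalized loss
                ``loss + n log|Sigma|``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve, solve_triangular

from .kernel import SpatialKernel, sigma_solve, whiten_columns, whiten_indicator

#: lower clamp for the estimated marginal variance (keeps Sigma factorisable)
TAU_FLOOR = 1e-12


class EmptyModelError(ValueError):
    """Raised when every row cluster or every column cluster is empty."""


@dataclass(frozen=True)
class Indicator:
    """Hard cluster assignment of m units into C clusters.

    ``labels`` holds 0-based cluster indices; clusters are allowed to be
    empty (emptying superfluous clusters is how the number of clusters is
    effectively selected).
    """

    labels: np.ndarray
    n_clusters: int

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64)
        if labels.ndim != 1 or labels.size == 0:
            raise ValueError("labels must be a nonempty 1-D integer array")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if labels.min() < 0 or labels.max() >= self.n_clusters:
            raise ValueError("labels must lie in [0, n_clusters)")
        object.__setattr__(self, "labels", labels)

    @property
    def m(self) -> int:
        return self.labels.size

    @property
    def dense(self) -> np.ndarray:
        """(m, C) one-hot matrix; every row sums to one."""
        out = np.zeros((self.m, self.n_clusters))
        out[np.arange(self.m), self.labels] = 1.0
        return out

    @classmethod
    def from_dense(cls, dense: np.ndarray) -> "Indicator":
        dense = np.asarray(dense)
        if dense.ndim != 2 or not np.all(np.isin(dense, (0, 1))) or not np.all(dense.sum(axis=1) == 1):
            raise ValueError("dense indicator must be one-hot with a single 1 per row")
        return cls(np.argmax(dense, axis=1), dense.shape[1])

    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


def count_nonempty(indicator: Indicator) -> int:
    """Number of clusters containing at least one unit."""
    return int(np.count_nonzero(indicator.counts()))


@dataclass
class CoclusterModel:
    """Full trifactorization state: labels, centroids, kernel parameters."""

    rows: Indicator  # F, n x K
    cols: Indicator  # G, p x R
    mu: np.ndarray  # K x R, real-valued
    tau: float
    phi: float

    def predicted(self) -> np.ndarray:
        """Mean matrix ``F mu G^T`` without forming the indicator products."""
        return self.mu[self.rows.labels][:, self.cols.labels]

    def copy(self) -> "CoclusterModel":
        return CoclusterModel(
            rows=Indicator(self.rows.labels.copy(), self.rows.n_clusters),
            cols=Indicator(self.cols.labels.copy(), self.cols.n_clusters),
            mu=self.mu.copy(),
            tau=self.tau,
            phi=self.phi,
        )


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def loss(X: np.ndarray, model: CoclusterModel, kernel: SpatialKernel) -> float:
    """Squared Frobenius norm of the column-whitened residual (the objective)."""
    residual = np.asarray(X, dtype=float) - model.predicted()
    white = solve_triangular(kernel.chol_lower, residual.T, lower=True)
    return float(np.sum(white**2))


def penalized_loss(X: np.ndarray, model: CoclusterModel, kernel: SpatialKernel) -> float:
    """``loss + n log|Sigma|``: the matrix-normal profile objective.

    The penalty is what makes the closed-form tau update a minimiser rather
    than sending tau to infinity, and it makes values comparable across
    restarts and across tau.
    """
    n = np.asarray(X).shape[0]
    return loss(X, model, kernel) + n * kernel.log_det_sigma


# ---------------------------------------------------------------------------
# Step 1 — centroids
# ---------------------------------------------------------------------------


def update_centroids(
    X: np.ndarray,
    rows: Indicator,
    cols: Indicator,
    kernel: SpatialKernel,
    prev: np.ndarray | None = None,
    nonneg: bool = False,
) -> np.ndarray:
    """Exact minimiser of the loss in mu:
    ``mu = (F^T F)^{-1} F^T X Sigma^{-1} G (G^T Sigma^{-1} G)^{-1}``.

    Empty clusters make ``F^T F`` (or ``G^T Sigma^{-1} G``) singular; the
    update is computed over nonempty clusters only and the centroids of empty
    clusters keep their previous values (zero when no previous mu is given).
    With identity Sigma the update reduces to plain block means.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if rows.m != n or cols.m != p:
        raise ValueError("indicator dimensions do not match X")
    row_counts = rows.counts()
    r_mask = row_counts > 0
    c_mask = cols.counts() > 0
    if not r_mask.any() or not c_mask.any():
        raise EmptyModelError("all row clusters or all column clusters are empty")

    G_ne = cols.dense[:, c_mask]
    G_sol = sigma_solve(G_ne, kernel)  # Sigma^{-1} G over nonempty column clusters
    M = G_ne.T @ G_sol
    B = rows.dense[:, r_mask].T @ (X @ G_sol)
    B /= row_counts[r_mask][:, None]
    mu_sub = solve(M, B.T, assume_a="pos").T  # B @ M^{-1}

    if prev is None:
        mu = np.zeros((rows.n_clusters, cols.n_clusters))
    else:
        mu = np.array(prev, dtype=float, copy=True)
        if mu.shape != (rows.n_clusters, cols.n_clusters):
            raise ValueError("previous centroid matrix has the wrong shape")
    mu[np.ix_(r_mask, c_mask)] = mu_sub
    if nonneg:
        np.maximum(mu, 0.0, out=mu)
    return mu


# ---------------------------------------------------------------------------
# Step 2 / 2S — rows
# ---------------------------------------------------------------------------


def row_criteria(X: np.ndarray, mu: np.ndarray, cols: Indicator, kernel: SpatialKernel) -> np.ndarray:
    """(n, K) matrix of per-row assignment criteria
    ``crit[i, k] = || X_tilde[i, :] - mu[k, :] @ G_tilde^T ||^2``.

    Summing the criterion of each row's assigned cluster gives the full loss,
    so the per-row argmin is the exact coordinate-descent step in F.
    """
    Xw = whiten_columns(X, kernel)
    Gw = whiten_indicator(cols.dense, kernel)
    H = mu @ Gw.T  # (K, p): whitened composite centroid of each row cluster
    crit = (Xw**2).sum(axis=1)[:, None] - 2.0 * Xw @ H.T + (H**2).sum(axis=1)[None, :]
    return np.maximum(crit, 0.0, out=crit)  # guard tiny negative round-off


def update_rows_classification(
    X: np.ndarray, mu: np.ndarray, cols: Indicator, kernel: SpatialKernel
) -> Indicator:
    """Assign every row to its criterion-minimising cluster (ties -> smallest index)."""
    crit = row_criteria(X, mu, cols, kernel)
    return Indicator(np.argmin(crit, axis=1), mu.shape[0])


def _softmax_draw(neg_energy_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one categorical label per row with P proportional to exp(neg_energy).

    The per-row maximum is subtracted before exponentiation: the raw weights
    exp{-loss} underflow for any realistic loss scale, and the shift leaves
    the normalised probabilities unchanged.
    """
    shifted = neg_energy_rows - neg_energy_rows.max(axis=1, keepdims=True)
    w = np.exp(shifted)
    pi = w / w.sum(axis=1, keepdims=True)
    cum = np.cumsum(pi, axis=1)
    u = rng.random(pi.shape[0])
    labels = (u[:, None] > cum).sum(axis=1)
    return np.minimum(labels, pi.shape[1] - 1)


def update_rows_stochastic(
    X: np.ndarray, mu: np.ndarray, cols: Indicator, kernel: SpatialKernel, rng: np.random.Generator
) -> Indicator:
    """Stochastic-EM row step: draw each row's label with probability
    proportional to ``exp(-crit[i, k])``."""
    crit = row_criteria(X, mu, cols, kernel)
    return Indicator(_softmax_draw(-crit, rng), mu.shape[0])


def row_assignment_probabilities(
    X: np.ndarray, mu: np.ndarray, cols: Indicator, kernel: SpatialKernel
) -> np.ndarray:
    """(n, K) softmax probabilities used by the stochastic row step."""
    crit = row_criteria(X, mu, cols, kernel)
    shifted = crit - crit.min(axis=1, keepdims=True)
    w = np.exp(-shifted)
    return w / w.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Step 3 / 3A / 3S — columns
# ---------------------------------------------------------------------------


def candidate_column_losses(
    X: np.ndarray,
    rows: Indicator,
    mu: np.ndarray,
    labels: np.ndarray,
    j: int,
    kernel: SpatialKernel,
) -> np.ndarray:
    """Full loss of each of the R relabellings of column ``j``.

    With ``A`` the residual under the current labels but column j's mean
    removed, assigning j to cluster r changes the residual by a rank-one term
    ``-comp_r e_j^T`` (``comp = F mu``), so the whitened norm expands as
    ``||A_w||^2 - 2 comp_r . (A_w w) + ||comp_r||^2 ||w||^2`` with
    ``w = L^{-1} e_j`` — exact, and far cheaper than re-whitening R times.
    """
    L = kernel.chol_lower
    comp = mu[rows.labels]  # (n, R) composite column centroids F mu
    A = X - comp[:, labels]
    A[:, j] = X[:, j]
    A_w_t = solve_triangular(L, A.T, lower=True)  # (p, n) = L^{-1} A^T
    e = np.zeros(kernel.p)
    e[j] = 1.0
    w = solve_triangular(L, e, lower=True)
    base = float(np.sum(A_w_t**2))
    c = A_w_t.T @ w  # (n,) = (A (L^{-1})^T) w
    return base - 2.0 * comp.T @ c + (comp**2).sum(axis=0) * float(w @ w)


def _sweep_columns(X, rows, mu, cols, kernel, choose) -> Indicator:
    X = np.asarray(X, dtype=float)
    labels = cols.labels.copy()
    for j in range(cols.m):
        losses = candidate_column_losses(X, rows, mu, labels, j, kernel)
        labels[j] = choose(losses)
    return Indicator(labels, cols.n_clusters)


def update_cols_exact(
    X: np.ndarray, rows: Indicator, mu: np.ndarray, cols: Indicator, kernel: SpatialKernel
) -> Indicator:
    """One sequential sweep of the exact column step: column j takes the label
    minimising the full loss among its R relabellings (ties -> smallest index).
    The current label is always among the candidates, so the loss never
    increases within the sweep."""
    return _sweep_columns(X, rows, mu, cols, kernel, lambda losses: int(np.argmin(losses)))


def update_cols_stochastic(
    X: np.ndarray,
    rows: Indicator,
    mu: np.ndarray,
    cols: Indicator,
    kernel: SpatialKernel,
    rng: np.random.Generator,
) -> Indicator:
    """Stochastic-EM column step: for each column j in sequence, draw the new
    label from Multinomial(1, pi) with ``pi_r`` proportional to
    ``exp(-full loss of relabelling j to r)`` (max-shifted for stability)."""

    def choose(losses: np.ndarray) -> int:
        return int(_softmax_draw(-losses[None, :], rng)[0])

    return _sweep_columns(X, rows, mu, cols, kernel, choose)


def update_cols_approx(X: np.ndarray, rows: Indicator, mu: np.ndarray) -> Indicator:
    """Fast approximate column step: assign each column independently to the
    nearest composite centroid ``F mu[:, r]`` in plain Euclidean norm.

    Deliberately ignores Sigma, which makes the step embarrassingly parallel
    over columns; the full (whitened) loss is not guaranteed to decrease.
    """
    X = np.asarray(X, dtype=float)
    comp = mu[rows.labels]  # (n, R)
    d2 = (X**2).sum(axis=0)[:, None] - 2.0 * X.T @ comp + (comp**2).sum(axis=0)[None, :]
    return Indicator(np.argmin(d2, axis=1), mu.shape[1])


# ---------------------------------------------------------------------------
# Step 4 — marginal variance
# ---------------------------------------------------------------------------


def update_tau(
    X: np.ndarray, rows: Indicator, mu: np.ndarray, cols: Indicator, kernel: SpatialKernel
) -> float:
    """Closed-form update ``tau = tr[R K^{-1} R^T] / (n p)`` with R the raw
    residual — the unique stationary point (and conditional minimum) of the
    penalized loss in tau.

    A value below ``TAU_FLOOR`` (zero residual: degenerate, noiseless fit)
    is clamped with a warning so Sigma stays factorisable.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    residual = X - mu[rows.labels][:, cols.labels]
    white = solve_triangular(kernel.chol_corr, residual.T, lower=True)
    tau = float(np.sum(white**2)) / (n * p)
    if tau < TAU_FLOOR:
        warnings.warn(
            f"estimated marginal variance {tau:.3g} is numerically zero (degenerate fit); "
            f"clamping to {TAU_FLOOR:g}",
            RuntimeWarning,
            stacklevel=2,
        )
        tau = TAU_FLOOR
    return tau
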