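"""Iterative fitting: initialisation, the outer loop, restarts, phi grid.

One outer iteration applies, in order: the centroid update, the row step
(classification or stochastic), the column step (exact, approximate or
stochastic), and the closed-form marginal-variance update. With the exact
column step the penalized loss is non-increasing across the whole sequence;
with the approximate or stochastic steps it need not be, so the driver tracks
and returns the minimum-penalized-loss state visited during the run.

Restart selection and phi-grid selection compare penalized losses. The raw
whitened loss evaluated right after the variance update equals n*p at any
stationary tau (tau is exactly the mean whitened squared residual), so it
cannot discriminate between fits; the penalized loss — equivalently the
matrix-normal profile objective, monotone in the estimated tau at fixed
phi — can, and both are reported.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .kernel import SpatialKernel, build_kernel
from .model import (
    CoclusterModel,
    EmptyModelError,
    Indicator,
    count_nonempty,
    loss,
    penalized_loss,
    update_centroids,
    update_cols_approx,
    update_cols_exact,
    update_cols_stochastic,
    update_rows_classification,
    update_rows_stochastic,
    update_tau,
)

log = logging.getLogger(__name__)

ROW_STEPS = ("classification", "stochastic")
COL_STEPS = ("exact", "approx", "stochastic")


@dataclass
class FitConfig:
    """Configuration of one fitting run.

    Defaults mirror the standard protocol: 50 random restarts, stopping when
    the relative decrement of the loss falls below 0.1%, with an optional
    label-stability (patience) criterion and a hard iteration cap.
    """

    K: int
    R: int
    phi: float | Sequence[float] = 1.0
    row_step: str = "classification"
    col_step: str = "exact"
    n_restarts: int = 50
    rel_tol: float = 1e-3
    patience: int | None = None
    max_iter: int = 100
    seed: int = 0
    nonneg_mu: bool = False

    def __post_init__(self):
        if self.K < 1 or self.R < 1:
            raise ValueError("K and R must be >= 1")
        if self.row_step not in ROW_STEPS:
            raise ValueError(f"row_step must be one of {ROW_STEPS}, got {self.row_step!r}")
        if self.col_step not in COL_STEPS:
            raise ValueError(f"col_step must be one of {COL_STEPS}, got {self.col_step!r}")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if not (0.0 < self.rel_tol < 1.0):
            raise ValueError("rel_tol must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    @property
    def variant(self) -> tuple[str, str]:
        return (self.row_step, self.col_step)


@dataclass
class FitResult:
    """Outcome of a fitting run: best state plus diagnostics."""

    model: CoclusterModel
    loss_trace: np.ndarray  # raw whitened loss per iteration (index 0 = initialisation)
    penalized_trace: np.ndarray
    best_loss: float  # penalized loss at the returned (best) state
    best_raw_loss: float
    n_iter: int
    converged: bool
    nonempty_row_clusters: int
    nonempty_col_clusters: int
    variant: tuple[str, str]
    phi_used: float
    runtime: float
    restart_losses: np.ndarray | None = None  # penalized loss of every restart
    restart_taus: np.ndarray | None = None  # estimated tau of every restart


@dataclass
class GridResult:
    """Per-phi fit summaries plus the overall (minimum penalized loss) winner."""

    table: pd.DataFrame
    results: list[FitResult]
    best: FitResult

    @property
    def phi_best(self) -> float:
        return self.best.phi_used


def _weighted_seeds(V: np.ndarray, n_seeds: int, rng: np.random.Generator) -> np.ndarray:
    """D^2-weighted seed selection over the rows of V (k-means++ style).

    The first seed is uniform; each further seed is drawn with probability
    proportional to its squared Euclidean distance from the nearest seed
    already chosen, which covers well-separated groups with high probability.
    """
    m = V.shape[0]
    seeds = [int(rng.integers(m))]
    d2 = ((V - V[seeds[0]]) ** 2).sum(axis=1)
    for _ in range(n_seeds - 1):
        total = d2.sum()
        j = int(rng.choice(m, p=d2 / total)) if total > 0 else int(rng.integers(m))
        seeds.append(j)
        d2 = np.minimum(d2, ((V - V[j]) ** 2).sum(axis=1))
    return np.asarray(seeds)


def _nearest_seed_labels(V: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    S = V[seeds]
    d2 = (V**2).sum(axis=1)[:, None] - 2.0 * V @ S.T + (S**2).sum(axis=1)[None, :]
    return np.argmin(d2, axis=1)


def initialize(
    X: np.ndarray, config: FitConfig, rng: np.random.Generator, kernel: SpatialKernel
) -> CoclusterModel:
    """Random start in F, mu and G.

    Row and column labels are seeded with D^2-weighted (k-means++ style)
    draws of K rows and R columns, each unit joining its nearest seed in
    plain Euclidean distance; the centroid and variance updates then make
    the state internally consistent. The random seeds give restarts their
    diversity while keeping every start in the scale of the data.

    Uniformly random labels are deliberately avoided: block means over
    near-uniform random subsets all sit close to the grand mean, which makes
    the first assignment passes noise-driven and prone to irrecoverably
    merging well-separated clusters.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if config.K > n or config.R > p:
        warnings.warn(
            f"more clusters than units requested (K={config.K} > n={n} or R={config.R} > p={p})",
            UserWarning,
            stacklevel=2,
        )
    row_seeds = _weighted_seeds(X, min(config.K, n), rng)
    col_seeds = _weighted_seeds(X.T, min(config.R, p), rng)
    rows = Indicator(_nearest_seed_labels(X, row_seeds), config.K)
    cols = Indicator(_nearest_seed_labels(X.T, col_seeds), config.R)
    mu = update_centroids(X, rows, cols, kernel, nonneg=config.nonneg_mu)
    tau = update_tau(X, rows, mu, cols, kernel)
    return CoclusterModel(rows=rows, cols=cols, mu=mu, tau=tau, phi=kernel.phi)


def fit_single(
    X: np.ndarray,
    coords: np.ndarray | None = None,
    config: FitConfig | None = None,
    rng: np.random.Generator | None = None,
    kernel: SpatialKernel | None = None,
) -> FitResult:
    """One run from a single random start.

    Either ``coords`` (from which the kernel is built at ``config.phi``) or a
    prefactored ``kernel`` must be supplied; ``fit`` passes the kernel so the
    p x p factorisation happens once per dataset, not once per restart.
    """
    if config is None:
        raise ValueError("a FitConfig is required")
    if kernel is None:
        if coords is None:
            raise ValueError("either coords or a prefactored kernel must be given")
        if not np.isscalar(config.phi):
            raise ValueError("fit_single requires a scalar phi; use phi_grid_fit for a grid")
        kernel = build_kernel(coords, float(config.phi), tau=1.0)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    t0 = time.perf_counter()

    model = initialize(X, config, rng, kernel)
    kernel = kernel.with_tau(model.tau)
    raw = loss(X, model, kernel)
    pen = raw + n * kernel.log_det_sigma
    raw_trace = [raw]
    pen_trace = [pen]
    best_model, best_pen, best_raw = model.copy(), pen, raw

    converged = False
    running_min = pen
    stable = 0
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        mu = update_centroids(X, model.rows, model.cols, kernel, prev=model.mu, nonneg=config.nonneg_mu)
        if config.row_step == "classification":
            rows = update_rows_classification(X, mu, model.cols, kernel)
        else:
            rows = update_rows_stochastic(X, mu, model.cols, kernel, rng)
        if config.col_step == "exact":
            cols = update_cols_exact(X, rows, mu, model.cols, kernel)
        elif config.col_step == "approx":
            cols = update_cols_approx(X, rows, mu)
        else:
            cols = update_cols_stochastic(X, rows, mu, model.cols, kernel, rng)
        tau = update_tau(X, rows, mu, cols, kernel)
        kernel = kernel.with_tau(tau)

        labels_unchanged = np.array_equal(rows.labels, model.rows.labels) and np.array_equal(
            cols.labels, model.cols.labels
        )
        model = CoclusterModel(rows=rows, cols=cols, mu=mu, tau=tau, phi=kernel.phi)
        raw = loss(X, model, kernel)
        pen = raw + n * kernel.log_det_sigma
        raw_trace.append(raw)
        pen_trace.append(pen)
        if log.isEnabledFor(logging.DEBUG):
            log.debug(
                "iter %d: loss %.6g penalized %.6g tau %.6g nonempty K %d R %d",
                n_iter, raw, pen, tau, count_nonempty(rows), count_nonempty(cols),
            )
        if pen < best_pen:
            best_model, best_pen, best_raw = model.copy(), pen, raw

        new_min = min(running_min, pen)
        rel = (running_min - new_min) / max(abs(running_min), 1e-300)
        running_min = new_min
        if rel < config.rel_tol:
            converged = True
            break
        if config.patience is not None:
            stable = stable + 1 if labels_unchanged else 0
            if stable >= config.patience:
                converged = True
                break

    return FitResult(
        model=best_model,
        loss_trace=np.asarray(raw_trace),
        penalized_trace=np.asarray(pen_trace),
        best_loss=best_pen,
        best_raw_loss=best_raw,
        n_iter=n_iter,
        converged=converged,
        nonempty_row_clusters=count_nonempty(best_model.rows),
        nonempty_col_clusters=count_nonempty(best_model.cols),
        variant=config.variant,
        phi_used=kernel.phi,
        runtime=time.perf_counter() - t0,
    )


def fit(
    X: np.ndarray,
    coords: np.ndarray | None = None,
    config: FitConfig | None = None,
    kernel: SpatialKernel | None = None,
) -> FitResult:
    """Best of ``config.n_restarts`` independent runs.

    Restart r uses the sub-seed ``config.seed + r``, so results are exactly
    reproducible and, were the restarts distributed, identical to sequential
    execution. The returned result is the restart with the lowest penalized
    loss; all restart losses are kept for stability diagnostics.
    """
    if config is None:
        raise ValueError("a FitConfig is required")
    if kernel is None:
        if coords is None:
            raise ValueError("either coords or a prefactored kernel must be given")
        if not np.isscalar(config.phi):
            raise ValueError("fit requires a scalar phi; use phi_grid_fit for a grid")
        kernel = build_kernel(coords, float(config.phi), tau=1.0)

    results: list[FitResult] = []
    errors: list[Exception] = []
    for r in range(config.n_restarts):
        rng = np.random.default_rng(config.seed + r)
        try:
            results.append(fit_single(X, config=config, rng=rng, kernel=kernel))
        except EmptyModelError as exc:  # pragma: no cover - requires pathological input
            errors.append(RuntimeError(f"restart {r} (seed {config.seed + r}) failed: {exc}"))
    if not results:
        raise RuntimeError(f"all {config.n_restarts} restarts failed: {errors}")
    restart_losses = np.array([res.best_loss for res in results])
    best = results[int(np.argmin(restart_losses))]
    best.restart_losses = restart_losses
    best.restart_taus = np.array([res.model.tau for res in results])
    return best


def phi_grid_fit(X: np.ndarray, coords: np.ndarray, config: FitConfig) -> GridResult:
    """Fit once per value of the kernel-scale grid and tabulate the outcomes.

    The table carries, per phi: variant, raw and penalized minimum losses,
    iteration count of the best restart, estimated tau, and the nonempty
    row/column cluster counts. The reported model is the minimum-penalized-
    loss row.
    """
    phis = np.atleast_1d(np.asarray(config.phi, dtype=float))
    if phis.size == 0:
        raise ValueError("the phi grid must be nonempty")
    results = []
    rows = []
    for phi in phis:
        res = fit(X, coords, replace(config, phi=float(phi)))
        results.append(res)
        rows.append(
            {
                "phi": float(phi),
                "variant": f"({res.variant[0][0].upper()},{res.variant[1][0].upper()})",
                "loss": res.best_raw_loss,
                "penalized_loss": res.best_loss,
                "n_iter": res.n_iter,
                "tau": res.model.tau,
                "n_row_clusters": res.nonempty_row_clusters,
                "n_col_clusters": res.nonempty_col_clusters,
                "converged": res.converged,
            }
        )
    table = pd.DataFrame(rows)
    best = results[int(table["penalized_loss"].idxmin())]
    return GridResult(table=table, results=results, best=best)
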