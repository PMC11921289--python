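"""Synthetic matrix-normal coclustered datasets with spatially contiguous
column clusters.

The generator draws a block-structured mean ``F mu G^T`` (random unbalanced
partitions with a minimum cluster size, centroids drawn around a preset mean
grid) and adds matrix-variate Gaussian noise with identity row covariance and
exponential-kernel column covariance ``Sigma = tau * K(S; phi)``. Pixels of
the same column cluster are laid out as contiguous vertical bands of a
near-square integer grid, so that within-cluster spatial correlation exceeds
between-cluster correlation — the regime the spatial column step is meant to
exploit.

Defaults: n=90 rows in K=3 clusters, p=100 pixels in R=4 clusters, minimum
cluster size 5, tau=3, phi=10 (grid units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernel import SpatialKernel, build_kernel
from .model import Indicator


def default_mean_matrix(K: int, R: int, step: float = 4.0) -> np.ndarray:
    """Preset block-mean grid ``m[k, r] = step * ((k + r) mod max(K, R))``,
    centred at zero.

    Cycling the levels makes every pair of row (and column) clusters differ in
    at least one block by ``step``; with the default step of 4 and unit
    centroid spread plus noise SD sqrt(3), adjacent blocks are at least two
    noise SDs apart, so recovery is hard but well-posed.
    """
    k = np.arange(K)[:, None]
    r = np.arange(R)[None, :]
    m = step * ((k + r) % max(K, R)).astype(float)
    return m - m.mean()


@dataclass
class SimulationConfig:
    n: int = 90
    p: int = 100
    K_true: int = 3
    R_true: int = 4
    tau_true: float = 3.0
    phi_true: float = 10.0
    spatial: bool = True
    min_cluster_size: int = 5
    mean_matrix: np.ndarray | None = None  # defaults to default_mean_matrix(K_true, R_true)
    centroid_sd: float = 1.0
    zero_noise: bool = False  # test hook: X = F mu G^T exactly
    seed: int = 0

    def resolved_mean_matrix(self) -> np.ndarray:
        if self.mean_matrix is None:
            return default_mean_matrix(self.K_true, self.R_true)
        m = np.asarray(self.mean_matrix, dtype=float)
        if m.shape != (self.K_true, self.R_true):
            raise ValueError(f"mean_matrix must be {self.K_true} x {self.R_true}, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("mean_matrix must be finite")
        return m


@dataclass
class SyntheticDataset:
    """Generated data plus the ground truth needed for recovery tests."""

    X: np.ndarray
    coords: np.ndarray
    rows_true: Indicator
    cols_true: Indicator
    mu_true: np.ndarray
    kernel_true: SpatialKernel | None  # None marks identity column covariance
    config: SimulationConfig

    @property
    def mean(self) -> np.ndarray:
        return self.mu_true[self.rows_true.labels][:, self.cols_true.labels]


def random_partition(m: int, C: int, min_size: int, rng: np.random.Generator) -> Indicator:
    """Partition m units into C clusters of random sizes, each >= min_size.

    Sizes are uniform over the compositions satisfying the constraint
    (stars-and-bars on the surplus m - C*min_size); unit-to-cluster assignment
    is then a random permutation.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if C < 1 or C * min_size > m:
        raise ValueError(f"cannot split {m} units into {C} clusters of size >= {min_size}")
    surplus = m - C * min_size
    if C == 1:
        sizes = np.array([m])
    else:
        cuts = np.sort(rng.choice(surplus + C - 1, size=C - 1, replace=False))
        bounds = np.concatenate(([-1], cuts, [surplus + C - 1]))
        sizes = min_size + (np.diff(bounds) - 1)
    labels = rng.permutation(np.repeat(np.arange(C), sizes))
    return Indicator(labels, C)


def layout_pixels(p: int, cols_true: Indicator) -> np.ndarray:
    """Place p pixels on an integer near-square grid so that each column
    cluster occupies a contiguous vertical band (clusters side by side in
    index order). Mean within-cluster distance is strictly smaller than mean
    between-cluster distance for any nontrivial partition."""
    if cols_true.m != p:
        raise ValueError("indicator length must equal p")
    height = max(1, int(round(np.sqrt(p))))
    cells = np.arange(p)
    grid = np.column_stack((cells // height, cells % height)).astype(float)
    order = np.argsort(cols_true.labels, kind="stable")
    coords = np.empty((p, 2))
    coords[order] = grid
    return coords


def sample_centroids(mean_matrix: np.ndarray, rng: np.random.Generator, sd: float = 1.0) -> np.ndarray:
    """Draw each centroid independently as Normal(m[k, r], sd^2); sd=0 is the
    deterministic test hook mu = m."""
    mean_matrix = np.asarray(mean_matrix, dtype=float)
    if not np.all(np.isfinite(mean_matrix)):
        raise ValueError("mean_matrix must be finite")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    return mean_matrix + sd * rng.standard_normal(mean_matrix.shape)


def sample_experiment(
    mean: np.ndarray,
    kernel: SpatialKernel | None,
    rng: np.random.Generator,
    zero_noise: bool = False,
) -> np.ndarray:
    """Matrix-normal draw ``mean + Z L^T`` with Z iid standard Gaussian: rows
    have covariance Sigma = L L^T, rows are mutually independent. ``kernel=None``
    means identity column covariance; ``zero_noise`` returns the mean itself."""
    mean = np.asarray(mean, dtype=float)
    if zero_noise:
        return mean.copy()
    Z = rng.standard_normal(mean.shape)
    if kernel is None:
        return mean + Z
    if kernel.p != mean.shape[1]:
        raise ValueError("kernel size does not match the number of columns")
    return mean + Z @ kernel.chol_lower.T


def generate(config: SimulationConfig) -> SyntheticDataset:
    """Compose the full generative scheme, reproducibly under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    rows_true = random_partition(config.n, config.K_true, config.min_cluster_size, rng)
    cols_true = random_partition(config.p, config.R_true, config.min_cluster_size, rng)
    coords = layout_pixels(config.p, cols_true)
    mu_true = sample_centroids(config.resolved_mean_matrix(), rng, sd=config.centroid_sd)
    kernel = build_kernel(coords, config.phi_true, config.tau_true) if config.spatial else None
    mean = mu_true[rows_true.labels][:, cols_true.labels]
    X = sample_experiment(mean, kernel, rng, zero_noise=config.zero_noise)
    return SyntheticDataset(
        X=X,
        coords=coords,
        rows_true=rows_true,
        cols_true=cols_true,
        mu_true=mu_true,
        kernel_true=kernel,
        config=config,
    )
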