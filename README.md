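# trifase

Spatially informed semi-nonnegative matrix trifactorization (TRIFASE) for
coclustering expression matrices whose columns live on a spatial raster —
the typical shape of MALDI mass-spectrometry-imaging data, where an
n × p matrix X holds the abundance of n molecular signals (rows, e.g. lipid
m/z values) at p tissue pixels (columns), each pixel carrying planar
coordinates (x, y). Coclustering simultaneously groups the signals into K
clusters and segments the tissue into R regions, exposing blocks of
molecules over- or under-expressed in specific tissue areas. The same
machinery applies to any spatial omics matrix (e.g. spatial
transcriptomics).

## Model

X is approximated by the trifactorization `F μ Gᵀ`, where

* `F` (n × K) and `G` (p × R) are hard cluster-indicator matrices (one 1 per
  row),
* `μ` (K × R) holds the cocluster centroids; μ is real-valued ("semi"-NMTF),
  so X may be log-transformed / centred data,
* spatial correlation among pixels enters through the column covariance
  `Σ = τ·K(S; φ)` with the exponential kernel
  `K[j,j′] = exp(−‖s_j − s_j′‖ / φ)`, marginal variance τ > 0 and scale
  φ > 0 in coordinate units.

The loss is the squared Frobenius norm of the column-whitened residual,

    ‖(X − FμGᵀ)(L⁻¹)ᵀ‖²_F  =  tr[(X − FμGᵀ) Σ⁻¹ (X − FμGᵀ)ᵀ],   Σ = LLᵀ,

the negative log-kernel of a matrix-variate Gaussian
`X ~ N(FμGᵀ, Iₙ, Σ)`. It is minimised by alternating convex steps:
generalised-least-squares centroids, per-row nearest-whitened-centroid
assignment, a column step that is either exact (sequential coordinate
descent on the full loss), approximate (per-column nearest composite
centroid, ignoring Σ — fast and parallel), or stochastic (stochastic-EM
draws from softmax weights of the full loss), and a closed-form update
`τ ← tr[(X−FμGᵀ) K⁻¹ (X−FμGᵀ)ᵀ] / (np)` of the marginal variance, obtained
from the loss penalized by `n·log|Σ|`. φ is held fixed per fit and explored
on a grid. Runs are repeated from many random starts and the best
(penalized-loss) solution is kept; starting with more clusters than needed
and letting some empty is the route to choosing K and R.

## Worked example

```python
import trifase

# a synthetic dataset with the package's standard simulation conditions:
# 90 signals x 100 pixels, 3 row and 4 column clusters laid out as
# contiguous bands, exponential-kernel noise with tau=3, phi=10
data = trifase.generate(trifase.SimulationConfig(seed=1))

config = trifase.FitConfig(K=3, R=4, phi=10.0, col_step="approx",
                           n_restarts=50, seed=7)
result = trifase.fit(data.X, data.coords, config)
print(trifase.recovery_report(result, data))
```

prints (runtime field varies):

```
{'row_concordance': 1.0, 'col_concordance': 1.0,
 'nonempty_row_clusters': 3, 'nonempty_col_clusters': 4,
 'tau_est': 2.9967413963067266, 'tau_error': -0.003258603693273354,
 'n_iter': 3, 'runtime': 0.005, 'penalized_loss': -29.21957921291869}
```

Both partitions are recovered exactly (concordance 1 = zero classification
error rate against the generating labels), and the estimated marginal
variance 2.997 matches the generating value 3. The same analysis from the
shell:

```
trifase simulate --seed 1 --out sim/
trifase fit --matrix sim/X.csv --coords sim/coords.csv \
            --k 3 --r 4 --phi 10 --col-step A --restarts 50 --seed 7 --out fit/
trifase evaluate --truth-cols sim/col_labels_true.csv --fit-cols fit/col_labels.csv
```

For real abundance data add `--log-transform` (fits X = log(Y+1)), and use
`trifase grid --phi 0.5,1,3,10` to compare kernel scales; the grid table
mirrors one row per φ with the minimum loss, estimated τ and nonempty
cluster counts, selecting the φ with the lowest penalized loss.

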