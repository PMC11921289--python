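"""Partition agreement and recovery summaries.

The classification error rate (CER) between two partitions of the same m
units is the fraction of the m(m-1)/2 unordered pairs whose co-membership
status (together / apart) differs between the partitions; it is invariant to
relabelling and equals one minus the Rand index, which is how it is computed
here (the quadratic pair enumeration is kept as the reference in the test
suite). Concordance is 1 - CER: 1 means identical partitions up to
relabelling.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import rand_score

from .fit import FitResult
from .model import count_nonempty
from .simulate import SyntheticDataset


def _validate_pair(labels_a, labels_b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.ndim != 1 or b.ndim != 1 or a.size != b.size:
        raise ValueError(f"label vectors must be 1-D and of equal length, got {a.shape} and {b.shape}")
    if a.size < 2:
        raise ValueError("at least two units are required to compare partitions")
    return a, b


def cer(labels_a, labels_b) -> float:
    """Classification error rate: pairwise co-membership disagreement in [0, 1]."""
    a, b = _validate_pair(labels_a, labels_b)
    return 1.0 - float(rand_score(a, b))


def concordance(labels_a, labels_b) -> float:
    """Agreement index 1 - CER."""
    return 1.0 - cer(labels_a, labels_b)


def recovery_report(fit: FitResult, truth: SyntheticDataset) -> dict:
    """Compare a fit against the generating truth of a synthetic dataset.

    Returns row/column concordance, nonempty cluster counts, the estimated
    marginal variance and its error, and run diagnostics.
    """
    model = fit.model
    if model.rows.m != truth.rows_true.m or model.cols.m != truth.cols_true.m:
        raise ValueError("fit and truth refer to data of different shapes")
    return {
        "row_concordance": concordance(model.rows.labels, truth.rows_true.labels),
        "col_concordance": concordance(model.cols.labels, truth.cols_true.labels),
        "nonempty_row_clusters": count_nonempty(model.rows),
        "nonempty_col_clusters": count_nonempty(model.cols),
        "tau_est": model.tau,
        "tau_error": model.tau - truth.config.tau_true,
        "n_iter": fit.n_iter,
        "runtime": fit.runtime,
        "penalized_loss": fit.best_loss,
    }
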