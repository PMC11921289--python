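"""Delimited-text I/O for datasets and fit results.

The canonical interchange formats are CSV/TSV (autodetected by extension):
a numeric n x p matrix file, optionally with a header row and a leading
column of row identifiers (e.g. m/z labels), and a coordinate file with two
numeric columns named x and y, one row per pixel, in the column order of the
matrix. Raw nonnegative abundances are mapped to the real line with
``log(Y + 1)`` before fitting.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .fit import FitConfig, FitResult
from .model import count_nonempty


def _sep(path: str | Path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab", ".txt")) else ","


def _read_matrix(path: str | Path) -> tuple[np.ndarray, list[str] | None]:
    """Read a numeric matrix, tolerating an optional header row and an
    optional first column of row identifiers."""
    raw = pd.read_csv(path, sep=_sep(path), header=None, dtype=str)
    first_row_numeric = raw.iloc[0].apply(_is_number).all()
    header = None if first_row_numeric else 0
    df = pd.read_csv(path, sep=_sep(path), header=header, float_precision="round_trip")
    row_ids = None
    first_col = df.iloc[:, 0]
    if not pd.api.types.is_numeric_dtype(first_col):
        row_ids = first_col.astype(str).tolist()
        df = df.iloc[:, 1:]
    try:
        X = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cells in matrix file {path}: {exc}") from exc
    return X, row_ids


def _is_number(token) -> bool:
    try:
        float(token)
        return True
    except (TypeError, ValueError):
        return False


def _read_coords(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep=_sep(path), header=None, dtype=str)
    if df.iloc[0].apply(_is_number).all():
        coords = pd.read_csv(path, sep=_sep(path), header=None, float_precision="round_trip").to_numpy(dtype=float)
    else:
        named = pd.read_csv(path, sep=_sep(path), float_precision="round_trip")
        named.columns = [str(c).strip().lower() for c in named.columns]
        if not {"x", "y"}.issubset(named.columns):
            raise ValueError(f"coordinate file {path} must have columns named x and y")
        coords = named[["x", "y"]].to_numpy(dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError(f"coordinate file {path} must have exactly two numeric columns")
    return coords


def read_dataset(matrix_path: str | Path, coords_path: str | Path):
    """Load a matrix/coordinate file pair into ``(X, coords, row_ids)``.

    The coordinate row order is taken to be the column order of X; a shape
    mismatch raises, duplicated coordinates only warn (the kernel
    factorisation handles them with jitter).
    """
    X, row_ids = _read_matrix(matrix_path)
    coords = _read_coords(coords_path)
    if X.shape[1] != coords.shape[0]:
        raise ValueError(
            f"matrix has {X.shape[1]} columns but the coordinate file has {coords.shape[0]} rows"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError(f"matrix file {matrix_path} contains non-finite values")
    if len(np.unique(coords, axis=0)) < coords.shape[0]:
        warnings.warn("duplicate pixel coordinates detected", UserWarning, stacklevel=2)
    return X, coords, row_ids


def log_transform(Y: np.ndarray) -> np.ndarray:
    """Entrywise ``log(Y + 1)`` for raw nonnegative abundances."""
    Y = np.asarray(Y, dtype=float)
    if np.any(Y < 0):
        raise ValueError("log transform expects nonnegative raw abundances")
    return np.log1p(Y)


#: float format that round-trips IEEE doubles exactly through text
_FLOAT_FMT = "%.17g"


def write_matrix(path: str | Path, X: np.ndarray) -> None:
    pd.DataFrame(np.asarray(X)).to_csv(
        path, sep=_sep(path), header=False, index=False, float_format=_FLOAT_FMT
    )


def write_coords(path: str | Path, coords: np.ndarray) -> None:
    pd.DataFrame(np.asarray(coords), columns=["x", "y"]).to_csv(
        path, sep=_sep(path), index=False, float_format=_FLOAT_FMT
    )


def write_labels(path: str | Path, labels: np.ndarray, coords: np.ndarray | None = None) -> None:
    if coords is None:
        df = pd.DataFrame({"unit": np.arange(len(labels)), "label": np.asarray(labels)})
    else:
        df = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], "label": np.asarray(labels)})
    df.to_csv(path, sep=_sep(path), index=False)


def read_labels(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep=_sep(path))["label"].to_numpy(dtype=np.int64)


def write_result(
    fit: FitResult,
    out_dir: str | Path,
    coords: np.ndarray | None = None,
    config: FitConfig | None = None,
    row_ids: list[str] | None = None,
) -> dict[str, Path]:
    """Serialize a fit: label files, centroid matrix, loss trace and a JSON
    summary (plus a config echo when the configuration is given)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = fit.model
    paths = {}

    rows_df = pd.DataFrame({"row": row_ids or np.arange(model.rows.m), "label": model.rows.labels})
    paths["row_labels"] = out / "row_labels.csv"
    rows_df.to_csv(paths["row_labels"], index=False)

    paths["col_labels"] = out / "col_labels.csv"
    write_labels(paths["col_labels"], model.cols.labels, coords=coords)

    paths["centroids"] = out / "centroids.csv"
    pd.DataFrame(model.mu).to_csv(paths["centroids"], header=False, index=False)

    paths["loss_trace"] = out / "loss_trace.csv"
    pd.DataFrame(
        {
            "iteration": np.arange(len(fit.loss_trace)),
            "loss": fit.loss_trace,
            "penalized_loss": fit.penalized_trace,
        }
    ).to_csv(paths["loss_trace"], index=False)

    summary = {
        "best_loss": fit.best_loss,
        "best_raw_loss": fit.best_raw_loss,
        "n_iter": fit.n_iter,
        "converged": bool(fit.converged),
        "variant": list(fit.variant),
        "phi": fit.phi_used,
        "tau": model.tau,
        "nonempty_row_clusters": count_nonempty(model.rows),
        "nonempty_col_clusters": count_nonempty(model.cols),
        "row_cluster_sizes": model.rows.counts().tolist(),
        "col_cluster_sizes": model.cols.counts().tolist(),
        "restart_losses": None if fit.restart_losses is None else fit.restart_losses.tolist(),
        "runtime": fit.runtime,
    }
    paths["summary"] = out / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=2))

    if config is not None:
        echo = dataclasses.asdict(config)
        echo["phi"] = np.asarray(config.phi).tolist()
        paths["config"] = out / "config.json"
        paths["config"].write_text(json.dumps(echo, indent=2))
    return paths
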