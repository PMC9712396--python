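"""Subject-level connectomes: absolutized Pearson correlation matrices.

Nodes are atlas regions, edges are ``|r|`` between regional timeseries.
Networks are kept fully weighted (no thresholding, no Fisher transform):
group comparisons downstream operate on raw ``|r|`` means.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Timeseries",
    "ConnectivityMatrix",
    "build_connectivity",
    "read_matrix",
    "write_matrix",
    "read_matrix_index",
    "write_matrix_index",
]


@dataclass(frozen=True)
class Timeseries:
    """T x N matrix of regional signals plus node labels.

    ``values[t, i]`` is the signal of node ``node_labels[i]`` at volume ``t``.
    """

    values: np.ndarray
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))
        if values.ndim != 2:
            raise ValueError("timeseries must be a T x N matrix")
        if values.shape[1] != len(self.node_labels):
            raise ValueError(
                f"{values.shape[1]} columns but {len(self.node_labels)} node labels"
            )
        if len(set(self.node_labels)) != len(self.node_labels):
            raise ValueError("node labels must be unique")
        if values.shape[0] < 20:
            raise ValueError("need at least 20 volumes")
        if not np.all(np.isfinite(values)):
            raise ValueError("timeseries contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def select_nodes(self, labels: list[str]) -> "Timeseries":
        """Restrict to ``labels`` (in the given order)."""
        idx = [self.node_labels.index(l) for l in labels]
        return Timeseries(self.values[:, idx], tuple(labels))


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric N x N matrix of absolutized correlations, zero diagonal."""

    w: np.ndarray
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))
        n = len(self.node_labels)
        if w.shape != (n, n):
            raise ValueError(f"matrix shape {w.shape} does not match {n} labels")
        if not np.all(np.isfinite(w)):
            raise ValueError("connectivity matrix contains non-finite values")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if w.min() < -1e-12 or w.max() > 1 + 1e-12:
            raise ValueError("edge weights must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.w.shape[0]


def build_connectivity(ts: Timeseries) -> ConnectivityMatrix:
    """Absolutized Pearson connectivity: ``w_ij = |r(ts_i, ts_j)|``, ``w_ii = 0``.

    Zero-variance nodes are an error (they should have been dropped in QC);
    the failing node is named.
    """
    x = ts.values
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd < 1e-12)
    if dead.size:
        names = ", ".join(ts.node_labels[i] for i in dead[:5])
        raise ValueError(f"zero-variance node(s) reached connectivity: {names}")
    r = np.corrcoef(x, rowvar=False)
    w = np.abs(r)
    np.clip(w, 0.0, 1.0, out=w)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w, ts.node_labels)


def write_matrix(m: ConnectivityMatrix, path: str | Path) -> None:
    """Whitespace-delimited N x N text matrix with a header row of node labels."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(m.node_labels) + "\n")
        for row in m.w:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    with path.open() as fh:
        labels = fh.readline().split()
    w = np.loadtxt(path, skiprows=1)
    return ConnectivityMatrix(np.atleast_2d(w), tuple(labels))


def write_matrix_index(entries: dict[str, Path], path: str | Path) -> None:
    """``index.tsv`` mapping subject_id -> matrix file path."""
    df = pd.DataFrame(
        {"subject_id": list(entries), "path": [str(p) for p in entries.values()]}
    )
    df.to_csv(path, sep="\t", index=False)


def read_matrix_index(path: str | Path) -> dict[str, Path]:
    df = pd.read_csv(path, sep="\t")
    base = Path(path).parent
    out: dict[str, Path] = {}
    for _, row in df.iterrows():
        p = Path(row["path"])
        out[str(row["subject_id"])] = p if p.is_absolute() else base / p
    return out
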