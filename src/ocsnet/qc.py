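"""Subject- and node-level quality control, plus joint denoising.

Motion exclusion follows the study rule: drop a subject when mean framewise
displacement (FD) exceeds 0.25 mm, or when more than 20% of volumes exceed
0.2 mm. Node exclusion drops atlas regions with fewer than four
signal-containing voxels, applied sample-wide (union of per-subject drops).
Denoising is a single joint least-squares projection onto nuisance
regressors plus a discrete-cosine basis spanning out-of-band frequencies —
"simultaneous" regression and band-pass filtering in one idempotent step,
which avoids the noise-reintroduction artifact of running them sequentially.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ocsnet.connectome import Timeseries

__all__ = [
    "QCReport",
    "motion_exclude",
    "drop_low_signal_nodes",
    "drop_zero_variance_nodes",
    "denoise",
    "read_fd_trace",
    "write_fd_trace",
]

#: Study defaults: mean-FD threshold (mm), spike threshold (mm), spike fraction.
MEAN_FD_THRESH = 0.25
SPIKE_FD_THRESH = 0.2
SPIKE_FRAC = 0.20

#: Repetition time in seconds (TR = 1760 ms) and band-pass edges in Hz.
DEFAULT_TR = 1.76
DEFAULT_BAND = (0.009, 0.08)


@dataclass(frozen=True)
class QCReport:
    included: bool
    reasons: tuple[str, ...] = ()
    dropped_nodes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.included and self.reasons:
            raise ValueError("included subjects cannot carry exclusion reasons")
        if not self.included and not self.reasons:
            raise ValueError("excluded subjects must carry at least one reason")


def motion_exclude(
    fd: np.ndarray,
    mean_thresh: float = MEAN_FD_THRESH,
    spike_thresh: float = SPIKE_FD_THRESH,
    spike_frac: float = SPIKE_FRAC,
) -> QCReport:
    """Apply the two motion-exclusion rules to a per-volume FD trace (mm).

    Excluded iff mean(fd) > ``mean_thresh`` or the fraction of volumes with
    fd > ``spike_thresh`` is strictly greater than ``spike_frac`` ("more
    than 20% of volumes"). Both reasons are reported when both fire.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("empty FD trace")
    if np.any(fd < 0):
        raise ValueError("framewise displacement cannot be negative")
    reasons = []
    if fd.mean() > mean_thresh:
        reasons.append("mean_fd")
    if np.mean(fd > spike_thresh) > spike_frac:
        reasons.append("spike_frac")
    return QCReport(included=not reasons, reasons=tuple(reasons))


def drop_low_signal_nodes(
    voxel_counts: dict[str, int], min_voxels: int = 4
) -> list[str]:
    """Node labels with fewer than ``min_voxels`` signal-containing voxels.

    ``voxel_counts`` may hold sample-wide minima; the caller applies the
    returned drop list uniformly across all subjects (sample-wide exclusion).
    """
    for label, c in voxel_counts.items():
        if c < 0:
            raise ValueError(f"negative voxel count for node {label}")
    return [label for label, c in voxel_counts.items() if c < min_voxels]


def drop_zero_variance_nodes(ts: Timeseries, tol: float = 1e-12) -> list[str]:
    """Signal-based surrogate for the voxel-count rule: flat nodes are dropped."""
    sd = ts.values.std(axis=0)
    return [ts.node_labels[i] for i in np.flatnonzero(sd < tol)]


def _dct_basis_outside_band(
    n_volumes: int, tr: float, band: tuple[float, float]
) -> np.ndarray:
    """DCT-II columns at frequencies outside ``band`` (intercept excluded).

    Basis vector k (k = 1..T-1) is cos(pi*(t+0.5)*k/T) with frequency
    k / (2*T*tr) Hz, so the set spans all drift/high-frequency structure
    the band-pass filter should remove.
    """
    low, high = band
    t = np.arange(n_volumes)
    cols = []
    for k in range(1, n_volumes):
        f = k / (2.0 * n_volumes * tr)
        if f < low or f > high:
            cols.append(np.cos(np.pi * (t + 0.5) * k / n_volumes))
    if not cols:
        return np.empty((n_volumes, 0))
    return np.column_stack(cols)


def denoise(
    ts: Timeseries,
    nuisance: np.ndarray | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    tr: float = DEFAULT_TR,
    rcond: float = 1e-10,
) -> Timeseries:
    """Simultaneous nuisance regression and band-pass filtering.

    Projects each node signal onto the orthogonal complement of
    [intercept | nuisance | out-of-band cosine basis] in a single joint
    least-squares step. Rank deficiency is handled by a pseudoinverse
    (equivalent to a minimum-norm regularized fit), so collinear nuisance
    columns do not raise.
    """
    T = ts.n_volumes
    nyquist = 1.0 / (2.0 * tr)
    if not (0 < band[0] < band[1] <= nyquist):
        raise ValueError(f"band must satisfy 0 < low < high <= Nyquist ({nyquist:.4g} Hz)")
    cols = [np.ones((T, 1)), _dct_basis_outside_band(T, tr, band)]
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != T:
            raise ValueError("nuisance regressors must have T rows")
        cols.insert(1, nuisance)
    X = np.hstack(cols)
    beta, *_ = np.linalg.lstsq(X, ts.values, rcond=rcond)
    resid = ts.values - X @ beta
    return Timeseries(resid, ts.node_labels)


def read_fd_trace(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, ndmin=1)


def write_fd_trace(fd: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(fd, dtype=float), fmt="%.6g")
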