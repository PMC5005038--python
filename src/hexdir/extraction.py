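"""Trial-pattern extraction from 4-D time series.

The analysis window targets the late BOLD response of the 10 s imagination
period: the volume during which imagination ends plus the two following
volumes are averaged per trial.  Before extraction the per-voxel time
series are residualised against a nuisance GLM (six motion regressors plus
intercept) and, in time-series mode, high-pass filtered with a 100 s
cutoff via discrete-cosine basis projection.

Volume-index convention: volume k covers [k*TR, (k+1)*TR), so the window
starts at floor(end_time / TR).  The convention the acquisition software
uses for on-the-boundary times is not observable from the data; this one
is fixed here and logged in extraction results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NuisanceError",
    "residualize_nuisance",
    "highpass_filter",
    "window_indices",
    "extract_trial_patterns",
    "compute_tsnr",
]


class NuisanceError(ValueError):
    pass


def _as_matrix(timeseries) -> np.ndarray:
    x = np.asarray(timeseries, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError("timeseries must be time x voxels")
    return x


def residualize_nuisance(timeseries, nuisance) -> np.ndarray:
    """Per-voxel least-squares residuals against the nuisance regressors.

    An intercept column is appended if none is present.  The residuals are
    orthogonal to every regressor column.  Rank-deficient designs raise a
    :class:`NuisanceError` naming the collinear columns.
    """
    y = _as_matrix(timeseries)
    X = np.asarray(nuisance, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise NuisanceError("regressor and time-series lengths differ")
    has_intercept = np.any(np.all(X == X[0, :], axis=0))
    if not has_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = [
            k for k in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, k, axis=1)) == rank
        ]
        raise NuisanceError(f"rank-deficient nuisance model; collinear columns {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _dct_basis(n: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine columns for all frequencies below 1/cutoff, DC included."""
    duration = n * tr_s
    k_max = int(np.floor(2.0 * duration / cutoff_s))
    t = np.arange(n)
    cols = [np.ones(n) / np.sqrt(n)]
    for k in range(1, k_max + 1):
        cols.append(np.sqrt(2.0 / n) * np.cos(np.pi * k * (2 * t + 1) / (2 * n)))
    return np.column_stack(cols)


def highpass_filter(timeseries, cutoff_s: float = 100.0, tr_s: float = 1.8) -> np.ndarray:
    """Remove fluctuations slower than ``cutoff_s`` (and the mean) by
    projecting out a discrete-cosine basis."""
    if not np.isfinite(cutoff_s):
        raise ValueError("an infinite cutoff disables the filter; pass a finite value")
    if cutoff_s <= 2.0 * tr_s:
        raise ValueError("cutoff must exceed twice the TR")
    y = _as_matrix(timeseries)
    B = _dct_basis(y.shape[0], tr_s, cutoff_s)  # orthonormal
    return y - B @ (B.T @ y)


def window_indices(imagination_end_s: float, tr_s: float, n_extra: int = 2) -> np.ndarray:
    """0-based indices of the analysis window: the volume containing the
    imagination end plus the ``n_extra`` following volumes."""
    first = int(np.floor(imagination_end_s / tr_s))
    return np.arange(first, first + n_extra + 1)


def extract_trial_patterns(
    timeseries,
    trials: pd.DataFrame,
    tr_s: float = 1.8,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Average the 3-volume analysis window per trial; trials x voxels.

    ``timeseries`` is time x voxels, or a 4-D array (x, y, z, time) if a
    boolean ``mask`` selects the voxels.  Raises listing the offending
    trials when any window exceeds the run length.
    """
    x = np.asarray(timeseries, dtype=float)
    if x.ndim == 4:
        if mask is None:
            raise ValueError("a 4-D time series needs a voxel mask")
        x = x[mask].T  # time x voxels
    else:
        x = _as_matrix(x)
    n_vols = x.shape[0]
    too_late = [
        int(t.trial_id)
        for t in trials.itertuples(index=False)
        if window_indices(t.imagination_end_s, tr_s)[-1] >= n_vols
    ]
    if too_late:
        raise ValueError(f"analysis window exceeds run length for trials {too_late}")
    out = np.empty((len(trials), x.shape[1]))
    for k, t in enumerate(trials.itertuples(index=False)):
        out[k] = x[window_indices(t.imagination_end_s, tr_s)].mean(axis=0)
    return out


def compute_tsnr(timeseries, mask: np.ndarray | None = None, voxelwise: bool = False):
    """Temporal signal-to-noise ratio of a region.

    By default tSNR is computed on the region-mean time course: its temporal
    mean divided by its temporal standard deviation.  ``voxelwise=True``
    instead averages voxelwise tSNR values.  Zero temporal variance yields
    NaN (undefined), never infinity.
    """
    x = np.asarray(timeseries, dtype=float)
    if x.ndim == 4:
        if mask is None:
            raise ValueError("a 4-D time series needs a region mask")
        x = x[mask].T
    else:
        x = _as_matrix(x)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    if voxelwise:
        sd = x.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(sd > 0, x.mean(axis=0) / sd, np.nan)
        return float(np.nanmean(vals)) if np.any(sd > 0) else float("nan")
    m = x.mean(axis=1)
    sd = m.std()
    return float(m.mean() / sd) if sd > 0 else float("nan")
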