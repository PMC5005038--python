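"""Pairwise pattern similarity and directional condition contrasts.

Similarity between two trials is the Pearson correlation of their
multi-voxel activity patterns, Fisher z-transformed (atanh) before
averaging.  Four contrast schemes compare mean z between pair conditions
defined on the angular difference Delta of the sampled directions:

``onefold``   Delta <= 30 (similar)      vs  Delta >= 60 (dissimilar)
``mod60``     Delta mod 60 == 0          vs  Delta mod 60 == 30
``mod90``     Delta mod 90 == 0          vs  Delta mod 90 in {30, 60}
``cardinal``  both directions cardinal   vs  the rest

On the 30-degree direction grid the one-fold conditions partition all
pairs (no Delta strictly between 30 and 60 exists), and the mod-60
remainder is always 0 or 30.  Pair-exclusion filters and distance
residualisation implement the design controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Z_CAP",
    "ContrastSpec",
    "ContrastResult",
    "ContrastError",
    "pairwise_similarity",
    "similarity_matrix",
    "condition_masks",
    "condition_contrast",
    "contrast_from_z",
    "filter_pairs",
    "residualize_distance",
]

#: Fisher z is capped at atanh(1 - 1e-15) so r = +-1 (noiseless synthetic
#: patterns) stays finite; such pairs are flagged.
Z_CAP = float(np.arctanh(1.0 - 1e-15))

SCHEMES = ("onefold", "mod60", "mod90", "cardinal")

#: recognised pair-exclusion filter names -> label column dropped when True
FILTER_COLUMNS = {
    "same_start": "same_start",
    "same_target": "same_target",
    "same_combo": "same_combo",
    "same_block": "same_block",
    "inner_target": "both_inner_target",
    "ns_street": "both_ns_street",
}

DISTANCE_COLUMNS = {
    "mean": "dist_mean",
    "absdiff": "dist_absdiff",
    "neighborhood": "dist_neighborhood",
}


class ContrastError(ValueError):
    pass


@dataclass(frozen=True)
class ContrastSpec:
    scheme: str = "mod60"
    filters: tuple[str, ...] = ()
    tail: str = "one"

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ContrastError(f"unknown scheme {self.scheme!r}")
        unknown = set(self.filters) - set(FILTER_COLUMNS)
        if unknown:
            raise ContrastError(f"unknown exclusion filter(s): {sorted(unknown)}")


@dataclass(frozen=True)
class ContrastResult:
    mean_a: float
    mean_b: float
    difference: float
    n_a: int
    n_b: int


def fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15))


def similarity_matrix(patterns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(z, valid) matrices of Fisher-z Pearson correlations between trial rows.

    ``patterns`` is trials x voxels.  Rows with zero variance yield invalid
    entries (they have no defined correlation).
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2 or patterns.shape[1] < 2:
        raise ValueError("need a trials x voxels matrix with at least 2 voxels")
    sd = patterns.std(axis=1)
    ok = sd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(patterns)
    valid = np.outer(ok, ok)
    np.fill_diagonal(valid, False)
    z = np.where(valid, fisher_z(np.where(valid, r, 0.0)), np.nan)
    return z, valid


def pairwise_similarity(patterns: np.ndarray) -> pd.DataFrame:
    """Long-format similarity table for all unordered trial pairs (i < j)."""
    z, valid = similarity_matrix(patterns)
    n = z.shape[0]
    if n < 2:
        raise ValueError("need at least 2 trials")
    i, j = np.triu_indices(n, k=1)
    r = np.tanh(z[i, j])
    return pd.DataFrame(
        {
            "i": i,
            "j": j,
            "r": np.where(valid[i, j], r, np.nan),
            "z": z[i, j],
            "valid": valid[i, j],
            "capped": valid[i, j] & (np.abs(z[i, j]) >= Z_CAP - 1e-9),
        }
    )


def condition_masks(labels: pd.DataFrame, scheme: str) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (condition A, condition B) masks over the rows of ``labels``."""
    if scheme == "onefold":
        a = labels.delta_deg.to_numpy() <= 30
        b = labels.delta_deg.to_numpy() >= 60
    elif scheme == "mod60":
        a = labels.rem60.to_numpy() == 0
        b = labels.rem60.to_numpy() == 30
    elif scheme == "mod90":
        a = labels.rem90.to_numpy() == 0
        b = np.isin(labels.rem90.to_numpy(), (30, 60))
    elif scheme == "cardinal":
        a = labels.both_cardinal.to_numpy()
        b = ~a
    else:
        raise ContrastError(f"unknown scheme {scheme!r}")
    return a, b


def filter_pairs(labels: pd.DataFrame, exclusions: tuple[str, ...] | list[str]) -> np.ndarray:
    """Boolean keep-mask over pairs, False where any requested flag is set."""
    keep = np.ones(len(labels), dtype=bool)
    for name in exclusions:
        col = FILTER_COLUMNS.get(name)
        if col is None:
            raise ContrastError(f"unknown exclusion filter {name!r}")
        keep &= ~labels[col].to_numpy()
    return keep


def condition_contrast(
    sim: pd.DataFrame, labels: pd.DataFrame, spec: ContrastSpec
) -> ContrastResult:
    """Mean Fisher-z per condition and the A-B difference.

    Condition means are unweighted means over the included valid pairs; the
    ``sim`` and ``labels`` tables must describe the same (i, j) pairs in the
    same order.
    """
    if len(sim) != len(labels):
        raise ContrastError("similarity and label tables must align")
    keep = filter_pairs(labels, spec.filters) & sim.valid.to_numpy()
    a, b = condition_masks(labels, spec.scheme)
    z = sim.z.to_numpy()
    na, nb = int((a & keep).sum()), int((b & keep).sum())
    if na == 0 or nb == 0:
        raise ContrastError(
            f"empty condition after filters {spec.filters!r} (nA={na}, nB={nb})"
        )
    ma = float(z[a & keep].mean())
    mb = float(z[b & keep].mean())
    return ContrastResult(ma, mb, ma - mb, na, nb)


def contrast_from_z(
    zmat: np.ndarray,
    directions_deg: np.ndarray,
    scheme: str = "mod60",
    include: np.ndarray | None = None,
) -> float:
    """Fast condition contrast from a z-matrix and per-trial directions.

    ``include`` is an optional n x n boolean matrix of admissible pairs
    (filters that do not depend on the direction labels).  Used by the
    permutation machinery, which relabels directions thousands of times.
    """
    th = np.asarray(directions_deg, dtype=float)
    d = np.abs(th[:, None] - th[None, :]) % 360.0
    d = np.minimum(d, 360.0 - d)
    if scheme == "mod60":
        a = (d % 60.0) == 0
        b = (d % 60.0) == 30
    elif scheme == "onefold":
        a = d <= 30
        b = d >= 60
    elif scheme == "mod90":
        a = (d % 90.0) == 0
        b = np.isin(d % 90.0, (30.0, 60.0))
    elif scheme == "cardinal":
        card = np.isin(th, (0.0, 90.0, 180.0, 270.0))
        a = card[:, None] & card[None, :]
        b = ~a
    else:
        raise ContrastError(f"unknown scheme {scheme!r}")
    iu = np.triu_indices_from(zmat, k=1)
    ok = np.isfinite(zmat)
    if include is not None:
        ok = ok & include
    am = (a & ok)[iu]
    bm = (b & ok)[iu]
    zt = zmat[iu]
    return float(zt[am].mean() - zt[bm].mean())


def residualize_distance(
    sim: pd.DataFrame,
    labels: pd.DataFrame,
    measure: str = "mean",
    binary: bool = False,
) -> pd.DataFrame:
    """Regress pairwise z on a distance measure; return residual similarity.

    One GLM per subject (per table): z ~ intercept + distance, where the
    distance is one of the three pair measures (continuous) or its
    median-split binary version.  Downstream contrasts on the residuals are
    controlled for that measure.
    """
    col = DISTANCE_COLUMNS.get(measure)
    if col is None:
        raise ContrastError(f"unknown distance measure {measure!r}")
    if len(sim) != len(labels):
        raise ContrastError("similarity and label tables must align")
    x = labels[col].to_numpy(dtype=float)
    if binary:
        med = np.median(x)
        if np.all(x == x[0]) or np.all((x > med) == (x[0] > med)):
            raise ContrastError("constant predictor: binary distance split undefined")
        x = (x > med).astype(float)
    valid = sim.valid.to_numpy()
    z = sim.z.to_numpy(dtype=float)
    X = np.column_stack([np.ones(valid.sum()), x[valid]])
    beta, *_ = np.linalg.lstsq(X, z[valid], rcond=None)
    resid = np.full_like(z, np.nan)
    resid[valid] = z[valid] - X @ beta
    out = sim.copy()
    out["z"] = resid
    out["r"] = np.nan  # residual z no longer maps back to a correlation
    return out
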