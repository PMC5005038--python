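"""Searchlight mapping of directional condition contrasts.

A sphere of 7 voxels diameter (123 voxel offsets) is centered on every
voxel of the volume; within each sphere the analysis is restricted to
gray-matter voxels and skipped unless more than 30 remain.  The sphere's
trials x voxels patterns feed the same condition contrast as the ROI
analysis, so every defined map voxel equals the ROI-level contrast of its
sphere.  Maps are NaN outside defined voxels and can be smoothed with a
4 mm FWHM Gaussian that ignores undefined voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hexdir import rsa

__all__ = ["SphereSpec", "sphere_offsets", "run_searchlight", "smooth_map"]


@dataclass(frozen=True)
class SphereSpec:
    diameter_voxels: int = 7
    min_voxels: int = 31  # "more than 30" -> strictly at least 31
    gray_restrict: bool = True

    def __post_init__(self):
        if self.diameter_voxels % 2 == 0:
            raise ValueError("sphere diameter must be odd")
        if self.min_voxels < 2:
            raise ValueError("minimum voxel count must be >= 2")


def sphere_offsets(spec: SphereSpec | int) -> np.ndarray:
    """Integer offsets with Euclidean norm <= (diameter - 1) / 2, center included."""
    d = spec.diameter_voxels if isinstance(spec, SphereSpec) else int(spec)
    if d % 2 == 0:
        raise ValueError("sphere diameter must be odd")
    r = (d - 1) // 2
    ax = np.arange(-r, r + 1)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = gx**2 + gy**2 + gz**2 <= r**2
    return np.column_stack([gx[keep], gy[keep], gz[keep]])


def run_searchlight(
    pattern_volume: np.ndarray,
    graymask: np.ndarray,
    labels: pd.DataFrame,
    contrast: rsa.ContrastSpec | None = None,
    sphere: SphereSpec | None = None,
) -> np.ndarray:
    """Voxelwise contrast map; NaN where the sphere fails the voxel-count rule.

    ``pattern_volume`` is (x, y, z, trials).  Every within-volume voxel may
    be a sphere center; sphere content is restricted to gray matter.
    """
    contrast = contrast or rsa.ContrastSpec(scheme="mod60")
    sphere = sphere or SphereSpec()
    vol = np.asarray(pattern_volume, dtype=float)
    if vol.ndim != 4:
        raise ValueError("pattern volume must be (x, y, z, trials)")
    if graymask.shape != vol.shape[:3]:
        raise ValueError("gray-matter mask does not match the volume geometry")
    offsets = sphere_offsets(sphere)
    shape = np.array(vol.shape[:3])
    out = np.full(vol.shape[:3], np.nan)
    a_mask, b_mask = rsa.condition_masks(labels, contrast.scheme)
    keep = rsa.filter_pairs(labels, contrast.filters)
    ii = labels.i.to_numpy()
    jj = labels.j.to_numpy()
    gray = graymask if sphere.gray_restrict else np.ones_like(graymask)
    for center in np.ndindex(*vol.shape[:3]):
        pts = offsets + np.array(center)
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[ok]
        inside = gray[pts[:, 0], pts[:, 1], pts[:, 2]]
        pts = pts[inside]
        if len(pts) < sphere.min_voxels:
            continue
        patterns = vol[pts[:, 0], pts[:, 1], pts[:, 2], :].T  # trials x voxels
        z, valid = rsa.similarity_matrix(patterns)
        zp = z[ii, jj]
        good = valid[ii, jj] & keep
        am = a_mask & good
        bm = b_mask & good
        if am.sum() == 0 or bm.sum() == 0:
            continue
        out[center] = zp[am].mean() - zp[bm].mean()
    return out


def smooth_map(
    contrast_map: np.ndarray, fwhm_mm: float = 4.0, voxel_mm: float = 2.0
) -> np.ndarray:
    """NaN-aware Gaussian smoothing; sigma = FWHM / (2 * sqrt(2 ln 2)).

    Undefined (NaN) voxels neither contribute nor receive values; the
    kernel is renormalised over the defined support.
    """
    from scipy.ndimage import gaussian_filter

    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return contrast_map.copy()
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_mm
    defined = np.isfinite(contrast_map)
    filled = np.where(defined, contrast_map, 0.0)
    num = gaussian_filter(filled, sigma_vox)
    den = gaussian_filter(defined.astype(float), sigma_vox)
    out = np.full_like(contrast_map, np.nan, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out[defined] = num[defined] / den[defined]
    return out
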