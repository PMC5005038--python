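"""Behavioral error statistics, chance testing and design-control analyses.

Performance on the direction-imagination task is the absolute wrapped
angular difference between the correct and the indicated direction, in
[0, 180] degrees.  A uniform-random responder's errors are uniform on that
interval, so chance level is a median error of 90 degrees; subjects whose
median error is not significantly below 90 (one-sided Wilcoxon signed-rank)
are excluded.  The behavioral 60-degree-modulation control multiplies the
errors of the two trials in every pair and contrasts the 0-mod-60 against
the 30-mod-60 condition, mirroring the pattern-similarity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "angular_error",
    "chance_performance_test",
    "combined_error_contrast",
    "accuracy_correlations",
    "map_test_score",
    "image_features",
    "image_feature_similarity",
    "visual_similarity_tests",
    "make_view_image",
]


def angular_error(true_deg, response_deg):
    """Absolute wrapped angular difference in degrees, in [0, 180]."""
    d = np.abs(np.asarray(true_deg, dtype=float) - np.asarray(response_deg, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


@dataclass(frozen=True)
class ChanceTestResult:
    median_error_deg: float
    p_value: float
    below_chance: bool  # True -> performs above chance level, keep subject
    degenerate: bool = False


def chance_performance_test(errors, alpha: float = 0.05) -> ChanceTestResult:
    """One-sided Wilcoxon signed-rank of errors against the 90-degree chance level.

    ``below_chance`` is True when the subject's errors are significantly
    smaller than 90 degrees (subject is retained); a non-significant result
    marks a chance-level performer.
    """
    e = np.asarray(errors, dtype=float)
    if len(e) < 6:
        raise ValueError("need at least 6 errors for the chance test")
    diffs = e - 90.0
    if np.all(diffs == 0):
        return ChanceTestResult(float(np.median(e)), 1.0, False, degenerate=True)
    stat = stats.wilcoxon(diffs, alternative="less")
    return ChanceTestResult(
        median_error_deg=float(np.median(e)),
        p_value=float(stat.pvalue),
        below_chance=bool(stat.pvalue < alpha),
    )


def combined_error_contrast(errors, labels: pd.DataFrame) -> float:
    """Mean product-of-errors difference, 0-mod-60 minus 30-mod-60 condition.

    The two trials' absolute errors are multiplied per pair; pairs with a
    missing (NaN) response are dropped.
    """
    e = np.asarray(errors, dtype=float)
    i = labels.i.to_numpy()
    j = labels.j.to_numpy()
    prod = e[i] * e[j]
    ok = np.isfinite(prod)
    a = (labels.rem60.to_numpy() == 0) & ok
    b = (labels.rem60.to_numpy() == 30) & ok
    return float(prod[a].mean() - prod[b].mean())


def accuracy_correlations(
    subjects: pd.DataFrame, control: str | None = "training_time"
) -> pd.DataFrame:
    """Correlate imagination accuracy with training/map-test performance.

    ``subjects`` needs a ``mean_error_deg`` column plus covariate columns
    (e.g. ``buildings_found``, ``training_error_deg``, ``map_score_z``).
    Accuracy is pi minus the mean angular error in radians, so a perfect
    performer scores pi and a chance performer about pi/2.  Reports Pearson
    r per covariate and, when ``control`` names a column, the partial
    correlation holding it fixed.
    """
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects")
    acc = np.pi - np.deg2rad(subjects.mean_error_deg.to_numpy(dtype=float))
    rows = []
    skip = {"mean_error_deg", control}
    for col in subjects.columns:
        if col in skip or not np.issubdtype(subjects[col].dtype, np.number):
            continue
        x = subjects[col].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise ValueError(f"zero-variance covariate {col!r}")
        r, p = stats.pearsonr(acc, x)
        row = {"covariate": col, "r": r, "p": p}
        if control is not None and control in subjects.columns:
            c = subjects[control].to_numpy(dtype=float)
            if np.std(c) == 0:
                raise ValueError(f"zero-variance covariate {control!r}")
            row["partial_r"], row["partial_p"] = _partial_corr(acc, x, c)
        rows.append(row)
    return pd.DataFrame(rows)


def _partial_corr(a, b, c):
    """Pearson correlation of a and b after regressing out c from both."""
    def resid(y):
        X = np.column_stack([np.ones_like(c), c])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return y - X @ beta
    return stats.pearsonr(resid(np.asarray(a, float)), resid(np.asarray(b, float)))


def map_test_score(true_xy, placed_xy) -> np.ndarray:
    """Euclidean distance between correct and indicated map locations."""
    t = np.atleast_2d(np.asarray(true_xy, dtype=float))
    p = np.atleast_2d(np.asarray(placed_xy, dtype=float))
    return np.linalg.norm(t - p, axis=1)


# --------------------------------------------------------------------------
# Visual-similarity control on rendered views

FEATURE_NAMES = ("fft_magnitude", "fft_phase", "L", "a", "b")


def make_view_image(
    start_xy, direction_deg: float, size: tuple[int, int] = (48, 64), seed: int = 0
) -> np.ndarray:
    """Procedural stand-in for a rendered city view (synthetic; no VR assets).

    A sky/ground gradient plus building-like rectangles whose placement and
    hue depend deterministically on the viewpoint and facing direction, so
    views from nearby directions share visual statistics the way rendered
    scenes would.  Returns an RGB float array in [0, 1].
    """
    h, w = size
    rng = np.random.default_rng(
        seed + int(1000 * (start_xy[0] + 10)) * 7919 + int(direction_deg) * 104729
    )
    img = np.zeros((h, w, 3))
    sky = np.linspace(0.9, 0.4, h)[:, None]
    img[..., 2] = sky
    img[..., 1] = 0.5 * sky
    horizon = h // 2
    img[horizon:, :, 1] += 0.3
    for _ in range(4):
        bw = rng.integers(6, 14)
        bh = rng.integers(8, horizon)
        x0 = int((direction_deg / 360.0) * w + rng.integers(0, w)) % max(w - bw, 1)
        color = rng.uniform(0.2, 0.8, size=3)
        img[horizon - bh : horizon, x0 : x0 + bw] = color
    return np.clip(img, 0.0, 1.0)


def image_features(image: np.ndarray) -> dict[str, np.ndarray]:
    """Five vectorised statistics per image: 2-D FFT magnitude and phase of
    the luminance, and the CIELAB L, a, b channels (D65 white point)."""
    from skimage.color import rgb2lab

    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    lab = rgb2lab(image)
    fft = np.fft.fft2(lab[..., 0])
    return {
        "fft_magnitude": np.abs(fft).ravel(),
        "fft_phase": np.angle(fft).ravel(),
        "L": lab[..., 0].ravel(),
        "a": lab[..., 1].ravel(),
        "b": lab[..., 2].ravel(),
    }


def image_feature_similarity(images: list[np.ndarray]) -> pd.DataFrame:
    """Pairwise Fisher-z Pearson correlation per feature dimension.

    Constant dimensions (e.g. the a/b channels of a grayscale set) are
    flagged NaN rather than producing spurious correlations.
    """
    if len({im.shape for im in images}) > 1:
        raise ValueError("all images must share dimensions")
    feats = [image_features(im) for im in images]
    rows = []
    for i in range(len(images)):
        for j in range(i + 1, len(images)):
            row = {"i": i, "j": j}
            for name in FEATURE_NAMES:
                x, y = feats[i][name], feats[j][name]
                if np.std(x) == 0 or np.std(y) == 0:
                    row[name] = np.nan
                else:
                    r = np.corrcoef(x, y)[0, 1]
                    row[name] = float(np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)))
            rows.append(row)
    return pd.DataFrame(rows)


def visual_similarity_tests(
    feature_z: pd.DataFrame,
    labels: pd.DataFrame,
    n_comparisons: int = 24,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sample t per feature dimension: similar-direction pairs (Delta <=
    30, different start) against dissimilar pairs (Delta >= 60), Bonferroni
    corrected over ``n_comparisons``.  A dimension is reported
    ``lower_for_similar`` when similar-direction views are significantly
    *less* correlated."""
    merged = feature_z.merge(labels, on=("i", "j"))
    sim = (merged.delta_deg <= 30) & ~merged.same_start
    dis = merged.delta_deg >= 60
    if sim.sum() == 0 or dis.sum() == 0:
        raise ValueError("similar or dissimilar pair group is empty")
    rows = []
    for name in FEATURE_NAMES:
        a = merged.loc[sim, name].dropna()
        b = merged.loc[dis, name].dropna()
        if len(a) == 0 or len(b) == 0:
            rows.append({"dimension": name, "t": np.nan, "p_corrected": np.nan,
                         "lower_for_similar": False, "defined": False})
            continue
        t, p = stats.ttest_ind(a, b, equal_var=True)
        p_corr = min(1.0, p * n_comparisons)
        rows.append(
            {
                "dimension": name,
                "t": float(t),
                "p_corrected": float(p_corr),
                "lower_for_similar": bool(t < 0 and p_corr < alpha),
                "defined": True,
            }
        )
    return pd.DataFrame(rows)
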