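"""Synthetic voxel patterns, 4-D time series and behavior with planted tuning.

The generator emulates the study conditions: 24 subjects, each with an
independent 96-trial counterbalanced design over the hexagonal building
layout, voxel populations with either grid-like (60-degree periodic),
head-direction-like (one-fold von Mises) or null direction tuning, and
von-Mises behavioral responses with a uniform lapse component.

Signal models
-------------
grid   x[t, v] = b_v + A_v * cos(6 * (theta_t - psi)) + eps
       Shared grid orientation psi per subject/region, per-voxel random
       amplitudes A_v (may be negative) -- the minimal population model
       giving a 60-degree periodic pattern-similarity structure.  Because
       the twelve sampled directions are 30 degrees apart, the sixth
       harmonic is sampled at exactly two phases: all 0-mod-60 pairs share
       the phase, all 30-mod-60 pairs are in antiphase.
hd     x[t, v] = b_v + g * exp(kappa * cos(theta_t - mu_v)) / I0-norm + eps
       Per-voxel preferred directions mu_v, yielding one-fold similarity.
null   x[t, v] = b_v + eps

The default grid amplitude is calibrated so a default 24-subject cohort
lands near a group effect size of d ~= 0.6 on the mod-60 contrast (see
docs/methods.md for the calibration rationale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hexdir import city
from hexdir.behavior import angular_error

__all__ = [
    "SignalModel",
    "VolumeGeometry",
    "AcquisitionParams",
    "CohortSpec",
    "SubjectData",
    "default_geometry",
    "simulate_trial_patterns",
    "embed_timeseries",
    "simulate_behavior",
    "simulate_cohort",
    "canonical_hrf",
]

#: grid amplitude spread giving a cohort mod-60 effect size near d ~= 0.6
#: with the default 1.0 baseline spread and 1.0 trial noise (see methods)
DEFAULT_GRID_AMP_SD = 0.06

#: behavioral concentration/lapse calibrated to a ~34-degree mean error
DEFAULT_KAPPA = 2.8
DEFAULT_LAPSE = 0.1


@dataclass(frozen=True)
class SignalModel:
    """Direction tuning of a simulated voxel population."""

    kind: str = "null"  # grid | hd | null | mixture
    grid_orientation_deg: float | None = None  # psi in [0, 60); None -> drawn
    grid_amp_sd: float = DEFAULT_GRID_AMP_SD
    baseline_sd: float = 1.0
    noise_sd: float = 1.0
    hd_kappa: float = 2.0
    hd_gain: float = 1.0
    mixture_weights: tuple[float, float] = (0.5, 0.5)  # (grid, hd)

    def __post_init__(self):
        if self.kind not in ("grid", "hd", "null", "mixture"):
            raise ValueError(f"unknown signal kind {self.kind!r}")
        if self.noise_sd < 0 or self.hd_kappa < 0:
            raise ValueError("noise_sd and hd_kappa must be non-negative")
        if self.grid_orientation_deg is not None and not (
            0 <= self.grid_orientation_deg < 60
        ):
            raise ValueError("grid orientation must lie in [0, 60)")


@dataclass(frozen=True)
class AcquisitionParams:
    """Timing and nuisance structure of the simulated acquisition."""

    tr_s: float = 1.8
    drift_amplitude: float = 0.0
    drift_period_s: float = 128.0
    ar_coef: float = 0.0
    noise_sd: float = 0.0
    motion_sd: float = 0.0          # step size of the random-walk motion traces
    motion_loading_sd: float = 0.0  # per-voxel loading on the motion traces

    def __post_init__(self):
        if self.tr_s <= 0:
            raise ValueError("TR must be positive")


@dataclass(frozen=True)
class VolumeGeometry:
    """3-D array geometry with named binary masks (2 mm isotropic voxels)."""

    shape: tuple[int, int, int]
    voxel_size_mm: float = 2.0
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for name, m in self.masks.items():
            if m.shape != self.shape:
                raise ValueError(f"mask {name!r} does not fit the volume shape")

    def n_voxels(self, name: str) -> int:
        return int(self.masks[name].sum())


def default_geometry(shape: tuple[int, int, int] = (20, 20, 14)) -> VolumeGeometry:
    """Small stand-in geometry with ROI-like boxes and a gray-matter mask.

    Synthetic plumbing: left/right pmEC-like and alEC-like boxes (~48
    voxels each) plus a parahippocampal-like slab, all inside a gray-matter
    envelope.
    """
    def box(x, y, z):
        m = np.zeros(shape, dtype=bool)
        m[x[0]:x[1], y[0]:y[1], z[0]:z[1]] = True
        return m

    masks = {
        "pmEC-left": box((3, 6), (4, 8), (3, 7)),
        "pmEC-right": box((14, 17), (4, 8), (3, 7)),
        "alEC-left": box((3, 6), (10, 14), (3, 7)),
        "alEC-right": box((14, 17), (10, 14), (3, 7)),
        "PHG-like": box((7, 13), (4, 12), (3, 7)),
    }
    gray = box((2, 18), (2, 16), (2, 9))
    masks["gray-matter"] = gray | np.any([m for m in masks.values()], axis=0)
    return VolumeGeometry(shape=shape, masks=masks)


def simulate_trial_patterns(
    trials: pd.DataFrame,
    model: SignalModel,
    n_voxels: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """trials x voxels activity matrix with the model's planted tuning."""
    if n_voxels < 2:
        raise ValueError("need at least 2 voxels (correlation undefined otherwise)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    th = np.deg2rad(trials.direction_deg.to_numpy(dtype=float))
    n = len(th)
    baseline = rng.normal(0.0, model.baseline_sd, size=n_voxels)
    x = np.tile(baseline, (n, 1))

    def grid_part():
        psi = model.grid_orientation_deg
        if psi is None:
            psi = rng.uniform(0.0, 60.0)
        amp = rng.normal(0.0, model.grid_amp_sd, size=n_voxels)
        return np.cos(6.0 * (th - np.deg2rad(psi)))[:, None] * amp[None, :]

    def hd_part():
        mu = rng.uniform(0.0, 2 * np.pi, size=n_voxels)
        tuning = np.exp(model.hd_kappa * np.cos(th[:, None] - mu[None, :]))
        from scipy.special import i0
        return model.hd_gain * tuning / i0(model.hd_kappa)

    if model.kind == "grid":
        x = x + grid_part()
    elif model.kind == "hd":
        x = x + hd_part()
    elif model.kind == "mixture":
        wg, wh = model.mixture_weights
        x = x + wg * grid_part() + wh * hd_part()
    if model.noise_sd > 0:
        x = x + rng.normal(0.0, model.noise_sd, size=x.shape)
    return x


def canonical_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic response (peak ~5 s, undershoot ~15 s)."""
    from scipy.stats import gamma
    h = gamma.pdf(t, a=6, scale=1.0) - gamma.pdf(t, a=16, scale=1.0) / 6.0
    peak = gamma.pdf(5.0, a=6, scale=1.0) - gamma.pdf(5.0, a=16, scale=1.0) / 6.0
    return h / peak


def trial_regressors(
    trials: pd.DataFrame, n_vols: int, tr_s: float, dt: float = 0.1
) -> np.ndarray:
    """Per-trial imagination-period boxcars convolved with the canonical HRF,
    sampled at volume acquisition times.  Returns trials x volumes."""
    t_fine = np.arange(0.0, n_vols * tr_s + 32.0, dt)
    hrf = canonical_hrf(np.arange(0.0, 32.0, dt))
    out = np.zeros((len(trials), n_vols))
    vol_idx = np.round(np.arange(n_vols) * tr_s / dt).astype(int)
    for k, tr in enumerate(trials.itertuples(index=False)):
        onset = tr.cue_onset_s
        box = ((t_fine >= onset) & (t_fine < tr.imagination_end_s)).astype(float)
        conv = np.convolve(box, hrf)[: len(t_fine)] * dt
        out[k] = conv[vol_idx]
    return out


def embed_timeseries(
    patterns: np.ndarray,
    trials: pd.DataFrame,
    geometry: VolumeGeometry,
    roi: str,
    acquisition: AcquisitionParams | None = None,
    seed: int | np.random.Generator = 0,
    n_vols: int | None = None,
):
    """Inject trial patterns into a 4-D volume for one run; emit motion table.

    Each trial's pattern modulates its ROI voxels through an imagination
    boxcar convolved with the canonical HRF.  Optional AR(1) noise, cosine
    drift and motion-loading confounds are added to every gray-matter voxel;
    the six motion time courses are returned for the nuisance GLM.  Returns
    ``(nibabel image, motion DataFrame)`` with the TR recorded in the header.
    """
    import nibabel as nib

    acq = acquisition or AcquisitionParams()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mask = geometry.masks.get(roi)
    if mask is None or not mask.any():
        raise ValueError(f"ROI mask {roi!r} missing or empty")
    n_roi = int(mask.sum())
    if patterns.shape != (len(trials), n_roi):
        raise ValueError("patterns must be trials x (ROI voxel count)")
    if n_vols is None:
        n_vols = int(np.ceil((trials.imagination_end_s.max() + 16.0) / acq.tr_s))
    if trials.imagination_end_s.max() + 2 * acq.tr_s > n_vols * acq.tr_s:
        raise ValueError("trial windows exceed the generated run length")

    reg = trial_regressors(trials, n_vols, acq.tr_s)  # trials x vols
    data = np.zeros(geometry.shape + (n_vols,), dtype=float)
    data[mask] = (reg.T @ patterns).T  # voxels x vols

    gray = geometry.masks.get("gray-matter", np.ones(geometry.shape, bool))
    n_gray = int(gray.sum())
    tvec = np.arange(n_vols) * acq.tr_s
    if acq.noise_sd > 0:
        eps = rng.normal(0.0, acq.noise_sd, size=(n_gray, n_vols))
        if acq.ar_coef != 0.0:
            for k in range(1, n_vols):
                eps[:, k] += acq.ar_coef * eps[:, k - 1]
        data[gray] += eps
    if acq.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi, size=n_gray)
        drift = acq.drift_amplitude * np.cos(
            2 * np.pi * tvec[None, :] / acq.drift_period_s + phase[:, None]
        )
        data[gray] += drift

    motion = rng.normal(0.0, max(acq.motion_sd, 1e-12), size=(n_vols, 6)).cumsum(axis=0)
    if acq.motion_sd > 0 and acq.motion_loading_sd > 0:
        load = rng.normal(0.0, acq.motion_loading_sd, size=(n_gray, 6))
        data[gray] += load @ motion.T

    affine = np.diag([geometry.voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((geometry.voxel_size_mm,) * 3 + (acq.tr_s,))
    motion_df = pd.DataFrame(motion, columns=[f"mot{k}" for k in range(1, 7)])
    return img, motion_df


def simulate_behavior(
    trials: pd.DataFrame,
    kappa: float = DEFAULT_KAPPA,
    lapse: float = DEFAULT_LAPSE,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Von-Mises responses around the true direction with a uniform lapse.

    With probability ``1 - lapse`` the response is drawn von Mises
    (concentration kappa) around the trial's direction, otherwise uniformly;
    a pure-lapse responder's absolute wrapped errors are uniform on
    [0, 180] with median 90 degrees -- the chance criterion.
    """
    if kappa < 0 or not (0 <= lapse <= 1):
        raise ValueError("kappa must be >= 0 and lapse in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    th = trials.direction_deg.to_numpy(dtype=float)
    n = len(th)
    vm = np.rad2deg(rng.vonmises(0.0, kappa if kappa > 0 else 1e-9, size=n))
    unif = rng.uniform(0.0, 360.0, size=n)
    lapsed = rng.uniform(size=n) < lapse
    resp = np.where(lapsed, unif, (th + vm) % 360.0)
    return pd.DataFrame(
        {
            "trial_id": trials.trial_id.to_numpy(),
            "direction_deg": th,
            "response_deg": resp,
            "error_deg": angular_error(th, resp),
            "confidence": rng.integers(1, 5, size=n),
        }
    )


@dataclass(frozen=True)
class CohortSpec:
    """A multi-subject synthetic cohort: which regions get which signal."""

    n_subjects: int = 24
    base_seed: int = 0
    region_models: dict[str, SignalModel] = field(
        default_factory=lambda: {"pmEC-left": SignalModel(kind="grid")}
    )
    region_voxels: dict[str, int] = field(default_factory=dict)
    default_voxels: int = 48
    behavior_kappa: float = DEFAULT_KAPPA
    behavior_lapse: float = DEFAULT_LAPSE


@dataclass
class SubjectData:
    subject: int
    trials: pd.DataFrame
    patterns: dict[str, np.ndarray]
    behavior: pd.DataFrame
    seeds: dict[str, int]


def simulate_cohort(
    spec: CohortSpec,
    layout: city.CityLayout | None = None,
    combinations: pd.DataFrame | None = None,
) -> list[SubjectData]:
    """Independent design realisation, patterns and behavior per subject.

    Each subject draws its own exclusion and trial-order seeds, its own grid
    orientation psi per region, and its own noise; seeds are spawned
    deterministically from ``spec.base_seed`` and recorded per subject.
    """
    layout = layout or city.build_city_layout()
    combinations = (
        enumerate_cached(layout) if combinations is None else combinations
    )
    ss = np.random.SeedSequence(spec.base_seed)
    children = ss.spawn(max(spec.n_subjects, 1))
    subjects = []
    seen: set[int] = set()
    for s in range(spec.n_subjects):
        sub_ss = children[s]
        key = int(sub_ss.generate_state(1)[0])
        if key in seen:
            raise ValueError("duplicate subject seeds")
        seen.add(key)
        rng = np.random.default_rng(sub_ss)
        combos48 = city.apply_exclusions(combinations, rng)
        trials = city.generate_design(combos48, seed=rng)
        patterns = {}
        for region, model in spec.region_models.items():
            nv = spec.region_voxels.get(region, spec.default_voxels)
            patterns[region] = simulate_trial_patterns(trials, model, nv, seed=rng)
        behavior = simulate_behavior(
            trials, kappa=spec.behavior_kappa, lapse=spec.behavior_lapse, seed=rng
        )
        subjects.append(
            SubjectData(
                subject=s + 1,
                trials=trials,
                patterns=patterns,
                behavior=behavior,
                seeds={"subject_entropy": key},
            )
        )
    return subjects


_COMBO_CACHE: dict[int, pd.DataFrame] = {}


def enumerate_cached(layout: city.CityLayout) -> pd.DataFrame:
    """Combination enumeration memoised on the layout object identity."""
    key = id(layout)
    if key not in _COMBO_CACHE:
        _COMBO_CACHE.clear()
        _COMBO_CACHE[key] = city.enumerate_combinations(layout)
    return _COMBO_CACHE[key]
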