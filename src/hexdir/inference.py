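"""Subject- and group-level inference, plus the simulation harness.

Subject level: the trial -> direction assignment is shuffled (10,000
permutations by default), the pair conditions are re-derived from the
permuted labels and the contrast recomputed, giving an add-one permutation
p-value p = (1 + #{perm >= observed}) / (n_perm + 1); p is converted to a
signed z-statistic via the inverse normal of 1 - p.

Group level: a one-sample T-test of the subject contrasts against zero
(df = n - 1), optionally one-tailed and Bonferroni-corrected over k
region comparisons, or its non-parametric sign-flipping analogue.
Small-volume corrections over a mask use Bonferroni over mask voxels or a
max-statistic permutation -- random-field corrections are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from hexdir import city, rsa
from hexdir.cohort import CohortSpec, SignalModel, SubjectData, simulate_cohort

__all__ = [
    "PermutationResult",
    "GroupResult",
    "permutation_test_subject",
    "group_one_sample_t",
    "group_permutation_t",
    "subject_contrast",
    "cohort_contrasts",
    "CalibrationConfig",
    "calibration_experiment",
]


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    n_perm: int
    p: float
    z: float


@dataclass(frozen=True)
class GroupResult:
    t: float
    df: int
    p: float
    tail: str
    correction: str = "none"


def permutation_test_subject(
    zmat: np.ndarray,
    directions_deg: np.ndarray,
    scheme: str = "mod60",
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    include: np.ndarray | None = None,
) -> PermutationResult:
    """Permutation test of a condition contrast within one subject.

    ``zmat`` is the n x n Fisher-z similarity matrix and ``directions_deg``
    the per-trial direction labels; each permutation shuffles the labels
    across trials and recomputes the contrast from the relabelled pair
    structure.  ``include`` optionally restricts to pairs admissible under
    direction-independent exclusion filters.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    th = np.asarray(directions_deg, dtype=float)
    uniq, inv = np.unique(th, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("degenerate labels: only one direction present")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    # pair conditions depend only on the two trials' direction values, so a
    # k x k class matrix over unique directions makes each permutation a
    # cheap table lookup instead of a full relabelling
    a_cls, b_cls = _pair_class_matrices(uniq, scheme)
    n = zmat.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    ok = np.isfinite(zmat[ii, jj])
    if include is not None:
        ok &= include[ii, jj]
    ii, jj = ii[ok], jj[ok]
    z = zmat[ii, jj]

    def stat(idx):
        ai, bi = a_cls[idx[ii], idx[jj]], b_cls[idx[ii], idx[jj]]
        na, nb = ai.sum(), bi.sum()
        if na == 0 or nb == 0:
            return -np.inf
        return (z @ ai) / na - (z @ bi) / nb

    observed = float(stat(inv))
    count = 0
    for _ in range(n_perm):
        if stat(rng.permutation(inv)) >= observed:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return PermutationResult(observed=observed, n_perm=n_perm, p=p, z=float(stats.norm.isf(p)))


def _pair_class_matrices(uniq_dirs: np.ndarray, scheme: str):
    """Condition-A/B membership for every ordered pair of unique directions."""
    d = np.abs(uniq_dirs[:, None] - uniq_dirs[None, :]) % 360.0
    d = np.minimum(d, 360.0 - d)
    if scheme == "mod60":
        a, b = (d % 60.0) == 0, (d % 60.0) == 30
    elif scheme == "onefold":
        a, b = d <= 30, d >= 60
    elif scheme == "mod90":
        a, b = (d % 90.0) == 0, np.isin(d % 90.0, (30.0, 60.0))
    elif scheme == "cardinal":
        card = np.isin(uniq_dirs, (0.0, 90.0, 180.0, 270.0))
        a = card[:, None] & card[None, :]
        b = ~a
    else:
        raise rsa.ContrastError(f"unknown scheme {scheme!r}")
    return a.astype(float), b.astype(float)


def group_one_sample_t(
    values, tail: str = "one", correction_k: int = 1
) -> GroupResult:
    """One-sample T-test of subject values against zero (df = n - 1)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 subjects")
    if v.std(ddof=1) == 0:
        raise ValueError("zero variance across subjects")
    t, p_two = stats.ttest_1samp(v, 0.0)
    p = p_two / 2.0 if tail == "one" else p_two
    if tail == "one" and t < 0:
        p = 1.0 - p_two / 2.0
    p = min(1.0, p * correction_k)
    corr = "none" if correction_k == 1 else f"bonferroni x{correction_k}"
    return GroupResult(t=float(t), df=len(v) - 1, p=float(p), tail=tail, correction=corr)


def group_permutation_t(
    values, n_perm: int = 10_000, seed: int | np.random.Generator = 0, tail: str = "one"
) -> GroupResult:
    """Sign-flipping permutation null of the one-sample t statistic.

    With n subjects only 2**n distinct sign patterns exist, which bounds the
    attainable p-value resolution for small cohorts.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sd = v.std(ddof=1)
    if sd == 0:
        # all-equal values: every sign flip is as extreme; p = 1 by convention
        return GroupResult(t=0.0 if v[0] == 0 else np.inf, df=len(v) - 1, p=1.0, tail=tail)

    def tstat(x):
        s = x.std(ddof=1)
        return 0.0 if s == 0 else x.mean() / (s / np.sqrt(len(x)))

    obs = tstat(v)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, len(v)))
    perm_t = np.array([tstat(v * f) for f in flips])
    if tail == "one":
        count = int((perm_t >= obs).sum())
    else:
        count = int((np.abs(perm_t) >= abs(obs)).sum())
    p = (1.0 + count) / (n_perm + 1.0)
    return GroupResult(t=float(obs), df=len(v) - 1, p=float(p), tail=tail)


# --------------------------------------------------------------------------
# Cohort-level harness

def subject_contrast(
    subject: SubjectData, region: str, scheme: str = "mod60"
) -> float:
    """Condition contrast of one subject's region patterns."""
    zmat, _ = rsa.similarity_matrix(subject.patterns[region])
    th = subject.trials.direction_deg.to_numpy(dtype=float)
    return rsa.contrast_from_z(zmat, th, scheme)


def cohort_contrasts(
    subjects: list[SubjectData], regions: list[str] | None = None, scheme: str = "mod60"
) -> pd.DataFrame:
    """Subjects x regions table of condition contrasts."""
    regions = regions or sorted(subjects[0].patterns)
    rows = []
    for s in subjects:
        row = {"subject": s.subject}
        for region in regions:
            row[region] = subject_contrast(s, region, scheme)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CalibrationConfig:
    """Repeated-cohort simulation for rejection-rate estimation."""

    signal_kind: str = "null"  # null | grid | hd
    grid_amp_sd: float | None = None  # None -> SignalModel default
    n_subjects: int = 24
    n_cohorts: int = 50
    alpha: float = 0.05
    tail: str = "one"
    correction_k: int = 1
    scheme: str = "mod60"
    n_voxels: int = 48
    base_seed: int = 0
    signal_region: str = "pmEC-left"
    null_region: str = "alEC-left"


def calibration_experiment(config: CalibrationConfig) -> pd.DataFrame:
    """Run cohorts end to end and tabulate group-test rejection rates.

    Each cohort simulates ``n_subjects`` subjects (independent designs,
    planted signal in ``signal_region`` according to ``signal_kind``, null
    in ``null_region``), computes the per-subject condition contrast and the
    group one-sample T-test per region, and records whether it rejects at
    ``alpha`` (after Bonferroni correction by ``correction_k`` in the signal
    region only).
    """
    layout = city.build_city_layout()
    model_kwargs = {}
    if config.grid_amp_sd is not None:
        model_kwargs["grid_amp_sd"] = config.grid_amp_sd
    signal_model = (
        SignalModel(kind="null")
        if config.signal_kind == "null"
        else SignalModel(kind=config.signal_kind, **model_kwargs)
    )
    rows = []
    for c in range(config.n_cohorts):
        spec = CohortSpec(
            n_subjects=config.n_subjects,
            base_seed=config.base_seed + c,
            region_models={
                config.signal_region: signal_model,
                config.null_region: SignalModel(kind="null"),
            },
            default_voxels=config.n_voxels,
        )
        subjects = simulate_cohort(spec, layout=layout)
        table = cohort_contrasts(subjects, scheme=config.scheme)
        row = {"cohort": c}
        for region in (config.signal_region, config.null_region):
            k = config.correction_k if region == config.signal_region else 1
            res = group_one_sample_t(table[region], tail=config.tail, correction_k=k)
            row[f"{region}_t"] = res.t
            row[f"{region}_p"] = res.p
            row[f"{region}_reject"] = res.p < config.alpha
            row[f"{region}_contrast_mean"] = float(table[region].mean())
            row[f"{region}_cohens_d"] = float(
                table[region].mean() / table[region].std(ddof=1)
            )
        rows.append(row)
    return pd.DataFrame(rows)
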