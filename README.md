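# hexdir

Searchlight RSA pipeline for detecting **directional codes in imagined
navigation**: one-fold (head-direction-like) and six-fold (grid-cell-like,
60°-periodic) structure in multi-voxel fMRI pattern similarity, with a
fully synthetic task and cohort generator so every stage is verifiable
end to end without real data.

## The problem

Grid cells fire on a hexagonal lattice, so the population signal they
contribute to an aggregate measure is 60°-periodic in (imagined) heading.
In a task where subjects imagine the direction between pairs of buildings
— 18 buildings on a triangular-lattice hexagon, sampling twelve directions
30° apart from six inner start locations — that periodicity predicts a
specific pattern-similarity structure: trial pairs whose imagined
directions differ by a multiple of 60° (Δ mod 60 = 0) should show higher
pattern similarity than pairs differing by 30° mod 60.  A head-direction-
like code predicts instead higher similarity for pairs at most 30° apart
than for pairs 60° or more apart.  For each subject, pattern similarity is
the Fisher-z Pearson correlation over voxels for all C(96,2) = 4560 trial
pairs, the statistic is the difference of condition means

    ΔZ = mean z(Δ mod 60 = 0) − mean z(Δ mod 60 = 30),

and the group test is a one-tailed one-sample T (df = n−1) against zero,
with subject-level label-shuffling permutation tests (10,000 shuffles) and
sign-flip group permutation as non-parametric counterparts.  The package
implements the full chain — design generation, nuisance-GLM
residualisation, 3-volume window extraction, pairwise similarity, the
four condition contrasts with all exclusion filters and distance controls,
the 7-voxel searchlight, and permutation inference — plus a synthetic
cohort generator that plants grid-like, head-direction-like or null voxel
tuning in ROI-like masks.

## Worked example

```python
from hexdir import city, rsa, inference
from hexdir.cohort import CohortSpec, SignalModel, simulate_cohort

spec = CohortSpec(
    n_subjects=24, base_seed=7,
    region_models={"pmEC-left": SignalModel(kind="grid"),   # 60-deg periodic
                   "alEC-left": SignalModel(kind="null")},  # control region
)
subjects = simulate_cohort(spec)
table = inference.cohort_contrasts(subjects, scheme="mod60")
for region in ("pmEC-left", "alEC-left"):
    res = inference.group_one_sample_t(table[region], tail="one", correction_k=2)
    print(f"{region}: T({res.df}) = {res.t:.2f}, p = {res.p:.4f}")
```

prints (seed 7):

```
pmEC-left: T(23) = 4.00, p = 0.0006
alEC-left: T(23) = -0.53, p = 1.0000
```

The grid-tuned region shows the 60° modulation (one-tailed p, Bonferroni-
corrected for two regions); the null region does not.  The numbered
scripts under `analysis/` walk the full study: `01_generate_design.py`
(the hexagonal layout, the 60 → 48 combination exclusion and the 96-trial
counterbalanced design; it prints the 12.23 % inner-ring pair fraction),
`02_simulate_cohort.py`, `03_directional_rsa.py` (contrasts, exclusion
filters, distance controls, group stats), `04_searchlight_demo.py`
(embedded 4-D run, extraction chain and contrast map),
`05_inference_calibration.py` and `06_behavior_controls.py` (chance-level
exclusion, behavioral mod-60 test, accuracy correlations, visual-
similarity control).  A `hexdir` CLI exposes design generation/validation
and the config-driven pipeline (`hexdir design generate --seed 3 --out d/`,
`hexdir pipeline --config cfg.json`).

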