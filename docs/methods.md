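# Methods

`hexdir` implements a representational-similarity (RSA) pipeline for
detecting directional codes in multi-voxel activity patterns recorded
while subjects *imagine* directions between known locations, together with
a synthetic task/cohort generator that makes every stage verifiable
without real data.  This note documents the model, the parameters that
matter, the numerical conventions, and what the synthetic verification
does and does not show.

## Task geometry and design

The imagined-direction task samples twelve directions, 30° apart, between
18 buildings whose entrances sit on the vertices of equilateral triangles
arranged in a hexagon: a side-2 triangular-lattice hexagon with the center
point excluded.  Six buildings at unit radius (on the 0°, 60°, …, 300°
axes) are the start locations; six more lie at radius 2 on the same axes
and six at radius √3 on the 30°-offset axes.  Coordinates are in lattice
units with north along +y; a `scale` factor converts to meters but is
never needed because all distance controls are scale-invariant after GLM
standardisation.

From each start, a direction is *sampled* if some other building lies on
an exact multiple-of-30° ray.  When both an inner and an outer building
lie on the same ray (the 120°, 180° and 240° rays relative to the start's
own axis), the outer building is the target.  This outer-preference rule
is what confines inner-ring targets to the 30°-offset directions, and it
is the unique rule consistent with the pair-structure fact checked in the
tests: both-inner-target pairs are 12.23 % of the 0-mod-60 condition and
absent from the 30-mod-60 condition.  Each start reaches 10 of the 12
directions (it misses the two offset directions adjacent to its own
outward axis), giving 60 combinations: 6 × 6 main-axis and 4 × 6 offset.

Because the six main-axis directions are oversampled (6 starts each), two
of their combinations are excluded per direction under the constraint of
exactly two exclusions per start.  The solver draws two disjoint random
bijections from directions to starts, which satisfies both marginals by
construction.  The remaining 48 combinations sample every direction four
times.  A design consists of four 24-trial blocks; blocks 1–2 use each
combination once (as do blocks 3–4, so every combination occurs exactly
twice), and within every block each direction appears twice and each start
four times.  The block split is found by randomised depth-first search
over directions with a 4-per-start cap; with 24 picks over 6 starts the
cap forces exactly 4 each.  Three trials per block are catch trials
(never the first trial; 50 % correct-view overall); they keep their normal
direction labels and stay in the RSA.

Trial timing: 2 s cue, 10 s imagination, then response (4 s), confidence
(2 s), a 2 s probe on catch trials, and an ITI drawn from {1.8, 3.6,
5.4} s.  One fMRI run per block; onsets restart per run.

### Pair structure

All C(96, 2) = 4560 unordered trial pairs are labelled with the wrapped
angular difference Δ ∈ {0, 30, …, 180}, its remainders mod 60 (∈ {0, 30})
and mod 90 (∈ {0, 30, 60}), the design flags (same start/target/
combination/block, both targets inner, both directions cardinal, both
trials on the designated north–south street column), and three distance
measures: the mean and absolute difference of the two start→target vector
lengths, and the "neighborhood distance", the mean length of the six
vectors connecting the four buildings of the pair.  On any valid design
the condition sizes are 2256 (0-mod-60, including the Δ = 0 pairs) and
2304 (30-mod-60), with 276 both-inner-target pairs, independent of the
exclusion seed.

## Signal models

Patterns are trials × voxels matrices
`x[t, v] = b_v + signal_v(θ_t) + ε_tv`, with per-voxel baselines
`b_v ~ N(0, σ_b²)` and i.i.d. trial noise `ε ~ N(0, σ²)`.

- **grid** (six-fold): `signal_v(θ) = A_v cos(6(θ − ψ))`, with one grid
  orientation ψ ∈ [0°, 60°) shared by all voxels of a subject's region and
  per-voxel amplitudes `A_v ~ N(0, σ_A²)` (signs may differ).  Because the
  sampled directions are 30° apart, the sixth harmonic takes exactly two
  phases: all 0-mod-60 pairs share it, all 30-mod-60 pairs are in
  antiphase — the population analogue of sampling a 60°-periodic rate
  curve at matched vs. opposite phases.
- **hd** (one-fold): von Mises tuning
  `g·exp(κ cos(θ − μ_v))/I₀(κ)` with per-voxel preferred directions μ_v,
  giving a one-fold similarity profile.
- **null**: baseline plus noise; **mixture**: weighted grid + hd.

### Amplitude calibration

With ψ uniform across subjects, the grid signal sampled on the 30° grid
has per-subject strength proportional to cos²(6ψ); a subject whose grid is
oriented 15° from the sampling grid contributes nothing.  This
heterogeneity caps the attainable cohort effect size near d ≈ 1.4
regardless of amplitude.  The default amplitude spread σ_A = 0.06 (with
σ_b = σ = 1, 48 voxels) sits in the measurement-noise-limited regime and
yields a 24-subject cohort effect size of d ≈ 0.6 on the mod-60 contrast.
The calibration targets reliable recovery (≥ 70 % of cohorts at one-tailed
α = 0.05, Bonferroni ×2 over hemispheres; analytic power at d = 0.6 is
≈ 0.78) while staying in the weak-signal regime representative of
entorhinal fMRI effects (reported effects in this literature are near
d ≈ 0.5).

### Behavior

Responses are von Mises around the true direction (probability 1 − lapse)
or uniform (lapse).  Defaults κ = 2.8, lapse = 0.1 reproduce a ~34° mean
absolute error.  A pure-lapse responder has errors uniform on [0°, 180°],
so chance level is a median error of 90°; the exclusion rule is a
one-sided Wilcoxon signed-rank of the errors against 90°.

## Time-series embedding and extraction

`embed_timeseries` injects trial patterns into a small NIfTI volume
(2 mm isotropic, TR 1.8 s) through an imagination-period boxcar convolved
with a canonical double-gamma HRF, plus optional AR(1) noise,
random-phase cosine drift and random-walk motion traces with per-voxel
loadings (the six traces are emitted for the nuisance GLM).  The analysis
protocol averages late volumes rather than modelling the HRF, so the
embedding only needs to concentrate signal in the analysis window; the
canonical HRF does that.

Extraction mirrors the protocol: per-voxel least-squares residualisation
against the six motion regressors plus intercept, an optional 100 s
high-pass via discrete-cosine projection (on by default in time-series
mode, unnecessary in pattern mode), and per-trial averaging of the volume
during which the 10 s imagination period ends plus the two following
volumes.  Volume k is taken to cover [k·TR, (k+1)·TR), so the window
starts at floor(end/TR); the acquisition software's rounding at exact
boundaries is not observable from data, so this convention is fixed and
logged.  tSNR is the temporal mean over the temporal SD of the
*region-mean* time course (a voxelwise-mean variant is available); zero
variance yields NaN, never infinity.

## Similarity, contrasts and controls

Similarity is the Pearson correlation over voxels for every trial pair,
Fisher z-transformed.  z is capped at atanh(1 − 1e−15) so noiseless
synthetic patterns with r = ±1 stay finite (such pairs are flagged);
zero-variance patterns are flagged invalid and dropped, not zero-filled.
Condition means are unweighted means over included pairs.  The four
schemes: one-fold (Δ ≤ 30 vs Δ ≥ 60 — these cover all pairs on the 30°
grid), mod-60 (remainder 0 vs 30), mod-90 (0 vs {30, 60} pooled), and
cardinal (both directions cardinal vs rest).  Exclusion filters drop pairs
by design flag; distance controls regress pairwise z on intercept plus one
distance measure (continuous or median-split binary) per subject and
contrast the residuals.

A deliberate property of unweighted averaging: a *pure* one-fold
similarity signal leaks a small **negative** mod-60 contrast, because the
0-mod-60 condition holds 336 same-direction but 384 opposite-direction
pairs (−48/2256 of the similarity amplitude under linearisation), while
the 30-mod-60 condition is balanced.  The conservatism is two-sided
protection for the six-fold claim: head-direction-like signals cannot
produce a spurious positive mod-60 effect.  The qualifier *pure* matters:
if the one-fold signal rides on a large shared baseline, same-direction
pairs sit near r = 1 where atanh is strongly convex and the leakage turns
positive.  The specificity checks therefore plant a baseline-free,
low-concentration (κ = 0.5, near-cosine) one-fold signal.

## Searchlight

Spheres of 7 voxels diameter (123 offsets with ‖o‖ ≤ 3) are centered on
every voxel; sphere content is restricted to gray matter and spheres with
30 or fewer voxels are skipped ("more than 30" read strictly).  Every
defined map voxel equals the ROI-level contrast of its sphere, which the
tests check exactly.  Maps are NaN outside defined voxels; smoothing uses
a 4 mm FWHM Gaussian (σ = FWHM/(2√(2 ln 2))) renormalised over the defined
support.  Searchlights are not run inside the small entorhinal-like masks;
those are analysed as ROIs.

## Inference

Subject level: the trial→direction assignment is shuffled (default 10,000
permutations), pair conditions re-derived, and the contrast recomputed;
p = (1 + #{perm ≥ obs})/(n_perm + 1) (add-one, so p is never 0 and the
inverse-normal z is always finite).  Because pair membership depends only
on the two trials' direction values, each permutation reduces to a lookup
in a k × k direction-pair class matrix, which keeps 10,000 permutations
under a second.  Group level: one-sample T against zero (df = n − 1),
optionally one-tailed and Bonferroni-corrected over region comparisons, or
the sign-flipping permutation analogue (add-one p; resolution bounded by
2⁻ⁿ).  Small-volume corrections are Bonferroni over mask voxels or
max-statistic permutation; random-field corrections are out of scope.

## Verification protocol and its limits

The repeated-cohort checks use 50 cohorts for planted-signal recovery,
200 for the null rejection rate, 200 subjects × 1,000 permutations for
p-uniformity, 100 seeds for the specificity signs and 100 cohorts for the
behavioral null (whose product-of-errors statistic is right-skewed, making
the two-tailed t at n = 24 mildly anti-conservative) — sizes chosen so
the binomial/KS acceptance bands are informative while the whole battery
runs in minutes on one CPU.

What passing shows: the combinatorial design generator reproduces the
task's printed structure exactly; the analysis chain recovers a planted
60°-periodic population signal at weak-signal amplitudes and rejects at
the nominal rate under the null; the mod-60 contrast is specific against
one-fold, four-fold and cardinal alternatives.  What it does not show:
performance on real fMRI noise (spatial autocorrelation, physiological
confounds, registration error are not modelled), nor anything about the
biological claim itself — the synthetic cohort plants the signal the
analysis is designed to detect.  Real-data group statistics cannot be
reproduced here because the underlying raw data are not public.

## Known limitations

- The generator's noise model (i.i.d. Gaussian per trial in pattern mode;
  AR(1) + cosine drift in time-series mode) is the simplest that exercises
  the nuisance steps, not a realistic fMRI noise model.
- Procedural "views" for the visual-similarity control are textured
  gradients with building-like rectangles — enough to exercise the
  FFT/CIELAB feature pipeline, not renderings of a virtual city.
- Confidence ratings are generated and stored but not analysed.
- The north–south street is modelled as a configurable lattice column
  (default x = 1) because the street's member buildings are a property of
  the virtual city, not of the lattice.
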