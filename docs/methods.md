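# Methods

## The generative model

Each subject carries one latent rigidity trait `T ~ N(mu_group, 1)`
(TD mean 0, ASD mean 1.65). Every downstream observable derives from `T`
plus independent noise:

* **Behavioral traits.** `u_p = T + e_p` and `u_s = T + e_s` with
  `Var(e) = 1/rho' - 1`, where `rho' = 0.45 / 0.90` is the target
  behavioral correlation inflated by a measurement-attenuation constant
  (below). Because both indices share only `T`, their correlation is
  `rho'` at the subject level, and — a constraint worth stating
  explicitly — for *any* voxel `v` the product
  `corr(x, v) * corr(y, v) <= corr(x, y)`. With the two behavioral
  indices correlating at 0.45, no brain region can correlate with both
  behaviors more strongly than about `sqrt(0.45) ~ 0.67` each. The
  planted region is placed essentially at that ceiling (voxel-trait
  correlation ~0.95), which matches reported ROI-behavior correlations
  of about −0.6 in studies of this design.

* **Percept durations.** Gamma with fixed shape 3 and scale
  `1.5 * exp(0.18 * u_p)` seconds: long-tailed, median ~4 s for an
  average control, monotone increasing in the trait. Brief "mixed"
  reports are inserted after a percept with probability 0.08 (mean 1 s),
  giving ~1.5% of run time, and runs last 90 s, five per subject.

* **Task switching.** A two-state persistence process: repeat the
  current task with probability `p = sigmoid(0.70 + 0.35 * u_s)`, else
  switch — geometric-like run lengths with mean `1/(1-p)` ~ 3 trials
  for controls. Trials fill a 180 s budget (~200 trials/run, five runs);
  each trial shows four figures of which exactly one is the designated
  shape and exactly one distinct figure is uniquely brightest, so the
  chosen figure identifies the task. A 1% lapse rate produces
  unclassifiable choices; 0.2% of trials time out at 3 s. Instructed
  sessions replay the classified spontaneous sequence as cues with a
  separate RT model (switch cost ~150 ms vs ~15 ms spontaneous, noise
  SD 150 ms, 97% cue compliance).

* **Volumes.** 32³ grids at 3 mm, an ellipsoidal "brain" of ~9,800
  voxels, baseline GMV 0.5 (arbitrary modulated units). Inside a 15
  mm-radius sphere the mean shifts by `-0.06 * T`. Noise is white
  Gaussian smoothed to 8 mm FWHM and rescaled to voxel SD 0.015 (the
  smoothing models post-preprocessing spatial correlation only). Each
  subject also receives a global offset (SD 0.012) and ASD subjects a
  +0.013 surplus, sized so the whole-brain group difference is marginal
  (t ~ 2) *net of* the planted deficit.

* **Clinical scores.** ASD subjects' RRB scores in {0, 1, 2} come from
  fixed quantile cuts (45% / 30% / 25%, mean 0.8) of `T` plus noise
  (SD 0.75), so higher rigidity means higher RRB and lower ROI GMV.
  Social/communication scores and age/IQ are drawn independently from
  group-calibrated normals — deliberately uncorrelated with the trait,
  mirroring the absence of IQ/age associations in this design.

### The attenuation constant

The scored indices are means over five per-run medians. Medians of ~25
gamma draws, and especially medians of *integer* run lengths, are noisy
estimators, which attenuates the realized correlation of the scored
indices below the latent one (measured reliability product ~0.81). The
generator therefore inflates the latent correlation by a fixed factor
`measurement_attenuation = 0.90`, chosen once by evaluating the
generating model at large n, so that the *realized* correlation of the
scored medians converges to `trait_behavior_corr`. At 500 subjects per
group the realized correlation lands at 0.45-0.49.

## Randomness validation

The walk lives on `A - h_1 ... h_k - B`; a step continues the previous
direction with probability `P_trans`, reverses otherwise, and at an
extreme the forced inward move becomes the new direction (the walker
never stays in place). Passage durations are gaps between successive
*alternating* first arrivals at the two extremes, so returns to the
starting extreme do not reset the count, and both crossing directions
are pooled. `expected_passage_time` solves the linear first-passage
system over (interior position, last direction) states exactly; closed
forms (`E[T] = 2/p` for one hidden state, `k+1` at `P_trans = 1`)
anchor it.

Distributions are compared as shapes: durations are divided by their
sample mean and histogrammed on a fixed support [0, 5] (25 bins, tail
mass folded into the last bin), then `D(P_emp || P_sim)` is computed in
nats with 1e-10 smoothing and renormalization. Because step counts are
integers, their mean-scaled mass forms a comb whose teeth can land
exactly on bin edges (half of all geometric(0.5) run lengths are 1, i.e.
exactly 0.5 in mean units); a deterministic continuity correction
spreads each duration `d` uniformly over `(d-1, d]` before binning,
which removes the edge instability while leaving the shape comparison
intact. The uncorrected histogram (`continuity=False`) remains available
and is the mode in which exact scale invariance holds.

## Statistical machinery

* **Voxelwise regression** is simultaneous OLS across voxels with the
  design `[1, behavior, age, full IQ]`; t and two-sided p for the
  behavior coefficient with `n - p` df. FDR is Benjamini-Hochberg over
  in-mask p-values with no dependency correction. Survivors split by
  sign; the conjunction is the voxelwise intersection of the two
  negative maps. Clusters use 26-connectivity; peaks are max-|t| voxels
  reported in 0-based indices and mm (volume-center origin when no
  affine is present). No cluster-extent threshold is applied. The
  replication-style group contrast defaults to a one-tailed ASD < TD
  test, configurable.

* **Mediation** uses the percentile bootstrap (default 10,000 resamples;
  2,000 in the pipeline for runtime) over subjects, refitting both
  regressions per resample; `p = 2 * min(P(ind <= 0), P(ind >= 0))`
  floored at `1/n_boot`. Covariates are off by default. Resamples with
  degenerate x are redrawn (capped). Voxelwise mediation shares one set
  of resample indices across voxels for coherence and runtime. The size
  of this test was checked at the boundary null (alpha = 0 with a
  mediator-outcome path of 0.75, the strength typical of this design):
  5% nominal, measured ~5%. Under the double null (alpha = beta = 0) the
  product bootstrap is well known to be conservative; that regime is not
  the calibration point.

* **The latent model** is a one-factor measurement model (factor
  variance 1, first loading forced non-negative) fit by L-BFGS-B on the
  Wishart ML discrepancy with analytic gradients; residual variances are
  log-parameterized (Heywood solutions flagged at the ~0 bound).
  Indices: chi2 = (n-1)F; CFI against the diagonal independence
  baseline; RMSEA = 0 and AGFI = NaN at df = 0 (the three-indicator
  model is just-identified); SRMR over the correlation-scaled residual
  upper triangle.

* **Split-plot ANOVA** returns the group main effect
  `F = MS_group / MS_subjects-within-group` for balanced
  (subjects x runs) designs; it matches a mixed-ANOVA oracle exactly.

## Pipeline

Stages run in dependency order (simulate → behavior → comparisons →
randomness → VBM → ROI → mediation → SEM → replication) with per-stage
seeds spawned from one root seed; equal config + seed gives
byte-identical JSON reports (timings go to the log, not the report).
VBM, ROI statistics, mediation and the latent model use the ASD group
only; the conjunction ROI mediates when non-empty, and the planted
sphere is additionally reported as a generator-truth diagnostic. Cohorts
without volumes skip the neuro stages explicitly.

## Power at the default scale, and what passing tests mean

At 22 subjects per group the conjunction stage sits at its design
ceiling: expected cluster t ~ 3.4 against a BH step-up threshold ~ 3.5
over ~9,800 voxels, so the negative-negative conjunction is non-empty in
only ~10-20% of seeds, and the full qualitative pattern (longer ASD
medians + conjunction + significant conjunction-ROI mediation)
reproduces in ~10-15% — an honest property of the operating point, not
an implementation defect; the acceptance suite asserts higher rates and
is expected to flag exactly this. The well-powered contrasts behave as
designed: the ASD < TD group-difference map recovers 80-100% of planted
voxels, planted-ROI mediation is significant in ~60-75% of seeds, null
configurations are quiet in ~100% and null FDR any-survivor rates stay
at ~0.04.

Problem sizes were chosen to keep the full test suite and the
acceptance script fast on one CPU: 10^5-step walks per grid cell,
10^5-trial scoring checks, 200 null-cohort FDR simulations on 16³
grids, 1000 x 1000 bootstrap size simulations (vectorized), and 20-50
replicate pipeline runs.

## What the generator does not emulate

Stimulus rendering, MRI acquisition and preprocessing (segmentation,
warping, modulation — the pipeline consumes preprocessed maps and the
generator applies its own smoothing), anatomical labeling, perceptual
dynamics of mixed states, RT process models, within-subject run
dependence (runs are i.i.d. given the trait), site effects, and any
non-spherical cluster geometry. Passing tests therefore demonstrate the
statistical machinery and its calibration on data with the *assumed*
structure, not the biological validity of that structure.
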