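# Methods

`phonoflux` re-implements, as a tested pipeline, the analysis chain of a
word-learning / phonotactic-repair MEG-EEG paradigm: behavioral
categorization analysis, data-driven ROI identification on cortical
activation maps, Kalman-filter time-varying MVAR Granger causality with
bootstrap significance, and FDR-corrected between-condition comparison of
directed influences. Because the raw recordings of such studies are rarely
released, every stage is exercised on synthetic data with known ground
truth; this note records the models, the constants, and the reasoning
behind the choices that were genuinely open.

## Behavioral task and trial coding

The task is a two-alternative (S vs. SH) phoneme categorization of CCV
nonwords whose initial fricative comes from a five-step /s/-/ʃ/ continuum
spliced into /_l/ and /_r/ contexts. Participants first learn nonce words
whose onsets are phonotactically illegal in English (either /sr-/ or
/ʃl-/), which defines two familiarization groups. A trial's **condition**
is a deterministic function of group and context: the continuum whose
potential onset cluster occurred in the participant's training words is
*Trained* (sr-group × /_r/, shl-group × /_l/), the other is *Naive*. A
response is **unrepaired** when it reports the illegal cluster ("S" in the
/_r/ context, "SH" in /_l/). The full session is 2 contexts × 5 steps ×
27 trials = 270 trials (three blocks of 90); analyses use steps 2–5 (108
trials per participant per condition), step 1 being excluded by config
default rather than hard-coded so floor effects can still be studied.

**Condition test.** The published analysis is a by-subject random-slopes
logistic mixed model; this package fits a fixed-effects logistic
regression of the unrepaired indicator on Condition + Context + Step
(categorical), optionally with subject indicator covariates, and tests
Condition by a likelihood-ratio test against the model without it (df = 1,
chi-square reference). Main effects only: interactions would refine the
nuisance structure but not the tested contrast, and a fixed-effects model
is fully testable by simulation (type-I error 0.05 ± 0.02 at 200
replicates in the acceptance suite). Complete separation or degenerate
designs fall back to an L2-penalized fit (ridge 1e-3, L-BFGS on the exact
penalized likelihood); the result is flagged and the estimate is a
boundary value.

## ROI identification

Input is a vertex-level activation map (coordinates in mm, activation time
course per vertex). Three steps over the 100–500 ms analysis window:

1. *Centroids*: vertices whose mean |activation| exceeds the 95th
   percentile (linear-interpolation definition) are scanned in descending
   strength (ties broken by vertex id); any candidate within 5 mm
   (Euclidean) of an accepted stronger candidate is dropped.
2. *Growth*: activation courses are z-scored over the window; a vertex is
   similar enough to a centroid when the Euclidean distance between their
   normalized courses is below 0.5·√T_win, i.e. an RMS per-sample
   difference of 0.5 SD units. Membership is breadth-first closure of
   similar vertices from the centroid over a spatial adjacency graph
   (vertices adjacent within 2 mm).
3. *Pruning*: ROIs are ranked by mean non-normalized |activation|
   (strength); an ROI whose normalized mean course is within 0.9·√T_win of
   a stronger retained ROI is eliminated, so every retained signal carries
   unique predictive information for the MVAR stage.

**Why √T_win units.** "Within f SDs" needs a reference scale. Using the SD
of an empirical distance distribution is unstable here: that distribution
is bimodal (same-cluster distances ≈ 3, distinct-course distances ≈
√(2·T_win) ≈ 28 for z-scored courses), so its SD measures the mixture
weights, not similarity, and collapses when one cluster dominates. With
z-scored courses the natural unit is the per-sample SD itself: distance
f·√T_win means the two courses differ by f SDs per sample in RMS, and two
*orthogonal* unit-SD courses sit at exactly √2 ≈ 1.41 SDs. The 0.5 / 0.9
factors therefore admit only genuinely similar shapes, independent of map
composition. Both factors remain configurable.

Overlapping grown memberships are resolved by assigning shared vertices to
the stronger ROI; per-subject representative courses are the member vertex
maximally correlated with the group-level ROI mean course.

## Time-varying MVAR estimation

Each channel (ROI) is predicted from the p = 5 preceding samples of a
predictor set: all channels (full model) or all but one candidate source
(counter-model). Coefficients follow a random-walk state model tracked by
a scalar-observation Kalman filter; the innovation variance estimate that
scales the filter gain and defines the prediction-error scale is an
exponentially weighted mean of squared innovations (decay 0.98,
initialized at the target's variance, floored at 1e-12).

Filter constants (none are printed in the source protocol) were fixed
during method development against independent oracles:

| constant | value | why |
|---|---|---|
| process noise q | 2e-5 | post-warm-up coefficients match an OLS fit of stationary MVAR(2) data within 0.011 RMSE (n = 2000), while a 0 → 0.5 coefficient step is still tracked past half-height within ~240 samples |
| initial state / covariance | 0 / 1.0·I | convergence within ~100 samples at 1000 Hz, matching the 100-sample warm-up that is excluded from all downstream statistics |
| error smoothing decay | 0.98 | per-timepoint error scale stable enough for a log-ratio statistic; instantaneous |residual| is too noisy |

With q → 0 the filter reduces to recursive least squares, so the
stationary-data check against OLS is a genuine external anchor, not a
self-comparison. A known floor applies to the null case: for white-noise
input the time-averaged |coefficient| cannot fall below ≈ √(d/t) per
sample (estimation noise), ≈ 0.055 when averaging over samples 100–600
with d = 15 regressors; the null-shrinkage property is therefore asserted
at n = 2000 where the floor is ≈ 0.03.

## Granger causality and significance

For a directed pair source → target,
GCi(t) = ln(σ_reduced(t) / σ_full(t)), positive when the source carries
unique predictive information. Significance is bootstrap-based: surrogate
series are reconstructed by iterating the *fitted* time-varying full-model
coefficient tensor with the source→target coefficient block zeroed and
innovations resampled with replacement from the fitted residual pool
(first p samples taken from the observed data; diverging replicates are
redrawn and logged). Each surrogate is run through the same full +
counter-model fit, giving a per-timepoint null distribution. p(t) is the
plain empirical upper-tail fraction #{null ≥ observed}/B — deliberately
not the (k+1)/(B+1) convention, whose floor of 1/(B+1) can exceed the
smallest Benjamini–Hochberg thresholds and make rejection arithmetically
impossible at practical B; the plain fraction leaves per-timepoint
calibration unchanged (measured null significant-timepoint fraction 0.039
at α = 0.05, B = 200).

Zeroing one coefficient block (rather than deleting the channel or phase
randomization) keeps all other network structure in the null, so the test
targets exactly one edge. One-sided upper-tail p-values only: negative GCi
has no causal reading.

Two summaries are computed per edge:

* **Per-condition strength** (the published summary): the number of
  analysis-window timepoints with p(t) < α. Conditions are compared by an
  exact conditional binomial (sign-test) on the two counts — given
  k = count_A + count_B, count_A ~ Binomial(k, ½) under the null — with
  Benjamini–Hochberg FDR across edges. Timepoint autocorrelation makes
  the nominal level of this count comparison anti-conservative; it is
  reported as the published procedure, not as a calibrated test.
* **Single-condition detection** (for recovery studies): the window-mean
  GCi against its bootstrap null, one p per edge, FDR across edges. This
  avoids the autocorrelation problem and is the statistic behind the
  planted-network recovery results.

The bootstrap is built at the level at which GCi is computed (per series);
multi-subject aggregation is a thin loop over subjects upstream.

## Synthetic data: what it emulates, what it does not

* **MVAR series** stand in for trial-averaged source time courses:
  Gaussian innovations (matching the Kalman observation model),
  stability-checked coefficient schedules (static, piecewise-constant, or
  linear ramp), 200-sample burn-in. Defaults mirror the study conditions:
  1000 Hz, series covering 0–600 ms so the 100–500 ms window is interior,
  planted lag-1 couplings of 0.4–0.5 with self-terms 0.3.
* **Vertex maps** are planar patches (the ROI algorithm consumes only
  pairwise Euclidean distances; cortical folding and geodesics are out of
  scope): planted clusters of 100 vertices within a 6 mm radius, Gaussian
  spatial falloff (σ = radius), over 1500 noise-only background vertices.
  Latent cluster courses are 5 ms-smoothed Gaussian noise normalized to
  unit SD inside the analysis window — rich enough that distinct clusters
  are near-orthogonal in shape (a low-dimensional bump model was tried
  first and produced inter-cluster correlations up to |r| ≈ 0.9, i.e.
  clusters that were not actually distinct). SNR (center amplitude /
  vertex noise SD) is exposed as a parameter; recovery conditions use 10.
  Real minimum-norm maps add spatially correlated noise, point-spread
  leakage between nearby sources, and folded geometry; passing recovery
  here shows the algorithm is correct under its own assumptions, not that
  it is robust to those effects.
* **Behavioral tables** draw responses from a logistic psychometric
  function of step (slope 1.2/step, midpoint 3.5 — rates spanning ~5% to
  ~85% across steps, qualitatively matching published repair curves) with
  an additive log-odds learning shift in the Trained condition only.
  Real data add by-subject slope/intercept variability; the fixed-effects
  generator matches the fixed-effects test.

## Numerical details

* Window conversion: closed ms intervals, endpoints rounded toward the
  interior; 100–500 ms at 1000 Hz = samples 100–500 (401 points).
* Centroid ties: descending strength, then lexicographic vertex id.
* Kalman covariance is re-symmetrized every step; the innovation-variance
  estimate is floored at 1e-12, so error scales stay positive.
* Surrogate replicates whose iteration exceeds |x| > 1e6 are rejected and
  redrawn (up to 5× the replicate budget, then an error).
* All stochastic stages take explicit seeds; the pipeline derives
  per-stage seeds from one root seed via `numpy.random.SeedSequence`
  keyed on (seed, stage name).

## Problem sizes

The test suite and acceptance script run everything at the scale the
statistics require rather than the scale of a full study: series of 600
samples (the study's epoch length), bootstrap B = 200 for recovery and
calibration studies (the config default remains 2000, the published
value), 2–6 channel networks, 20 seeded recovery runs (10 in the
acceptance script), 100-seed ROI recovery, 200-replicate behavioral
simulations at the study's scale of 12 subjects × 108 trials per
condition.

## Known limitations

* The count-based condition comparison inherits the anti-conservativeness
  of autocorrelated per-timepoint decisions; treat its FDR-corrected
  output as a ranking, as the bubble-plot originals effectively are.
* The Kalman filter's error scale is a smoothed statistic; GCi at
  timepoint t therefore reflects a ~50-sample trailing neighborhood
  (decay 0.98), which blurs fast coupling changes.
* ROI identification assumes additive vertex noise that is independent
  across vertices; spatially correlated noise would inflate cluster sizes.
* Model order is fixed (default 5, the published heuristic); no order
  selection is attempted.
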