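# Methods

`dgspace` analyzes single-cell calcium activity and spatial coding in
head-fixed mice running on a circular treadmill belt, with the nested
statistics needed when cells are pooled across animals. This note describes
the models and procedures, the parameters that matter, the synthetic data
the test suite is built on, and the numerical choices made where the design
was genuinely open.

## Session model

A session is one mouse-day recording: a cells × frames ΔF/F matrix, an
optional parallel matrix of nonnegative deconvolved event amplitudes, and a
per-frame belt position in `[0, L)` cm with its timestamps. The belt is
circular and assumed to advance forward only (it is moved by the animal /
experimenter in one direction), so a drop in raw position is read as a wrap:
the per-step displacement is `(Δposition) mod L`, laps are counted at wraps,
and total distance is the sum of forward displacements. Total distance is
invariant under re-binning of time. Timestamps are taken from the file, not
reconstructed from the nominal frame rate; the frame rate is used only for
filter design and synthesis. Default belt length is 180 cm (a config value,
not a constant — any positive length works).

Cell detection, deconvolution, and cross-day ROI matching are upstream of
this package (Suite2p-class tools); their outputs are our inputs.

## Preprocessing

* **Lowpass filtering.** ΔF/F is filtered with a zero-phase
  (forward–backward) Butterworth lowpass, order 3, cutoff 2 Hz by default.
  The order and zero-phase application are fixed by the analysis being
  reproduced; the cutoff is our choice: at 15.25 fps, 2 Hz removes
  frame-to-frame noise while leaving jRGECO transient shapes (≈ 0.8 s decay)
  intact. The forward–backward pass squares the single-pass magnitude
  response and cancels phase lag; padding extends well past the filter
  transient (≥ 15·fs/cutoff samples) so the operation is symmetric under
  time reversal to machine precision.
* **Baseline and thresholding.** The baseline is a centred rolling mean
  (default window 30 s — long relative to transients, short relative to
  slow drift), truncated at the recording edges rather than padded. The
  noise scale σ per cell is the standard deviation of (filtered − baseline)
  over the whole recording; a robust alternative (1.4826 × MAD) is
  available via `AnalysisConfig.robust_sigma`. The suprathreshold trace is
  `max(0, filtered − baseline − kσ)` with k = 2. Subtraction (rather than
  gating) is used here because this trace feeds an area-under-the-curve
  activity measure. Constant traces (σ = 0) are flagged degenerate and
  carried with zero suprathreshold activity.
* **Deconvolved events** are thresholded differently: amplitudes are
  nonnegative with baseline 0, σ is the RMS of the event row about 0, and
  values at or below kσ are *set to zero* while values above are kept at
  full amplitude — an event amplitude is already a point estimate of
  transient size, so nothing is subtracted.
* **Movement epochs.** Frames with speed above 1 cm/s (config) forming
  maximal runs strictly longer than 1 s become movement epochs. Only these
  frames enter the spatial analyses; activity deliberately uses the whole
  recording.

## Single-cell activity

Activity is the area under the suprathreshold trace divided by the distance
run: `A = Σ_t supra[t]·Δt[t] / D`, with D in metres. The time-weighting
(×Δt) makes the value a true area, invariant to frame rate; a raw frame-sum
mode exists behind `time_weighted_activity=False` for compatibility with a
cumulative-sum convention (the two differ by the constant frame interval
when the frame rate is shared, so comparisons are unaffected). The choice
of metres affects only a global scale. A cell is *active* if it has at
least one suprathreshold frame; a session with zero distance has undefined
activity (NaN, excluded downstream).

## Spatial tuning

The belt is divided into 100 equal half-open bins. Occupancy is the
movement-epoch time per bin; a cell's rate map is the time-weighted mean
suprathreshold activity per bin divided by occupancy. Unoccupied bins get
rate 0 and are excluded from normalization rather than interpolated
(interpolation would invent rates). Tuning uses thresholded deconvolved
events when present, else the thresholded filtered trace; the source is
recorded in outputs.

Because the belt loops, the normalized rate map `w` lives on the circle:
bin j maps to angle θ_j = 2π(j + 0.5)/100 and the **tuning index** is the
mean resultant length `|Σ_j w_j e^{iθ_j}|` ∈ [0, 1]. It is invariant under
rotation of the belt and equals 1 for a single-bin cell, 0 for a uniform
one. For a noiseless von Mises tuning curve with concentration κ the index
converges to I₁(κ)/I₀(κ); for untuned cells with m effective events the
null expectation is ≈ √(π/(4m)) — the index is biased upward at small
sample sizes, which matters when comparing groups with different event
counts (the nested bootstrap operates on the pooled per-cell values and is
agnostic to this, but interpretation should not treat small indices as
exact zeros).

Lap rasters accumulate suprathreshold activity per (lap, bin) during
movement, split laps by parity, and reuse the all-lap preferred-bin sort
for both parities so even/odd reliability is visible. Cells with no
defined tuning direction (zero total rate) are flagged, never dropped
silently. The "extreme-decile Fisher information" cell selection defaults
to the *top* decile (cells whose activity concentrates at one location);
a `bottom` mode exists because the opposite reading of a percentile cut is
defensible.

## Single-cell Fisher information

Discriminability of two belt locations by one cell is a signal-to-noise
ratio on the *unfiltered* ΔF/F: signal = (difference of the two location
means)², noise = average of the two within-location sample variances
(ddof = 1). Position is divided into 20 bins; samples are the movement-epoch
frames in each bin. The naive ratio is biased upward by sampling noise in
the means; with T = min(T_j, T_k) samples per location the corrected
estimator is

    FI = raw · (2T − 4)/(2T − 2)/δs² − 2/(T·δs²),  δs = 1 bin.

Under Gaussian sampling with equal variances this is exactly unbiased for
(Δμ)²/σ² (the first factor cancels the inverse-chi-square moment of the
pooled variance, the subtracted term the sampling variance of the mean
difference), so null cells average zero and single estimates may be
negative. Using min(T_j, T_k) is conservative under unequal occupancy; the
exact unequal-T correction is not part of the reproduced description.

A cell's FI is the mean over the 20 circularly adjacent bin pairs — Fisher
information is a local, slope-like quantity, and averaging all pairs would
mix length scales. An `all` mode exists that uses every pair with δs set
to the circular bin distance. Pairs with fewer than 3 samples or zero
pooled variance on either side are skipped and excluded from the mean;
cells with no usable pair are flagged undefined. FI is computed on
movement frames for consistency with the tuning analysis. Known
limitation: within-bin frames are temporally autocorrelated (indicator
decay ≈ 0.8 s), so they are not independent samples; no correction is
applied, which inflates effective sample counts equally in both groups
being compared.

## Nested bootstrap group test

Cells within a mouse are not independent, so pooled cell-level tests
overstate evidence. The group statistic is the mean of per-mouse means
(equal mouse weighting — the natural estimator under nesting; a
pooled-cell mean exists behind `statistic="pooled"`). For each of B
iterations (default 100,000) a null surrogate is built by drawing, for
every mouse in both groups, that mouse's observed cell count with
replacement from the pool of **all** cells of both groups (pooling
enforces the null), and the surrogate group-statistic difference is
recorded. With empirical difference d:

* directional p = (1 + #{null ≥ d})/(B + 1) for d ≥ 0, mirrored otherwise
  (the convention used for headline p-values);
* two-sided p = (1 + #{|null| ≥ |d|})/(B + 1);
* the significance decision is **two-tailed** at α = 0.05: choosing the
  tail from the observed sign would double the one-tailed error rate, so
  both p-values are reported but the decision uses the two-sided one.

Add-one smoothing keeps p in (0, 1] with floor 1/(B + 1) — at B = 100,000
the finest reportable granularity is 10⁻⁵. All draws come from a single
seeded generator in a documented order (one B × n_m index block per mouse,
first group's mice in order, then the second's), so an independently coded
loop reproduces the null distribution exactly. A `hierarchical` scheme
additionally resamples mouse identities with replacement within each group
before drawing cells, following standard hierarchical-bootstrap practice;
whether the original analysis also resampled mice is not determinable from
its description, so both are provided with `cell_pool` as the default.
Families of comparisons (e.g. one test per imaging day) are
Bonferroni-corrected with the family size m, which may exceed the number
of p-values supplied.

Calibration: across 1,000 simulated null datasets (two groups × 8 mice ×
100 i.i.d. cell values) the two-tailed rejection rate at α = 0.05 stays at
or below nominal within Monte-Carlo error (see `tests/test_acceptance.py`
and `scripts/acceptance.py`, which recompute it).

## Multi-day reactivation

Cross-day identity comes from an input match table
(`mouse_id, day, cell_id_day1, cell_id`); ROI matching itself is out of
scope. The reactivation rate of a mouse on day d is the percentage of its
day-1-active cells that are matched and active on day d, each day
evaluated against day 1 independently. "Active" inherits the activity
module's definition (≥ 1 suprathreshold frame); with real data the set of
deposited traces is already curated to active cells, so the two notions
can differ slightly — a documented difference, not computable from traces
alone. Cells of a given day can be partitioned into reactivated vs
non-reactivated subpopulations (day pair configurable, 1 vs 4 by default)
whose metric values feed the nested bootstrap, and matched day-1/day-4
value pairs support within-cell comparisons; cells defined on only one day
are excluded and counted.

## Synthetic cohorts

The generator produces the hierarchical structure the analysis assumes,
with ground truth, so every stage is testable without downloads.

* **Track:** alternating running bouts (exponential durations, mean 8 s;
  uniform speed 8–25 cm/s) and pauses (probability 0.3, mean 2 s),
  emulating irregular belt motion; 600 s at 15.253 fps on a 180 cm belt
  with four texture-zone boundaries recorded as metadata.
* **Cells:** event times from an inhomogeneous Poisson process with a
  peak-normalized von Mises rate bump (baseline 0.02 events/s, in-field
  0.4 events/s — sparse, as appropriate for dentate granule cells; κ = 0
  gives an untuned cell, place-cell fraction 0.5). Event amplitudes are
  gamma(2, 0.5) (mean 1), scaled by condition gain × a per-mouse lognormal
  gain (sd 0.1) — the mouse-level random effect that makes nesting real.
  ΔF/F is the event train convolved with a two-exponential kernel (rise
  0.05 s, decay 0.8 s, peak-normalized; config fields approximating a
  red-shifted indicator) plus white noise.
* **Noise scaling:** the per-cell noise sd is `noise_sd × total gain`
  (noise specified relative to the unit event amplitude): indicator
  expression sets both transient and noise amplitude in ΔF/F, so a
  condition-level gain is an exact affine rescaling of the trace. This
  keeps amplitude-invariant quantities (tuning index, FI) invariant under
  the gain knob by construction, and the hyperactivity manipulation shows
  up only where it should — in distance-normalized activity.
* **Events matrix:** the true binned amplitudes are emitted as an
  ideal-deconvolution channel so tuning-path tests are not confounded by
  an inference step that real pipelines outsource.
* **Cohort:** per group × mouse × day one session. Day-1 cells persist
  across all later days with probability 0.2 (keeping their preferred
  position; κ follows the group's per-day schedule); non-persistent cells
  are replaced by fresh ones so per-session counts stay constant, and the
  ground-truth match table is emitted. The default "paper-like" scenario:
  young — 8 mice × 114 cells, κ = 4 on all days; aged — 8 mice × 87
  cells, amplitude gain 1.5, κ = 1, 2, 3, 4 across days 1–4 (initially
  degraded tuning recovering with familiarity). Everything is
  deterministic for a fixed seed, to the byte, including written bundles.

**What the generator does not emulate:** motion artifacts, neuropil
contamination, slow drift, bursting/refractoriness, non-von-Mises field
shapes, remapping of persistent cells, or correlated noise across cells.
Passing tests therefore demonstrate correctness and calibration of the
*analysis* under the assumed generative structure, not robustness to
imaging artifacts that precede this package's entry point.

## Problem sizes in the validation suite

The module tests run on seconds-scale fixtures. The end-to-end pattern
check runs the full default cohort (2 × 8 mice × 4 days, 600 s sessions)
with the bootstrap scaled to B = 2,000 — at that B the smallest resolvable
p is 5 × 10⁻⁴, an order of magnitude below the Bonferroni threshold
0.0125 used there, so the scaling does not affect any decision boundary.
The null-calibration experiment uses 1,000 datasets at B = 2,000 for the
same reason. Monte-Carlo oracle checks use 10,000 replicates with
3-standard-error tolerances.

## Degenerate inputs and tie-breaks

Constant traces, all-zero event rows, silent cells, unvisited bins,
zero-variance bin pairs, zero day-1-active mice, and zero-distance
sessions are all flagged (NaN / boolean flags) and excluded from group
statistics rather than raised or silently dropped; truly malformed inputs
(non-monotone time, positions outside the belt, mismatched shapes) raise.
Decile cell selection breaks ties by lexicographic cell id; the raster
cell sort is a stable argsort by preferred bin. p-values can never be 0 by
the add-one rule.
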