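# Methods

This note documents the models, estimators and numerical choices behind
`caflow`, in the order data flows through the pipeline.

## Transient model and synthetic data

The generator's trace model is piecewise: a cell's fluorescence holds a
plateau `P` until the delay time `T_D` after arrest, rises to `P · I_P`
over the peak time `T_P`, and then relaxes exponentially back toward the
plateau with time constant `τ`. The rise is a linear ramp by default —
the simplest monotone shape with an unambiguous peak time — with a
smoothstep alternative (`rise_shape="smooth"`). Real descriptions of such
transients only constrain the rise qualitatively ("swift") and say
nothing quantitative about the decay, so `τ` is a free generator
parameter (default 40 s) that the analysis never estimates. Noise is
additive Gaussian per frame; Poisson shot noise can be enabled for
rendered scenes. Peak SNR is defined as the noiseless rise amplitude
`P(I_P − 1)` divided by the per-frame noise SD.

Rendered scenes place each cell as an isotropic Gaussian-profile disk
(σ = radius/2, default radius 7.5 µm, a typical lymphoid-cell size) whose
brightness scales with its trace. Cells *occlude* the uniform background
(pixel = max(background, cell)) rather than adding to it: a dye-loaded
cell is much brighter than the substrate beneath it, and occlusion keeps
the measured cell intensity proportional to the trace, so intensity
ratios are preserved exactly through rendering. Translating cells move
along +x at constant velocity until their arrest time; entry and arrest
times are snapped to the frame grid (sub-frame phase is unobservable) and
the snapped values are what ground truth records.

Default acquisition mirrors the two assay configurations: calcium scenes
at 20 fps (0.05 s frame interval), adhesion scenes coarser; pixel size is
an explicit configuration value (default 0.8 µm/px) because it depends on
the camera/objective pairing and must always be supplied with real data.

**Cohorts.** Conditions (ligand µg/mL, shear dyn/cm², treatment) are
labels mapped to sampling distributions of (T_D, T_P, I_P): lognormal
with condition-dependent medians and geometric SDs (defaults 1.35, 1.30,
1.20), I_P floored at 1.6 so every activated draw clears the activation
threshold by construction. Published results for this assay family are
boxplots without printed values, so the absolute medians are package
choices on the reported scale (reference condition: T_D 30 s, T_P 15 s,
I_P 2.5, plateau 150 a.u. over background 60 a.u.); the *directions* of
the condition effects follow the reported biology — higher ligand density
or shear shortens T_D and T_P and raises I_P; membrane-channel blockade
or adaptor knockdown does the opposite; an ER-channel inhibitor does
nothing. Arrested cells in calcium scenes appear in the field at their
arrest time. A cell that rolls and then stops is supported by the
generator, but note that the displacement-window criterion then places
the onset up to `threshold/velocity` *before* the true stop (any window
accumulating < 10 µm qualifies), an inherent property of the criterion
rather than an implementation artifact.

What the generator does *not* emulate: photobleaching, dye kinetics and
calcium oscillations; uneven illumination; cell shape change and
spreading after arrest; receptor-level bond mechanics (shear is a label,
not a solved flow field). Passing tests therefore demonstrate the
*pipeline's* correctness on data satisfying its assumptions, not
robustness to every real-microscopy artifact.

## Detection, linking, firm adhesion

Detection is smooth (Gaussian, σ = 1 µm) → global threshold → connected
components → physical size filter (10–2000 µm²) → intensity-weighted
centroids, reported in µm with the pixel-centre convention
`(index + 0.5) × pixel_size` (origin top-left, x rightward, y downward).
The default threshold is `median + max(k·1.4826·MAD, 0.05·median)` with
k = 3. Robust statistics matter here: when one cell is at its calcium
peak a mean + k·SD threshold rises with the frame SD and can drop dim
plateau cells below threshold, splitting their tracks mid-recording; the
median/MAD version is insensitive to a few bright objects. The 5 %-of-
median floor handles noise-free frames (MAD = 0) and keeps the threshold
proportional to illumination, preserving exact illumination-scale
invariance of the whole pipeline. `mean_sd` and `otsu` thresholds remain
selectable.

Linking is greedy nearest-neighbour: per frame transition, candidate
(track, detection) pairs within `max_step` (default 10 µm) are sorted by
(distance, track id, detection index) and assigned first-come — fully
deterministic; unmatched detections found new tracks; tracks unmatched
for more than `max_gap` frames (default 2) close.

Firm adhesion: a track is firm iff some window of 60 s has travel
displacement **strictly** below 10 µm. "Travel displacement" is read as
net Euclidean displacement between the window's first and last positions
(the weaker criterion and the common arrest-vs-rolling convention); a
cumulative path-length mode is available (`displacement_mode="path"`).
The window slides at frame resolution; its endpoint is the first
observation at or after start + 60 s, which makes the definition robust
to linking gaps; the earliest qualifying window start is the arrest onset
and the calcium-trace time origin. Tracks shorter than one window are
non-firm with an `insufficient_span` flag; motion after the onset
(possible detachment) is flagged `motion_after_onset` but the earliest
onset stands. The 7-minute firm-adherent count is the number of distinct
firm tracks with onset inside the assay window.

## Trace measurement

From the onset frame onward, `F_IC` is the mean intensity over the cell
mask and `F_IB` the mean of the per-domain means of the four background
domains (radius 6 µm at 24 µm, axis-aligned). A domain is dropped for a
frame when it leaves the field or overlaps any other detected cell that
frame (a slider passing through); at least two domains must survive or
the frame QC-fails. Traces with more than 20 % QC-failed frames are
rejected. `F_IN = (F_IC − F_IB)/F_IB` is recomputed row-wise and a
non-positive background is a domain error, never silently clamped.

Two mask choices depart from the naive per-frame segmentation mask, both
to protect the peak/plateau ratio from segmentation bias:

* the mask is frozen at the arrest-onset frame (`mask_mode="onset"`,
  default) — an arrested cell does not move, and a per-frame threshold
  mask grows when the cell brightens, diluting the peak with rim pixels
  (`mask_mode="frame"` is available);
* within the mask, F_IC is measured over the bright core — pixels at or
  above the mask's median intensity in the reference frame
  (`mask_core_quantile = 0.5`) — because the robust detection threshold
  admits rim pixels at background level whose intensity does not follow
  the cell.

## Onset, peak and features

The "sharp increase" has no standard operational definition, so the
package uses a two-stage estimator whose trigger thresholds are exposed
and echoed into provenance:

1. **Trigger.** The trace is smoothed with a 0.5 s moving mean
   (edge-shrinking windows, no padding bias). The running plateau
   estimate is the mean and SD of the smoothed trace from t = 0 up to the
   candidate; the trace activates at the first candidate where
   `m = 5` consecutive smoothed frames exceed
   `mean + max(k·SD, floor)` (k = 3, absolute floor 0.05 F_IN units, and
   at least 2 s of plateau data before any candidate). Smoothing is what
   keeps this workable at realistic noise: it moves the first crossing
   close to the true onset, so the running estimate is still an estimate
   of the *plateau* rather than of plateau-plus-rise.
2. **Refinement.** The trigger time is refined to the least-squares
   breakpoint of a flat-then-ramp model of the *unsmoothed* trace on
   [0, trace maximum] (vectorized over breakpoints with prefix sums,
   slope constrained positive), then to sub-frame precision by
   intersecting the fitted plateau level with a free line through the
   rise, clamped to one frame around the grid breakpoint. `T_D` is this
   refined onset; for a noiseless linear rise it is exact.

The peak is the global maximum of F_IN after onset, earliest frame on
ties, whenever the measured plateau noise is below the per-frame rise
increment — in that regime the raw argmax already localizes the corner to
one frame, and the noiseless recovery contract (errors within one frame
interval, I_P within 1 %) is met by construction. At higher noise a raw
argmax wanders several seconds along the flat corner region, so the peak
is instead the breakpoint of a least-squares two-line corner fit (rising
and falling slopes, continuous at the corner) on a window around the
smoothed maximum; the fitted corner height also de-noises the peak
*value*, which matters because the maximum of hundreds of noisy frames
overestimates the peak by 2–3 SDs. If the corner fit is degenerate the
smoothed maximum is used. This noise-adaptive rule replaces a fixed
"always use the raw argmax" convention, which cannot meet both the
noiseless and the SNR-5 recovery contracts simultaneously.

`I_P` has two conventions, both implemented because both readings exist
for this assay family and they disagree when the plateau F_IN is near
zero: the default `raw-ratio`, `(1 + F_IN_peak)/(1 + F_IN_plateau)`, is
algebraically the raw-intensity ratio under a stable background and is
well defined for any physical trace; `normalized-ratio`,
`F_IN_peak/F_IN_plateau`, is the literal ratio of normalized values and
QC-fails when the plateau F_IN is non-positive. The convention used is
recorded in provenance. A cell is **activated** iff an onset triggered
and `I_P ≥ 1.5` (a value exactly at the threshold activates). The double
gate is deliberate: a spurious trigger on a flat noisy trace almost never
survives the I_P gate because the fitted corner height stays near the
plateau.

## Statistics

Two groups: Student's two-sample t-test, pooled variance by default
(the classically named test), Welch behind a flag; two zero-variance
groups with equal means report t = 0, p = 1 with a flag. Three or more:
one-way ANOVA with Tukey HSD on all unordered pairs (studentized-range
adjustment, via scipy). Summaries report min/Q1/median/Q3/max with
quartiles by linear interpolation between order statistics (the one
documented rule; boxplot conventions vary) plus mean ± SEM (SD/√n, 0 by
convention for n = 1). p-values carry star notation (ns, *, **, ***,
**** at 0.05/0.01/0.001/0.0001). Any group below 15 values is flagged
against the usual ≥ 15-events-per-group collection rule.

## Determinism and problem sizes

Every stochastic step derives from an explicit integer seed
(`numpy.random.default_rng`); rendering, cohort sampling, the pipeline
and the acceptance script are bit-reproducible per seed, and re-running
the pipeline with an identical config writes byte-identical CSVs. The
validation suite uses synthetic problem sizes chosen to exercise the
contracts at single-CPU scale: 60-cell cohorts for parameter recovery
(rendered scenes for the noiseless contract, traces at peak SNR 5 for
the noisy one), 200 tracks for the arrest-classifier oracle equivalence,
1000 replicates of scaled-down 15-cell-per-group cohorts for type-I
calibration, and 20 cells per shear condition for directionality.

## Known limitations

* Greedy nearest-neighbour linking has no motion model and will swap
  identities in dense fast-moving fields; the intended assays track
  arrested or slowly translating cells.
* The onset refinement assumes a single transient per trace; oscillating
  or multi-burst cells get the first burst's onset and the global peak,
  which may belong to different bursts.
* Background domains assume the 24 µm annulus is mostly cell-free;
  in confluent fields all four domains can be excluded and the trace
  QC-fails rather than guessing a background.
* No calcium-concentration calibration is attempted; all intensities are
  arbitrary units, as in the assays this mirrors.
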