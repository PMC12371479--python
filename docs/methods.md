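# Methods

`mesopipe` is a headless analysis pipeline for mesoscale widefield imaging
of cortex: recordings of fluorescence (e.g. GCaMP) and reflectance acquired
with interleaved illumination, organised as longitudinal projects of many
subjects, groups and sessions. This note documents the models, conventions
and numerical choices behind each stage, what the synthetic generators do
and do not emulate, and the known limitations.

## Data model and conventions

A recording channel is a `(T, H, W)` float array plus metadata (frame rate,
shape, channel identity, optional wavelength/pixel size). On disk it is a
headerless float32 little-endian binary (C-order, time-major) next to a
JSON sidecar; the sidecar also carries a `format_version` and the audit
trail — an ordered list of `{stage, params}` records appended by every
processing stage, so any stored stack documents its own provenance.

Conventions used throughout:

* indices are 0-based; arrays are `time x row x column`;
* frame `t` starts at `t / frame_rate_hz` seconds (frame-start convention);
* the frame associated with a timestamp `ts` is `ceil(ts * rate)` — the
  first frame at or after the event, with timestamps landing exactly on a
  frame boundary assigned to that frame (a small relative snap tolerance
  absorbs binary-float representation error);
* missing data is NaN; means, traces and correlations exclude missing
  values pairwise; nothing is ever interpolated;
* event timestamps are seconds from recording start.

The project manifest (`project.json`) indexes subjects (with user-edited
group labels and attributes) and acquisitions found under
`raw_root/subject/acquisition/`. Rescanning appends new entries, flags
vanished ones (`missing: true`) and never touches user-entered fields;
serialisation is pretty-printed with sorted keys so idempotence is
byte-testable.

## Hemodynamic correction

Fluorescence recorded through tissue is modulated by blood volume and
oxygenation. With simultaneously recorded reflectance channels, the default
correction is a per-pixel ordinary least squares of the fluorescence trace
on `[1, refl_1, ..., refl_k]`; the corrected trace is the residual plus the
pixel's temporal mean. Restoring the mean is a deliberate choice so dF/F
remains computable downstream. The fit runs on raw (not dF/F) traces by
default. Degenerate pixels whose reflectance traces are constant fall back
to an intercept-only fit (output equals input) with a warning; the batched
solver uses the pseudoinverse, which also covers rank deficiency. After
correction every residual trace is numerically orthogonal to each
mean-centred regressor.

The ratiometric alternative divides the mean-normalised fluorescence by the
mean-normalised reflectance per pixel, cancelling any multiplicative
artifact shared by the two channels; it requires strictly positive data.

## Hemoglobin estimation (modified Beer-Lambert)

With reflectance at two or more wavelengths, optical-density changes
`dOD(lambda, t) = -ln(R / R_baseline)` are solved per pixel and frame for
`[dHbO, dHbR]` through the linear system whose design rows are
`[eps_HbO(lambda) D(lambda), eps_HbR(lambda) D(lambda)]` — extinction
coefficient times mean pathlength. The package ships an editable default
table at 525/590/625 nm (values approximated from tabulated hemoglobin
spectra, in 1/(uM cm), with nominal pathlengths per band); these are
configuration, not constants, because the correct values depend on the
illumination and camera spectra of a given rig. A design whose extinction
columns are proportional is rejected as singular.

## Global-signal regression, filtering, dF/F

Global-signal regression computes the spatial mean trace `g(t)` (optionally
within a mask) and regresses each pixel on `[1, g]`, keeping the residual
plus the pixel mean (a per-pixel fitted beta, not plain subtraction;
subtraction is available as `mode="subtract"`). Temporal filtering is a
zero-phase (forward-backward) Butterworth of order 4 by default, applied per
pixel; low-pass preserves DC, high-/band-pass removes it and then restores
the pixel temporal mean. dF/F is `(F - F0)/F0` with F0 either the whole-
trace mean (spontaneous recordings) or a frame-range mean (the pre-event
window for evoked data); F0 must be strictly positive, and dF/F is invariant
to positive rescaling of the input.

## Event-triggered analysis

Trials are cut around event onsets (`pre_s` before to `post_s` after, via
the ceil frame convention); trials that would cross a recording edge are
dropped and counted, never padded. Averages carry across-trial SD and SEM
(n-1 denominator).

Per-pixel metrics of an average movie with `pre` baseline frames:

* peak amplitude — maximum over the post window of the baseline-subtracted
  signal (raw maximum available via `absolute_peak`); ties take the
  earliest frame;
* peak latency — `(argmax_post + 1) / rate` seconds, i.e. the first
  post-event frame reads 1/rate;
* onset latency — first post-window frame strictly above
  `baseline_mean + k * baseline_SD` (default k = 2, sample SD); NaN where
  never crossed. The strict inequality makes a flat trace report "no
  onset"; for continuous-valued data strict and non-strict agree almost
  surely;
* AUC — trapezoidal integral of the baseline-subtracted post window, with
  no re-zeroing at onset.

The latency bookkeeping presumes stimuli asynchronous to the camera clock
(an event falls strictly between frame starts, so the first at-or-after
frame is about one frame later). The synthetic generator therefore places
its default events mid-frame; boundary-aligned events would shift measured
latencies one frame relative to continuous-time truth.

## Connectivity

Seed-pixel maps are Pearson correlations between a seed trace (a pixel, or
the unweighted mean over an ROI mask) and every pixel trace. ROI matrices
correlate unweighted ROI-mean traces pairwise; note that correlating means
is not the mean of correlations, except for single-pixel ROIs. Fisher
z is `arctanh(r)` with r clipped to `+/-(1 - 1e-7)` so identical traces
(exact r = 1, common in synthetic data) stay finite; the z diagonal is NaN.
Matrix subtraction against a reference session operates in r- or z-space,
demands identical ROI name order (a permutation is an error, not a silent
reorder), and the two spaces always agree in sign. The SD map is the
per-pixel sample standard deviation over time.

## Registration

A similarity transform (rotation `theta`, isotropic scale `s`, translation
`t`, about a center `c`, in pixel units, row/col order) maps
`T(p) = c + s R (p - c) + t`. Resampling is inverse-mapping
(`out(p) = img(T^{-1}(p))`, nearest or bilinear, out-of-bounds NaN).

* Landmark registration is the closed-form least-squares similarity
  (Umeyama/Procrustes) over matched point pairs; it is exact (RMS 0)
  whenever the target really is a similarity image of the source, and needs
  at least two non-coincident pairs.
* Automatic registration maximises histogram mutual information (32 bins
  by default, computed over the finite overlap). The optimiser is
  deterministic: a coarse grid over rotation (±15°) and scale (±10%) with
  the translation per grid point estimated by FFT cross-correlation
  (NaN filled with the image mean to avoid artificial edges), followed by
  Nelder-Mead refinement from the four best candidates. The initialization
  is always retained as a candidate, so the result never has lower MI than
  it. The transform is estimated on single frames (in batch use, a temporal
  mean image) and applied to all frames and channels.
* Inter-subject registration applies only scale and translation
  (rotation fixed at 0): `scale = pixel_ratio_target / pixel_ratio_ref`
  with pixel ratios in pixels per physical unit (px/mm), anchored on a
  named skull landmark (Bregma by default). The returned transform is the
  pull-back map from the reference grid into target coordinates — the map
  used directly by inverse resampling — so a target recorded with pixels
  twice as large gets scale 0.5; apply it as
  `apply_transform(target, T.inverse())` to land the target on the
  reference grid.

Transforms persist as JSON (`tform_info.json` style) with a schema version;
round trips are exact, and a non-positive scale fails validation.

## ROIs

Pixel centers sit at integer coordinates. Circles include boundary pixels
(distance <= radius); polygons use the even-odd rule with points on an edge
counted inside (a hand-rolled vectorised ray cast — the brute-force
point-in-polygon scan is kept in the tests as an independent oracle).
Threshold ROIs select strictly above/below a cutoff and freeze the mask at
creation. Combination is boolean union/intersection/AND-with-mask (the last
for cropping to the visible-cortex field). ROI files store geometry where
possible (so ROIs survive re-registration by transforming coordinates);
mask-kind ROIs are run-length encoded. Trace extraction is the per-frame
unweighted mean over mask pixels, excluding missing values, and is linear
in the stack.

## Group statistics

Per-ROI metrics aggregate into one long table (subject, group, acquisition,
timepoint, modality, ROI, metric, value) with deterministic row order;
acquisitions lacking metrics are reported, never silently dropped.

The automatic test dispatch follows the structure of the data: normality is
assessed by Shapiro-Wilk per group (on paired differences for pre/post
designs) and homogeneity of variance by median-centred Levene, both at
alpha = 0.05 — these specific tests are the package's choice of criterion
implementations. Two independent groups get an equal-variance t-test when
both assumptions pass, Welch when only normality does, Mann-Whitney U
otherwise; paired designs get a paired t-test or Wilcoxon signed-rank;
three or more groups get one-way ANOVA or Kruskal-Wallis; group-by-time
designs get a two-way ANOVA (type-II, interaction F reported as the
headline statistic) when all cells pass normality and Levene passes, else a
per-timepoint two-group dispatch with Holm correction — there is no
standard nonparametric two-way test, which is a documented limitation.
Groups smaller than three cannot be normality-tested and fall back to the
nonparametric branch with a warning. Repeated-measures modelling is out of
scope; the two-way ANOVA treats timepoints as independent cells.

The pre-testing procedure mildly inflates the realised type-I error of the
downstream test (a long-run null rejection rate near 0.052 rather than
0.050 at n = 15/group in our simulations) — an inherent property of
assumption-gated dispatch, shared by any implementation of it.

## Synthetic generators: what they emulate, and what not

Each generator returns machine-readable truth alongside data and is
bit-deterministic for a fixed seed on one platform.

* **Hemodynamic mixture** — reflectance channels oscillate around baseline 1
  (sinusoidal artifact, ~10% amplitude, spatially weighted); fluorescence
  is `sum beta_i refl_i + clean + N(0, 0.01)` per pixel, with the clean
  signal a sinusoid at a distinct integer-cycle frequency so it is exactly
  orthogonal to the artifacts and the betas are identifiable. The 10%
  artifact amplitude was set from the OLS standard-error formula
  `sigma_n / (sigma_refl sqrt(T))` so coefficient recovery is
  noise-limited but well-determined in a 100 s recording.
* **Evoked responses** — Gaussian spatial blobs with a double-exponential
  time course `(1 - e^{-t/rise}) e^{-t/decay}` (normalised to unit peak;
  analytic peak time `rise ln(1 + decay/rise)`), GCaMP6-like kinetics
  (rise 0.15 s, decay 0.8 s), 5% dF/F amplitude, events every 10 s placed
  mid-frame. Truth includes the exact AUC integral over the sampled post
  window and the noise-free threshold-crossing frame.
* **Connectivity** — region traces are `loading * z(t) + noise` with a
  shared latent factor; the closed-form pairwise correlation is returned.
  Default loadings (1.0, 0.8, 0.6, 0.4) with latent sigma 0.03 put all
  pairs in the moderately-to-strongly correlated regime typical of
  mesoscale resting state; near-zero pairs are avoided in the defaults
  because their sampling SD `(1 - r^2)/sqrt(T)` is maximal, and the
  zero-loading case is exercised separately at its own `1/sqrt(T)`
  tolerance.
* **Vessel images** — smoothed random-walk dark curves on a bright slowly
  varying background, displaced by a known transform for registration
  tests.

None of these emulate photon/shot noise, realistic hemodynamic response
functions, motion, bleaching or optical vignetting. Passing against them
demonstrates correctness of the estimators under their stated models —
identifiable linear mixing, known response shapes, stationary latent-factor
correlation — not robustness to every artifact of real recordings.

## Problem sizes

Default study scale is deliberately desk-sized: 64 x 64 pixels, 600-2000
frames, up to 4 channels; the batch-processing check uses a 200-acquisition
project of 40-frame 16 x 16 recordings. These sizes exercise every code
path (including the batched per-pixel linear algebra) while keeping the
full verification suite interactive.

## Known limitations

* Hemodynamic regression assumes the artifact is linear in reflectance and
  shares no spectrum with the neural signal; correlated signal/artifact
  components are absorbed into the betas.
* MI registration searches ±15° rotation and ±10% scale by default; larger
  displacements need an initialization (e.g. from landmarks).
* Mask-kind ROIs are resampled by nearest neighbour under re-registration;
  geometric ROIs transform exactly.
* The statistics module covers the four supported designs only; mixed
  models, permutation tests and repeated-measures ANOVA are out of scope.
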