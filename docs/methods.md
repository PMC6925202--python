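# Methods

This note documents the models, estimators and numerical choices behind
`mps-scope`, and what the synthetic scenes do and do not establish about real
data.

## The structure being quantified

Axons are lined by a membrane-associated periodic scaffold (MPS):
circumferential actin rings connected by ~190 nm spectrin tetramers, giving a
~185–190 nm longitudinal repeat. In single-molecule localization microscopy
(SMLM) the scaffold appears as periodic bands along the axon; in
platinum-replica electron microscopy (PREM) of unroofed neurons each ring
appears as a *braid* of two long intertwined actin filaments, spaced ~184 nm,
with an apparent single-filament thickness of 9–11 nm after rotary shadowing
with ~2 nm of platinum. The package quantifies the repeat distance
("spacing", *s*), the strength of the periodicity ("autocorrelation
amplitude"), and braid morphometrics (spacing, width, length), and registers
the two modalities with a control-point affine transform.

## Periodicity estimation

**Profiles.** An axon tracing is a polyline in physical nm coordinates
(origin at the top-left pixel center, y down). The path is resampled at a
uniform arc-length step equal to the reconstruction pixel size (default
16 nm, the analysis grid), and intensity is averaged over a configurable band
perpendicular to the local path direction using bilinear interpolation. The
band defaults to 160 nm — the scale of an axon's width — because profile
quality, not the period estimate, depends on it; it is a free parameter.

**Autocorrelation.** The normalized *biased* estimator is used:

    AC(k) = Σ_i (v_i − v̄)(v_{i+k} − v̄) / Σ_i (v_i − v̄)²

Normalizing by the full-length sum (independent of lag) guarantees
AC(0) = 1 and |AC(k)| ≤ 1, at the cost of a linear taper (a factor
≈ 1 − k/N) that is negligible for tracings ≥ 20 periods. The unbiased
(overlap-normalized) variant does not bound |AC| and amplifies long-lag
noise; the biased form is standard for this analysis and is asserted against
the O(N²) defining sum in the tests. Zero-variance profiles raise an
explicit error rather than propagating NaN.

**Spacing.** The highest grid local maximum of the (usually tracing-averaged)
curve inside a search window (default 100–300 nm) seeds a least-squares
Gaussian-plus-offset fit over ±64 nm; the fitted center is the spacing *s*
and its standard error is reported. Ties between equal maxima resolve to the
smaller lag (first-peak semantics). A quadratic-vertex fallback is used when
the Gaussian fit fails (and is available as an explicit model; the two agree
within ~2 nm on well-formed curves). If the window contains no interior
local maximum — e.g. a drug-disrupted, non-periodic scaffold — the fit
raises a no-peak error instead of returning a number.

**Amplitude.** Periodicity strength is AC(192 nm) − AC(96 nm): the
approximate first peak minus first valley of a ~190 nm-period pattern. Both
lags are exact multiples of the 16 nm analysis step, so no interpolation is
involved on the default grid (linear interpolation covers other grids). The
fixed lags follow the published convention; an adaptive mode (fitted
peak/valley) exists but is off by default.

*A property worth knowing:* the amplitude is a **contrast** statistic, not a
sharpness statistic. For very sharp ring images (localization precision
below ~10 nm at 16 nm pixels) the intensity profile is a narrow-duty-cycle
comb whose autocorrelation valley at half-period is shallow, so the
amplitude is *lower* than for quasi-sinusoidal profiles at intermediate
smoothness. On synthetic scenes (period 190 nm, 10 seeds per point) the mean
amplitude is ≈1.03 at 5 nm precision, peaks ≈1.26 at 15 nm, then falls to
≈0.47 at 50 nm. Amplitude therefore decreases monotonically with degrading
precision only from ~15 nm upward, which is the regime of real SMLM data;
comparisons of amplitudes between conditions assume comparable localization
precision.

**Group statistics.** Two conditions are compared with a two-tailed
Mann–Whitney U test; three or more with a Kruskal–Wallis omnibus followed by
Dunn's rank-based pairwise z-tests under Holm correction (a parametric
switch to one-way ANOVA + Tukey HSD is provided). The non-parametric
post-hoc was chosen because a rank-based omnibus combined with Tukey's
(parametric) post-test is internally inconsistent; Dunn + Holm is the
standard rank-based counterpart. Summaries are mean ± SEM (sd/√n) with
significance codes ns/*/**/*** at 0.05/0.01/0.001.

## Rendering

Histogram mode (default) bins localizations into half-open [left, right)
pixels, conserving counts exactly — counts are what the autocorrelation
operates on. Gaussian mode deposits a unit-integral Gaussian per
localization (sd = `blur_sd`, or the per-record uncertainty), integrated
per pixel via error functions over a ±5 sd window, conserving intensity to
<0.1% when the emitter is ≥4 sd from the border. Image bounds default to
the tight bounding box of the localizations (padded 3 sd in Gaussian mode);
quantitative pipelines pass explicit bounds so the grid covers the full
nominal structure. Spacing estimates on synthetic scenes are insensitive to
the rendering mode.

## Morphometry

A distance data point is the mean of **five** traced parallel line lengths —
between consecutive braids for spacing, across one braid for width — kept
with its component values for audit. Profile-based widths are full width at
half maximum (FWHM) above the local background, with the background taken as
the median of the outer profile samples and sub-sample interpolation of the
half-maximum crossings. FWHM is this package's operationalization of
"width" on a replica image (the manual protocol does not define one); it is
validated against analytic Gaussian ridges and against the synthetic
coated-filament model, where a 7 nm filament with 2 nm of platinum reads
11 nm by construction. An optional obliquity correction multiplies the
width by the cosine of the angle between the cut and the ridge normal
(structure-tensor estimate); it is off by default to mirror the manual
protocol.

## Registration

The SMLM→EM map is a full 6-parameter planar affine fitted to ≥3
non-collinear control-point pairs by linear least squares; a
similarity-constrained mode (rotation + isotropic scale + translation,
closed-form) is available for low point counts. The reported residual is
the RMS *Euclidean* distance in the EM (target) frame — the frame where
biological distances are read. With per-coordinate fiducial noise σ and n
points, the expected residual is √2·σ·√(1 − 6/(2n)), which the tests verify
over seeds along with the absence of parameter bias. Overlays resample an
SMLM image into the EM grid by bilinear pullback, or transform localization
coordinates exactly and re-render them (no double interpolation).

## Synthetic scenes

**Localization scenes** place rings at k·period plus independent Gaussian
jitter along a straight axis (independent jitter, not cumulative drift,
matches the fixed-spacing autocorrelation model; axons are locally straight
at the 1–2 µm analysis scale). Each ring contributes Poisson-distributed
labels spread uniformly across the axon width — rings span the whole width —
blurred isotropically by the localization precision; a uniform Poisson
background covers the axon footprint; photon counts are log-normal
(positivity) and frames uniform. Defaults: period 185 nm, jitter 5 nm, axon
4 µm × 300 nm, precision 10 nm, 50 labels/ring, background 10 µm⁻²,
5000 ± 2000 photons, 30 000 frames. Period, analysis pixel and frame count
follow the study conditions; labeling efficiency and background are not
published anywhere for this preparation, so those defaults are realistic
round numbers chosen once for testability, not fidelity claims.

**Braid scenes** render each braid as two parallel ridges of Gaussian
cross-section whose FWHM equals the apparent coated-filament width
(diameter + 2 × coating = 11 nm by default), separated laterally by
`braid_gap`. The default gap of 9 nm leaves the pair merged into a single
ridge measuring ≈18 nm FWHM — matching the observed braid thickness, which
exceeds a single filament but is less than two resolved filaments
(intertwined filaments are laterally offset, not perfectly stacked). A gap
of 0 superposes them exactly (and then measures a single-filament width);
gaps ≳3× the filament width model the split state. Noise is additive
Gaussian. No electron-optics image formation is modeled.

**Correlative scenes** express one ring geometry in both frames: rings
generate the localization table, and their centerlines mapped through a
known affine become the EM braid ridges; fiducial pairs (with optional
jitter) provide control points, and the true transform is stored in the
ground truth.

All generators are pure functions of their seed (bit-identical output for
identical parameters), and ground truth records ring positions, centerlines,
per-ring label counts and background counts so conservation is assertable.

**What passing tests show — and don't.** The synthetic scenes establish that
the estimators are correct and unbiased under the generative model
(straight axons, stationary period, isotropic noise, uniform background,
no drift, no photophysics, no sample distortion between modalities). They do
not establish robustness to curved or varicose axons, spatially varying
labeling, blinking artifacts, or EM replica distortions — on real data those
effects enter through the manual tracing and control-point steps, which
remain inputs here exactly as in the manual workflow.

## Problem sizes in the bundled analyses

The test suite and the acceptance script run entirely on synthetic scenes:
4 µm axons (≈22 rings, ~1100 localizations), 10 seeds per condition for
spacing/amplitude, 5 braid images (≈5 braids each) for morphometry, and 20
seeds for registration — sizes at which every estimator's sampling error is
well below the tolerances being checked, while a full run stays in the
seconds range.
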