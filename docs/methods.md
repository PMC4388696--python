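# Methods

This note documents the models and procedures implemented in `divlayers`,
the conventions and defaults chosen where the underlying analysis admits
more than one reasonable reading, and what the synthetic-data generators do
and do not emulate.

## Coordinate conventions

All coordinates are continuous nanometres. The per-cell frame has its origin
at the cell centre, x along the long axis and y along the short axis
(right-handed; `to_cell_frame` is a rigid rotation + translation and is
exactly invertible). Because a 2D image cannot distinguish the two sides of
the cell axis, displacements along the short axis are reported as absolute
values wherever a cross-cell average is formed. Image rendering uses
half-open bins `[k·p, (k+1)·p)` anchored at the minimum corner of the data
(deterministic; counts are conserved exactly when no smoothing is applied),
with a 15 nm default pixel.

The localization CSV dialect (`x_nm, y_nm, z_nm, frame, channel,
precision_nm`, one header row) is an artifact decision — the reader also
accepts common SMLM export aliases such as `x [nm]`.

## Synthetic data: what it emulates

The generators produce data with exactly the statistical structure each
estimator assumes, which is what makes parameter recovery a meaningful
validation:

* **Ring/band**: molecules on a cylindrical shell of radius d/2 about the
  long axis; long-axis positions Gaussian with FWHM w. Band width is
  *defined* as this FWHM throughout the package, so generator and
  measurement are self-consistent. Defaults (d = 689 nm, w = 115 nm,
  20 nm lateral / 17 nm axial precision, 600 molecules per ring, no
  background) are the conditions of the measurements the package validates;
  the molecules-per-ring count is a free parameter chosen to give images
  comparable to typical live-cell PALM data.
* **Two-color**: channel 2 is an independent detection of the same true
  molecules, shifted by a known `shift_y` along the short axis, with its own
  localization noise plus isotropic registration noise (default sd 18 nm,
  the registration error of a bead-calibrated two-channel setup).
* **Radial clusters**: radius from N(μ_r, σ_r) with negative draws rejected
  and redrawn (rejection ≈ 1% at 280/120 — negligible bias), or uniform
  over a disk of radius R; angle uniform on [0, 2π); the observable is
  r′ = |r cos φ|.
* **iPALM layers**: a surface-dye channel at z = 0 with 10 nm FWHM and
  protein layers Gaussian about their depths with 17 nm axial sd.
* **FRAP**: 120 frames at 2 s (30 frames/min for 4 min), photobleach during
  frame 2; the bleach-ROI trace recovers as
  floor + (plateau − floor)(1 − e^(−kt′)) from the first post-bleach frame,
  the midcell ROI is constant at the prebleach level, and both get Gaussian
  noise (default sd 0.05 of prebleach).

Not emulated: fluorophore photophysics (blinking, repeated localizations of
one molecule), camera noise, drift, cell-to-cell variability of ring
geometry, cell curvature in z, and photobleaching during FRAP imaging.
Passing recovery tests therefore shows the estimators are unbiased under
their own model assumptions — not that those assumptions hold in any given
real dataset.

## Band morphometry

**Width.** A Gaussian (plus constant baseline) is fitted to the 15 nm-binned
long-axis density; the width is its FWHM, 2√(2 ln 2)·σ. When the table
carries per-localization precision, the localization error is removed in
quadrature (σ² → σ² − ⟨precision²⟩), so the reported width estimates the
molecular distribution rather than its blurred image; at 20 nm precision the
uncorrected width of a 115 nm band would read ≈ 124 nm. Samples narrower
than one bin are flagged as degenerate.

**Diameter.** The short-axis projection of a shell of radius R has density
∝ 1/√(R² − y²), diverging at ±R. The profile is histogrammed (15 nm bins),
smoothed (Gaussian, 1 bin sd), and local maxima with prominence ≥ 10% of the
profile maximum are found; the diameter is the distance between the two
most distal (outermost, not tallest) peaks, refined to sub-bin accuracy by
parabolic interpolation. Blur pulls the peak of a blurred (R − y)^(−1/2)
edge inward by 0.765·σ_blur (the argmax of the blurred edge profile,
computed by numerical quadrature), so the measurement adds
2 × 0.765·σ_blur back, with σ_blur² = ⟨precision²⟩ + (smoothing sd)² +
bin²/12. Without this correction the diameter of a 689 nm ring at default
noise is underestimated by ≈ 6%; with it, recovery bias is ≤ 1.3% across
400–800 nm. Cells with fewer than two qualifying peaks raise a
no-diameter error and are recorded as unmeasurable.

**Aggregation and comparison.** Per-cell values are summarised as mean ±
standard error. Group comparisons use Welch's two-sample t-test (the
appropriate default when group variances differ); two zero-variance groups
with equal means return p = 1 by convention. The diameter-diameter relation
between two co-imaged species is an unconstrained OLS line; its x-intercept
halved estimates the radial separation of the two layers, valid when the
diameter difference is constant through constriction.

## Colocalization

Registration is a least-squares affine map of channel-2 control points onto
channel 1 (≥ 3 non-collinear pairs; collinearity raises a rank error). The
RMS post-fit pair distance is the registration error; with 9 nm isotropic
noise per channel per axis it is √(4·81) = 18 nm.

The cross-correlation is computed on coordinates, not rendered pixels, with
a Gaussian kernel of bandwidth h = 30 nm (near the localization precision)
on a signed displacement grid ±300 nm in 5 nm steps; the reported apparent
displacement is |argmax C(Δ)|, ties broken toward smaller |Δ|. A curve with
no structure is flagged rather than reported. The exact kernel and
normalization of this statistic are a design choice of this package; the
constant prefactor does not affect the argmax. The double sum is evaluated
in row chunks; it equals the naive double loop to floating-point accuracy.

## iPALM z-estimation

The coverslip surface is located by a Gaussian fit to the 1 nm-binned z
histogram of the surface-dye channel (fits wider than 50 nm FWHM trigger a
quality warning). Per cell, the mean z is taken over molecules inside a box
at the bottom of the cell — z ∈ [z₀, z₀ + 150 nm], |y| ≤ 100 nm by default —
which automates what is otherwise a manual box placement; cells with < 10
in-box molecules yield a missing value. Species displacements carry an
uncertainty of √(s₁² + s₂²) from the two label sizes (≈ 5.7 nm for two
~4 nm fluorescent-protein labels), optionally combined in quadrature with
both standard errors; label-only mode reproduces the pure label budget.

## Radial placement models

Cluster detection binarizes a rendered image at a fraction of its maximum
(default 0.2), labels 8-connected components, and reports each component's
intensity-weighted centroid, second-moment-ellipse major axis and
eccentricity, and localization count.

Projected short-axis displacements r′ are binned at 60 nm and compared as
unit-area histograms (the count-vs-density choice is immaterial after
normalization). The Gaussian-radius model has no closed-form projected
density, so candidates on a (μ_r, σ_r) grid are scored by simulating 1000
projections per candidate (configurable) and summing squared density
differences; a common random seed across candidates (common random numbers)
keeps the objective surface smooth enough for a grid argmin. The
uniform-disk model uses the analytic projected density integrated per bin
and a 1 nm r_max grid. Both fits warn when the minimum lands on the grid
boundary. The disk fit attaches the closed-form radial moments mean = 2R/3
and sd = R/√18. A useful identity, tested for several radius
distributions: E|r cos φ| = (2/π)·E[r].

Long-axis cluster positions are reported as binned means by cell length;
no model is fitted to them.

## FRAP

Frames are numbered from 1; the photobleach occurs during frame 2, so frame
3 is the first post-bleach acquisition. Traces are screened by the bleach
ratio (I(1) − I(3))/I(1) > 0.40 — the only bounded-in-[0,1] reading of the
ratio consistent with a "greater than 40%" criterion. Normalization sets
frame 3 to exactly 0 and uses the mean midcell intensity over frames 61–120
as the maximum, because the tail of the bleach-ROI trace is noisy while the
whole-midcell trace is stable. The accepted traces are averaged pointwise
and fitted with A(1 − e^(−kt′)) by nonlinear least squares (A bounded in
(0, 1.2], since plateaus below full recovery are the norm; k > 0), with
τ½ = ln 2/k; fitting the average rather than per-trace fits is the default
mode. The bootstrap resamples whole traces with replacement (default 3000
resamples), refits each resampled average, and reports the sd of the
bootstrap half-times as the standard error; individual resample fit
failures are skipped and counted, with > 5% failures escalated to an error.

Note an algebraic consequence of this normalization: with a constant
midcell trace, a generator plateau p and bleach floor f, the fitted
amplitude is A = (p − f)/(1 − f), not p (e.g. 0.75 at p = f-complement
0.8/0.2) — the recovery tests assert the former.

## Expression calibration

With a reference fusion at a known fraction f_ref of total (wt + fusion)
protein and wild-type copy number N_ref, the per-molecule intensity is
k_int = I_ref / (f_ref/(1 − f_ref)·N_ref); any fusion's copy number is
I/k_int and its fraction of total is copies/(endogenous + copies). The
alternative reading of the known fraction (relative to wild-type alone) is
available behind a flag but is not the default. Fractions are reported to
0.1% — e.g. the worked reference triple (46,000 a.u., 30%, 5,000 copies)
gives 46.7% for a 94,000 a.u. fusion over 5,000 endogenous copies, and
11.0% for 40,000 a.u. over 15,000 — values that round to the conventional
5%-grid statements of 45% and 10%.

## Problem sizes and determinism

All generators and both simulation-based fits are deterministic given a
seed; the acceptance script derives all sub-seeds from a single `--seed`.
Default problem sizes (10⁵ draws for projection means, 50 cross-correlation
replicates of 500-molecule rings, 54 morphometry cells, 59 FRAP traces,
125 + 315 iPALM cells, 100 OLS replicates) were chosen so that Monte-Carlo
error is comfortably below each quantity's reported precision while the
whole recomputation stays under a minute on one CPU.

## Known limitations

* Cell frames are inputs; there is no segmentation of cells from
  transmitted-light images.
* The cross-correlation kernel/normalization and the Welch test are
  explicit design choices where the analysis chain admits alternatives.
* The width measurement assumes a Gaussian band profile; strongly bimodal
  or non-planar structures should be excluded upstream.
* The blur correction for diameters assumes the localization precision
  column is trustworthy and the ring is thin compared to its radius.
* No correction for photophysics-induced overcounting; cluster
  localization counts are localization counts, not molecule counts.
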