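# Methods

This note records the models, conventions and numerical choices behind
each stage, the reasoning where the design was genuinely open, and what
the synthetic tests do and do not demonstrate about real recordings.

## Receptive-field model and kernel fit

A photoreceptor's angular sensitivity is modelled as an elliptical,
axis-aligned 2D Gaussian with standard deviations σ_h, σ_v (degrees).
The response to the drifting dark square is small (≤ 5 mV) so the cell
is treated as linear: the measured RF map is the kernel convolved with
the stimulus target.  The model map is computed as a discrete 2D
convolution on the raster grid:

* the target is rendered as per-cell **area fractions** of the square,
  so its integral is exact for any sub-cell placement;
* the Gaussian is sampled on the grid at the kernel centre and
  normalized to **unit discrete mass**.  Unit-sum normalization (rather
  than the midpoint rule pdf×Δ) makes the convolution
  amplitude-preserving in both limits — a wide kernel behaves as the
  continuous unit-integral Gaussian, a sub-cell kernel degenerates to a
  discrete delta — which is what lets `amplitude` mean "response to a
  fully resolved dark target" at every σ;
* the axis-aligned Gaussian is separable, so the 2D convolution is two
  1D passes (`scipy.ndimage.convolve1d`, zero-padded edges).

The fit minimizes the summed squared difference between model and
observed map by Nelder–Mead over (x₀, y₀, σ_h, σ_v, A).  Settings:
parameter tolerance 1e−4 deg, at most 2000 evaluations per start, five
starts (the raster peak and the four cells one step away, with σ
initialized from the raw-map second moments minus the rendered target's
— a moment-based deconvolution guess).  σ enters the model through its
absolute value so the simplex can cross zero without failing; the best
SSE across starts wins and non-convergence is reported as a flag, not an
exception.  A flat map, or a peak below 3× the robust (MAD-based) noise
estimate, is rejected.

Two kernel modes are provided because the source protocol is ambiguous
about whether one shared σ or two were fitted while both horizontal and
vertical acceptance angles are reported: the default fits independent
σ_h and σ_v; `isotropic=True` shares one σ.

**Acceptance angle.** Δρ = 2√(2 ln 2)·σ, the FWHM of the Gaussian
kernel — the standard definition of the acceptance angle.  The vertical
component is the conventional single-number Δρ.

**Raster geometry.** The protocol's stated numbers (61 raster lines at
0.15° over a 6° ROI) are mutually inconsistent (61×0.15 ≈ 9°).  The
package keeps `n_lines` and `line_spacing` independently configurable
and defaults to 61 lines with spacing = roi/(n_lines−1) = 0.1°, honouring
the ROI size and line count and letting the resolution follow.

**Gridding and baseline.** Line-by-line traces are gridded by mapping
each post-stimulus sample to the raster cell implied by the drift speed;
the mean of the 0.5 s pre-stimulus window is subtracted per line and
repeats are averaged pointwise.  Responses are hyperpolarizations
(dimming of a dark target); traces are negative-going and the analysis
stores and fits positive magnitudes.

**Bar-sweep localization.**  The response extremum of a sweep occurs
when the bar centre crosses the RF centre, delayed by the cell's latency
τ, so a single-direction position estimate is biased by exactly
velocity×τ and the midpoint of opposing directions cancels the bias.
Because a 5°-wide bar saturates a ~1° RF, the response has a flat-bottom
plateau and the sample-wise extremum is noise-fragile; the extremum time
is instead the midpoint of the two half-depth crossings, located by
linear interpolation (sub-sample accurate, exact for the symmetric
profiles a straight bar produces).  The detection threshold defaults to
4× the pre-stimulus noise SD.

**Screen transform.** Pixel offsets from the screen centre convert to
angles by arctan(physical offset / viewing distance) per axis — the flat
stimulus screen at 200 mm needs the tangent correction beyond ~10°.

## Eye mapping

Facet coordinates (fₓ, f_y) observed at grid directions sample a smooth
map from direction to the ommatidial lattice.  In the Lambert
cylindrical equal-area chart scaled to degrees,

    u = longitude,  v = (180/π)·sin(latitude),

one unit of chart area is one true square degree, so the Jacobian
determinant ∂(fₓ, f_y)/∂(u, v) *is* the ommatidial density ρ in facets
per square degree, with no residual cos-latitude factor.  The
hexagonal-lattice conversion Δϕ = √(2/(√3 ρ)) assumes each ommatidium
occupies a hexagonal cell of area (√3/2)Δϕ² — the geometry of real
ommatidial lattices and of the cited pseudopupil literature.  Only the
local *average* Δϕ is reported; direction-resolved (anisotropic)
interommatidial angles are out of scope.

**Why a global surface fit.**  Observed facet coordinates are integers:
the pseudopupil centres on a whole facet, which quantizes a smooth map
with ±0.5-facet error.  Per-node differencing amplifies that noise —
with 10° grid steps and Δϕ = 3° a 3×3 affine Jacobian fit shows worst
node errors above 10% — while a single smooth surface fitted to the full
field averages it away.  `build_eye_map` therefore defaults to fitting
one bivariate polynomial per facet coordinate in (u, v), with one shared
total degree selected by BIC over 1..6 (BIC's conservative penalty keeps
the degree low when residuals are dominated by quantization), and
differentiates analytically.  The per-node estimator
(`local_density`, equally weighted least squares over the 3×3
neighbourhood with longitude steps scaled by cos latitude) remains
available via `method="local"` as the transparent, assumption-light
cross-check.

Nodes without an observation, or where the fitted Jacobian is
non-positive (lattice fold-over — typically the steep dorsal edge of a
strongly graded field), are flagged and hold NaN; they are filled from
the nearest valid node for contour tracing only and never reported as
values.  Contours are marching squares (`skimage.measure.find_contours`)
on the node grid in (longitude, latitude) space, clipped to the
visual-field boundary polygon with shapely.

## Ommatidial optics

White-light optical sensitivity uses the standard
apposition-eye (Kirschfeld/Land) form

    S = (π/4)²·D²·(d/f)²·k·l/(2.3 + k·l)   [µm² sr]

where the last factor is the fraction of entering light a rhabdom of
length l absorbs, with the broad-spectrum constant 2.3 = ln 10.  This
reconstruction is pinned by test: it must reproduce both published
acute-zone sensitivities (0.20 and 0.14 µm² sr) from the published
morphology (D = 29/26 µm, f = 67 µm, d = 2.1/1.9 µm, l = 227/255 µm,
k = 0.0067 µm⁻¹) at two decimals.  Defaults: f = 67 µm, k = 0.0067 µm⁻¹,
λ = 0.53 µm (green light) for the Airy half-width λ/D.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the analysis
assumes: Gaussian angular sensitivity; negative-going (hyperpolarizing)
responses to dark targets; additive i.i.d. Gaussian recording noise; a
fixed response latency that shifts bar-sweep extrema by v·τ and raster
maps by drift_speed·τ along the drift axis; and hexagonal facet lattices
generated from smooth separable density fields Δϕ²(u, v) = p(u)·q(v)
whose planar map (∫du/p, ∫dv/q) passed through the inverse hexagonal
basis has *exactly* the target density everywhere, then rounded to the
integer facet a pseudopupil would single out.

Defaults are the study's stimulus conditions: 5°×144° bar at 96 deg/s,
dark square (Weber contrast −0.998) of 1.5/2.0/3.0° drifted at 48 deg/s
through a 6° ROI in 61 lines, 0.5 s pre-stimulus, 10° facet grid over
longitudes ±100° and latitudes ±80°.  Response amplitude defaults to
3 mV with a hard 5 mV ceiling (the linearity regime of the small-signal
model); noise SD and sampling rate are unreported for the original
recordings, so they are explicit configuration with defaults of 0 mV and
one sample per raster cell (480 Hz), chosen for transparency rather than
inferred.  The built-in acute-zone field places Δϕ = 1.0° at longitude
15°, latitude −15° rising quadratically to 3.0° at the dorsal pole, the
qualitative layout of a vespid worker eye.

Passing recovery tests on these data shows the estimators are correct
and well-conditioned *under the model's own assumptions*.  They do not
probe electrode drift, spike-like artifacts, phototransduction
nonlinearity, non-Gaussian receptive fields, or pseudopupil digitization
errors beyond integer rounding — real recordings can fail in ways the
generator does not emulate.

## Statistics

Acceptance-angle collections are summarized boxplot-style: median;
quartiles by linear interpolation (type 7, the numpy default — the
original plotting software's convention is unknown); whiskers at
1.5×IQR with points beyond reported as outliers; and a notch-style 95%
CI on the median, median ± 1.57·IQR/√n.  Whether the source's published
CIs used the notch formula or a bootstrap is unstated; the notch is the
documented default and a percentile bootstrap is available without any
claim of equivalence.  For n = 1 the CI degenerates to the point and is
flagged.  Note the notch's actual coverage for Gaussian data is ≈91%,
so coverage checks must allow binomial noise around that rate.

## Pipeline determinism

All randomness flows from one master seed through
`numpy.random.SeedSequence` children (masked below 2³¹); every CSV is
written with a fixed `%.10g` float format; the manifest records the
configuration hash, seed, package versions and SHA-256 of every output,
and contains no timestamps — timings go to the log stream only.  Two
runs with the same configuration and seed are byte-identical, which the
test suite asserts.

## Problem sizes

Recovery studies use the full 61×61 raster per fit; the noiseless sweep
covers Δρ ∈ {1.0, 1.5, 2.0, 3.0}° × target ∈ {1.5, 2.0, 3.0}° (12 fits)
and the noisy sweep adds 20 seeds per combination at peak/noise = 10
(240 fits).  The simplex-vs-lattice comparison uses 12 instances against
a 3×3×5×5×5 parameter lattice.  Eye-map round trips use the full 21×17
direction grid.  The notch-coverage simulation uses 1000 replications of
n = 39.  These sizes give stable medians and maxima while keeping the
whole suite fast enough to run routinely.

## Known limitations

* Only the mean local Δϕ is mapped; vertical/horizontal anisotropy —
  real in lateral eye regions where the pseudopupil is elliptical — is
  not captured.
* Facet-coordinate quantization sets a noise floor on density recovery;
  with the default grid, worst-node Δϕ error is ~1–2% for constant
  fields and grows where the field is steep or the eye sparsely
  faceted.  Smoothing-degree selection (BIC) can flag fold-over at the
  extreme dorsal edge of strongly graded fields.
* The kernel fit assumes small-signal linearity and an axis-aligned
  Gaussian; rotated or non-Gaussian receptive fields are fitted only in
  projection.
* The acute-zone argmin is localized to the 10° grid; a minimum falling
  between nodes is attributed to an adjacent node by construction.
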