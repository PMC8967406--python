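# Methods

`chromashade` is a synthetic test bed for a perceptual claim: that the
wavelength-dependent albedo of pigmented translucent materials creates
color-borne information about 3-D shape.  The package implements the full
computational chain — subsurface photon transport, translucent-stimulus
rendering, CIELAB saturation analysis against surface geometry, and
paired-comparison psychophysics with synthetic observers — so that every
qualitative claim can be exercised end-to-end on data the package generates
itself.

## Surface geometry

Stimulus surfaces are graph surfaces z = f(x, y) ("bumpy planes") viewed
fronto-parallel from +z.  The generator draws white Gaussian noise on an
n x n periodic grid and filters it in the Fourier domain with
exp(-(pi L f)^2 / 2), leaving essentially no power above spatial frequency
2/L; the result is rescaled to a target RMS amplitude.  Defaults: n = 67
cells at 0.25 model units (a 16.75-unit tile), amplitude 0.5, correlation
length L = 3.0.  These were chosen so that (a) several distinct bumps span
the image, as in the study's stimulus, and (b) the bump wavelength is large
compared with the photon mean free path (0.5 units), so shallow scattering
preserves shading structure — the regime the study's images occupy.

Principal curvatures come from the first/second fundamental forms of the
graph surface via central differences; the sign convention makes
convex-toward-the-viewer positive, and the one-cell grid border (where the
differences are one-sided) is masked.  The shape index is

    s = -(2/pi) * atan2(k1 + k2, k1 - k2),  k1 >= k2,

so symmetric convexities score -1, saddles 0, symmetric concavities +1, and
the statistic is invariant to the overall amount of curvature.  Region
classes cut the range into equal thirds at |s| = 1/3 (the source analysis
names the three classes without stating cutoffs); display grays follow
(1 - s)/2 so concavities plot darkest.

OBJ meshes are supported by resampling onto a height grid with vertical ray
casting (barycentric point-in-triangle tests in the xy projection, exact
for graph-like meshes).  Curvature is always computed on the resampled
grid, not per-vertex: the stimulus is a height field by construction.

## Photon-beam simulator

The beam simulator reproduces the published diagram setup: a corrugated
boundary of circular arcs (ridge radius 1.1148, centre separation 2.0268,
valleys centred at sqrt((2r)^2 - sep^2) above the ridge line so arcs join
tangentially), refractive indices 1.3 inside / 1.0 outside, photons entering
vertically at the ridge/valley inflection point.  Free paths follow
P = 0.001 - alpha ln(beta) with beta uniform on (0, 1] and alpha = 0.5
(inverse pigment density); the 0.001 offset is implemented literally.  Each
collision absorbs the photon with probability 1 - albedo or scatters it
into a uniformly random 3-D direction (Henyey-Greenstein when the
anisotropy g is nonzero).  Boundary hits are solved by line-circle
intersection against the in-profile (x, z) components, with arc-half
validity checks so only true boundary arcs count; the profile tiles
periodically in x, so laterally wandering photons never escape the
corrugation.  Exit versus internal reflection is decided by Schlick's
approximation with total internal reflection detected from Snell's law
first and, when leaving the denser medium, the transmission-side cosine in
the (1 - cos)^5 term.  Entry specular reflection is ignored (all photons
enter).  After an internal reflection the photon continues the remaining
free path; photons are capped (reported, not dropped) at 10^5 events.

## Renderer

The renderer is this package's stand-in for a production physically-based
renderer: it applies the same transport physics to a height-field boundary
and accumulates exiting photons into an orthographic 67 x 67 pixel grid,
weighted by max(0, cos of the exit direction toward the viewer).
Illumination is one directional source at elevation 0-90 degrees from the
viewing direction (0 = frontal, 90 = from above, in the y-z plane) plus a
cosine-weighted hemispheric ambient term carrying 25% of the energy.
Because the study varied illumination by rotating one light map, the
directional component's integrated power is normalized to be
elevation-invariant.  Shadowing of one bump by another and multi-crossing
steps over air gaps are ignored; the medium is treated as semi-infinite by
dropping photons deeper than 10 mean free paths.

Estimator choices (these change precision, not expectation): absorption is
handled by weight attenuation (weight *= albedo per collision) instead of
binary killing; the Fresnel exit/reflect decision is split deterministically
(weight (1-R) exits, R continues); low weights are terminated by Russian
roulette below 0.005; entry points are stratified over pixel cells and the
first free-path draw is stratified across photons; at albedos below 0.5 the
first scatter is branched into eight polar-stratified directions at 1/8
weight (short walks make the branches cheap); and the exit map is
reconstructed with a periodic Gaussian kernel of 0.7 px (photon-mapping
style density estimation).  On an internal reflection a fresh free path is
drawn — exactly equivalent to continuing the remainder, up to the 0.001
offset, because the exponential is memoryless.  With these choices a
10^6-photon channel render resolves the 67 x 67 grid with a flat-field
coefficient of variation near 4%.

Channel coupling: all three wavelength bands of a stimulus are rendered
from the same seed, so bands with equal albedo are bit-identical; in
particular the R band of the red pigment (0.81, 0.13, 0.09) coincides with
the light-gray (0.81 uniform) render at the same seed.

sRGB encoding scales the 99.5th percentile of the linear image (all bands
jointly, preserving color ratios) to 1.0 and applies the IEC 61966-2-1
transfer function.  The Maxwell-style material settings the synthetic
pigment emulates (attenuation 4.29 mm, particle density 305.41, roughness
100) are carried as provenance metadata only; transport is parameterized by
(albedo, alpha, refractive index, g), and alpha = 0.5 was kept from the
beam simulator because it reproduces the intended qualitative channel
structure (shading-like dim bands, curvature-like bright band).

## Color analysis

Images are converted 8-bit sRGB -> linear -> XYZ(D65) -> CIELAB (2-degree
observer).  Saturation is sqrt(a*^2 + b*^2)/L*, the chroma radius relative
to lightness; pixels with L* < 1 are masked rather than divided.  Analyses
run at 67 x 67 (block-mean downsampling when the source is larger).  The
saturation-versus-G/B correlation concatenates the individually
range-normalized G and B vectors against a duplicated saturation vector;
the multilinear R^2 regresses saturation on G and B as two separate
predictors plus shape index (and, for the comparison model, on lightness
plus shape index).  All correlations are Spearman rank correlations.

## Psychophysics

The paired-comparison machinery presents every image pair once per
observer (C(14,2) = 91 pairs for the elevation experiment, C(21,2) = 210
for the albedo ladder) and scores each image by the proportion of its
comparisons won.  The "multivariate analysis of variance with planned
orthogonal contrasts" is implemented as within-observer contrast scores
c_i = sum_j w_j score_ij tested by a one-sample t, reported as F = t^2 on
(1, n-1) degrees of freedom — this reproduces the degrees-of-freedom
pattern of the published tests (e.g. F(1,10) with 11 observers).  Weight
sets for the 2 x 7 layout are the material main effect, the linear
elevation trend (-3..3, the standard orthogonal-polynomial weights for 7
levels), and their elementwise product; the three are mutually orthogonal.
Raw proportions are analyzed (no arcsine transform).  PSEs monotonize the
preference-versus-albedo function by isotonic regression (direction chosen
from the data) and interpolate the 50% crossing linearly; results carry a
method tag so a logistic fit could be swapped in.

## Synthetic observers

Human data are stood in for by a Thurstone Case V observer with lapses:
P(choose A) = (1 - lapse) Phi((u_A - u_B)/(sigma sqrt(2))) + lapse/2.
Three image-computable cues feed the utilities:

* shading — the RMS contrast of the shading-like component of the
  luminance image, obtained by regressing the band-mean image onto the
  clamped Lambert pattern max(0, n.l) of the generating surface.  Using
  the generative geometry is an ideal-observer shortcut for "how much
  shading structure is visible"; the regression form makes the cue robust
  to render noise, returns exactly the Lambert map's own RMS contrast for
  a stimulus proportional to it, and — because it weights bands by
  radiance — dilutes a chromatic surface's crisp-but-dim G/B shading with
  its bright deeply-scattered R band, which is what places the red
  surface's shape-clarity match at a mid-dark achromatic albedo rather
  than at its own darkest band;
* curvature — the convex-minus-concave mean-intensity difference of the
  highest-albedo band, relative to that band's mean; it grows with albedo;
* saturation contrast — the standard deviation of the CIELAB saturation
  map, identically zero for achromatic stimuli.

Shape-clarity utilities read w_shading * shading + w_saturation *
saturation; translucency utilities read w_curvature * curvature.  Defaults
(w_shading 1.0, w_saturation 0.25, w_curvature 1.0, sigma 0.02, lapse
0.02) were set from the measured cue scales so that the generative
observer reproduces the study's two qualitative behavioral patterns — the
chromatic surface preferred at every illumination elevation with scores
rising toward light-from-above, and a shape-clarity PSE at a darker
achromatic albedo than the translucency PSE.  All cue definitions live
behind `CueVector` so alternates can be swapped in; whether perceived
translucency tracks the curvature cue or saturation spread is left open,
and the curvature mapping is the default.

Model fitting recovers the identifiable ratio w/sigma (plus the lapse) by
maximum likelihood with L-BFGS-B multistart and a profile-likelihood 95%
CI.  The lapse is only identified when some trials are easy (|Delta u| >>
sigma); recovery tests therefore use stimulus sets whose cue spread
produces such trials.

## What the synthetic data do and do not show

The generator emulates: per-channel albedo-dependent subsurface transport,
sRGB stimulus statistics, the coupling between shading structure and
saturation, and choice data from cue-driven noisy observers.  It does not
emulate: image-based lighting with a real light map (a directional +
ambient approximation stands in), surface micro-roughness and speculars,
hyperspectral image formation, inter-observer heterogeneity, or any aspect
of human shape inference beyond the three summary cues.  Passing tests
therefore demonstrate internal consistency of the computational chain and
qualitative agreement with the published patterns, not quantitative
reproduction of human data or of the original renders.

## Problem sizes and numerical choices

Test-suite problem sizes: beam runs use 10^4 photons; single-channel
property checks use 10^6 photons; full stimulus sets for the end-to-end
behavioral checks use 2-3 x 10^5 photons per channel (cue statistics are
regression-based and stable at that budget); the pigment-density and
phase-function controls use 6 x 10^6 photons because a Spearman
correlation between two independently rendered maps needs per-pixel noise
well below the structure being compared.  Degenerate inputs are defined
rather than exceptional: flat geometry renders to a uniform finite grid,
all-zero images encode to zero, dark pixels are masked from saturation,
zero-variance inputs return flagged NaNs from correlation/regression, and
contrast tests with zero between-observer variance return a degeneracy
flag instead of an infinite F.

## Known limitations

* The renderer's boundary test only checks the end of each free-path step
  and the first crossing within it, so a step that exits and re-enters
  through an air gap in one move is treated as staying inside; with the
  default geometry (bump wavelength >> mean free path) such steps are rare.
* Directional entry ignores bump-on-bump shadowing, which matters most at
  grazing elevations; contrast at high elevations is therefore somewhat
  overestimated.
* The curvature estimator assumes a graph surface; meshes with overhangs
  resolve to their top surface.
* The Gaussian reconstruction kernel slightly blurs the rendered image
  (0.7 px against an ~12 px bump wavelength).
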