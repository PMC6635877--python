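# Methods

`organelle_stoich` quantifies the protein stoichiometry and mobility of
individual organelles — its motivating system is the β-carboxysome of
rod-shaped cyanobacteria, tagged with YFP on one shell or cargo protein —
from fluorescence image stacks. Because no public raw-image dataset exists
for this kind of acquisition, the package ships a ground-truth simulator
whose defaults emulate the two acquisition modes the analysis serves, and
every quantitative claim in the test suite is a recovery test against that
simulator.

## Image model and simulator

A cell is a spherocylinder (default length 3 µm, radius 0.5 µm) with its
long axis in the image plane. Two diffuse compartments emit background: an
inner cytosol and a thylakoid shell of configurable thickness (default
0.15 µm) whose chlorophyll emission bleeds into the detection channel. The
expected camera value of a pixel is

```
E[counts] = baseline + gain · (Σ_foci N_i · ν · m_i(px) + Σ_compartments ρ · depth(px) · A_px)
```

where `N_i` is the number of surviving fluorophores on focus *i*, `ν` the
photon emission per fluorophore per frame, `m_i(px)` the PSF mass in the
pixel, `ρ` a compartment's photon density (photons/µm³/frame), `depth` the
compartment's extent along the optical axis above the pixel, and `A_px` the
pixel area. Shot noise is Poisson on the photon scale, then scaled by the
camera gain; optional Gaussian read noise is off by default.

The PSF is a 3D Gaussian surrogate: lateral σ = 160 nm (2 px at the 80
nm/px single-molecule pixel size, giving fitted focus widths of ~250 nm),
axial σ = 400 nm entering only through defocus broadening
σ(z) = σ₀·√(1+(z/σ_ax)²). Pixel masses use the exact erf form. Organelles
(200 nm default diameter) are rendered as point emitters since their
diameter is below 2σ; a uniform-sphere surrogate (per-axis variance r²/5
added to σ²) is available but off by default.

**Photobleaching.** Each fluorophore bleaches independently at an
exponentially distributed time, sampled per frame as a geometric law with
hazard 1−e^(−λ); sub-frame bleaching within the 5 ms exposure is ignored
(the bleach timescale is hundreds of frames). The default rate λ = 0.01
/frame (mean bleach time 100 frames) is a plausible full-laser-power
single-molecule value; the paper-scale photon budget per fluorophore and
camera gain are not published for this kind of rig, so the defaults
(ν·gain between 200 and 1000 counts/frame depending on the scenario,
baseline 100 counts) are calibration knobs chosen once to give realistic
single-molecule signal-to-noise, not claims about any particular camera.

**Diffusion.** Brownian steps per axis are N(0, 2DΔt) per frame interval
(default Δt = 60 s, confocal pixel size 41.5 nm); positions reflect
specularly at the spherocylinder surface, which preserves the uniform
stationary density. The benchmark scene is three 200 nm organelles at
D = 1.3×10⁻⁵ µm²/s imaged for 40 frames.

All randomness flows from one seeded generator recorded in the
`GroundTruth` object, so identical configuration + seed reproduces stacks
bit-for-bit.

## Focus detection and photometry

Candidates come from a light Gaussian smoothing (σ = 1 px), a white top-hat
(disk radius 4 px) and a robust threshold (median + 5·1.4826·MAD of the
transform), with ≥ 3 px non-maximum separation. Sub-pixel centroids use
iterative Gaussian masking: the centroid of (image − local median)₊ × a
Gaussian mask is recomputed with the mask recentered until the displacement
falls below 10⁻³ px (mask σ = PSF σ, max 100 iterations; non-convergence
flags the measurement out). Candidates converging within 3 px of an
already-localized focus are treated as duplicates of it.

Intensity is the sum over a circular ROI of radius 5 px (pixel
center-in-circle membership, 81 px) minus n_inner × the mean of the
surrounding 17 × 17 px window with the inner disk excluded. The
signal-to-noise ratio is the background-corrected inner mean divided by the
outer-window sd, and foci pass only if SNR > 0.4 (strict). Foci whose
window leaves the image are flagged `edge-truncated` and excluded from
quantification.

Tracking is greedy nearest-neighbor per frame pair (foci are sparse):
candidate links sorted by distance, ties broken by the lower track id, no
link beyond the displacement cap, no gap closing by default. After a track
ends, photometry continues at its last centroid for a configurable number
of frames ("overtracking"), sampling single-fluorophore-level and
background-level intensities.

## Copy numbers from bleach traces

The characteristic single-fluorophore intensity I_unit is estimated from
the pooled distribution of intensities in the final portion of each track
plus its overtracked tail. Two practical details matter:

* Annulus photometry does not fully remove *structured* cell background
  (the ROI sits on the bright cell axis while the annulus includes dimmer
  cell edge), leaving a positive per-focus offset. The median of a track's
  post-bleach overtracked measurements estimates exactly that offset and is
  subtracted from the track's pooled values, so the background cluster
  lands at zero instead of imitating a small I_unit.
* Values below a noise floor (3× the background sd, estimated from the
  negative excursions of the pooled values) are excluded before the modal
  KDE peak is read off; the peak's half-width is quoted as the I_unit
  uncertainty and motivates the 0.5-molecule kernel used for periodicity
  analysis downstream.

The independent cross-check estimates I_unit from the periodicity of the
intensity distribution, whose mass sits at integer multiples of I_unit.
Because a plain power spectrum is invariant to shifting the distribution
(a single bump at K has a flat magnitude spectrum), the spectrum is
computed as the origin-anchored cosine transform C(f) = mean cos(2πf·Iₖ) —
intensity has a physical zero, so phase alignment at the origin is
meaningful. Its first significant non-DC local maximum sits at f = 1/I_unit;
if no peak clears the significance floor (default 0.3, ~3–4σ of the
n ≥ 50 sampling noise) the estimator raises and the caller falls back to
the endpoint method. On simulated data the two estimators agree within 15%.

A trace's copy number is its initial intensity divided by I_unit
(multiplied by any neutral-density attenuation factor used during
acquisition). Because the laser bleaches from the very first exposure, the
initial intensity is back-extrapolated to t = 0: a single exponential
A·e^(−kt) is fitted to the Chung–Kennedy-filtered trace with frames
attributed to mid-exposure (tᵢ = i + ½), and the first five frames divided
by e^(−ktᵢ) are averaged. Using the fitted *rate* but the measured early
plateau avoids the systematic amplitude overshoot a free least-squares
exponential exhibits on traces with only a handful of discrete steps (the
convex curve must cross a flat plateau twice, pushing A above it — several
percent at 5 copies, negligible at 300).

The Chung–Kennedy filter is the standard two-window edge-preserving
filter: each sample is the variance-weighted mean of its trailing-window
and leading-window means, weights ∝ variance^(−p) (window 10 frames,
p = 4). A window with zero variance wins outright, so noiseless plateaus
and steps pass through exactly.

## Population statistics

Distributions of per-organelle copies are summarized as the modal peak ±
half width at half maximum of a Gaussian-kernel density. "Standard" kernel
width means Silverman's rule; the explicit 0.5-molecule kernel is reserved
for resolving periodic features (pentamer multiples). HWHM is read from
linearly interpolated half-max crossings, the two sides averaged.

Background (chlorophyll autofluorescence) is removed at the distribution
level: corrected = max(sample − rate·background, 0), renormalized, with the
rate defaulting to the ratio of background foci per cell to sample foci per
cell. Peaks far from the background peak move by < 1%.

The triple-Gaussian decomposition is fitted to the KDE curve (not raw
values), seeded at the three tallest density maxima or at user-supplied
means. A three-component fit of a unimodal curve is degenerate — multiple
overlapping components can tile one bump — so components whose means lie
within 1.5× the wider sd of each other are merged afterwards
(area-weighted moments); vacated components carry zero area and a
degeneracy flag. Reported percentages are component *area fractions*.

The nearest-neighbor overlap model asks how often two organelles fall
within one diffraction-limited focus: organelle centers are uniform in the
2D projection of the cell (a stadium built with exact geometric
primitives), and a focus overlaps if a neighbor lies within the resolution
radius (default 250 nm, the measured focus σ). The analytic mode integrates
1−(1−a(p)/A)^(n−1) over positions p, with a(p) the resolution disk clipped
to the cell — an edge-corrected finite-area result — on a deterministic
grid; the Monte-Carlo mode places points directly (≥10⁵ placements). The
two agree within 3 Monte-Carlo sd for 2–20 foci per cell. The predicted
copy distribution of merged pairs is the self-convolution of the singles
density.

Confocal quantification uses prominence-gated regional maxima (h-maxima
transform, tolerance set from empty-region background), which also merges
twin peaks separated by a dip shallower than the tolerance; foci containing
saturated pixels are excluded. Cytosolic background is the mean central-line
intensity over non-focus positions, subtracted from each focus peak
(negatives clipped and flagged). Absolute calibration divides the
single-molecule copy-number peak by the confocal intensity peak of the same
strain under the reference condition; applying the factor to the reference
distribution reproduces the single-molecule peak exactly by construction.
Conditions are compared by two-sided Mann-Whitney U on functional-unit
values (fold change = ratio of medians; stars: *** for P<0.005, * for
P<0.05). Sampling error of a distribution peak is estimated by randomized
grouping (70–100 entries per group, sd/mean of per-group peaks) and flagged
when above 5%.

Functional units are subunit copies divided by the oligomer size (pentamer
5, hexamer 6, dimer 2, L₈S₈ Rubisco 8 via its small subunit), unrounded
until presentation.

## Diffusion analysis

Time-lapse stacks are first drift-registered by cross-correlation against
frame 0 at 1/20 px precision; frames are clipped at their 80th intensity
percentile before correlation so the stationary cell body, not the moving
organelles, anchors the shift estimate. Tracks reuse the greedy linker with
a search radius of √(4DΔt) plus a 3 px guard band.

The time-averaged MSD uses all start frames for lags up to half the track
length. The ensemble validation admits only tracks covering at least 80% of
the movie: a track fragmented by a single missed detection counts one
organelle twice, and short fragments yield unreliable single-track fits. The apparent diffusion coefficient is slope/4 of an OLS fit to the
first six lags **with a free intercept**: localization error adds a
constant offset to every lag, and the intercept absorbs it without biasing
the slope (the choice is recorded in the output metadata; at benchmark
noise levels forcing the intercept through zero changes the ensemble mean
by under a percent). A negative fitted slope reports D = 0 with a flag.
The anomalous exponent α is the log-log slope over all positive-MSD lags;
α ≈ 1 is Brownian, α < 1 subdiffusive (confinement), α = 2 ballistic.

## Problem sizes and what the tests show

The recovery benchmarks run at sizes chosen to make Monte-Carlo error
comfortably smaller than the tolerances they check: 100 replicate
simulations (300 tracks) for the diffusion validation, 200 organelles per
population for copy-number recovery, 2000 draws for mixture decomposition,
10⁵ placements for the overlap Monte Carlo. Copy-number population
benchmarks use the trace-level generator (identical bleach and noise model,
no image rendering) so that hundreds of organelles stay cheap; the
image-level chain is validated separately end-to-end on three-organelle
stacks.

Passing these tests shows the estimators are unbiased at realistic noise
under the simulator's assumptions. Real data differ in ways the simulator
deliberately omits: fluorophore blinking and immature (non-fluorescent)
tags (up to ~15% undercounting bias in practice), aberrated or spatially
varying PSFs, vignetting, cell-to-cell autofluorescence variability,
stage drift beyond pure translation, and non-Brownian motor- or
cytoskeleton-driven motion. Estimates on real stacks inherit those biases;
the package reports only what the images support (e.g. "apparent" diffusion
coefficients, since MSD curves bend at large lags).

## Numerical conventions

Coordinates are 0-based pixel indices, (x, y) = (column, row), origin at
the center of pixel (0, 0); physical conversions use the configured pixel
size. Degenerate inputs follow explicit rules rather than NaNs: a
featureless image yields zero candidates; zero background sd with positive
signal gives SNR = +∞ (accepted); all-zero traces give zero initial
intensity; all-tie condition comparisons give p = 1 with a warning; KDE
refuses n < 10; the grouped-error estimator refuses n < 2 × group size and
states the required n.
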