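# Methods

This note documents the models implemented in oligospot, the parameter
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical decisions that shape the results.

## 1. The forward model (synthetic data)

**Cell geometry.** A cell is the 2-D projection of a rod: a stadium (rectangle
with hemispherical caps) of length L and width W, positioned and oriented in
the image frame.  Cells longer than 9 µm are classified as filaments;
shorter cells are "unconstricted" or "constricted".  The membrane is the
outline band of the stadium, 0.1 µm wide — a projection of the inner
membrane, adequate for placement statistics but not a 3-D membrane model.

**Emitters.** Noncentral monomers are placed uniformly in arclength over the
membrane outline.  Midcell clusters are single point sources of k × 6
fluorophores (k copies of a hexameric unit), placed on the outline within
±0.5 W of the cell centre along the long axis: all copies are colocalized
below the diffraction limit, consistent with one diffraction-limited midcell
spot per cell.  Default k ranges follow division stage: 1–3 before visible
constriction, 4–7 early in constriction.

**Photophysics.** Bleaching is irreversible and memoryless: each emitter
survives each frame transition with probability 1 − k_b, so ensemble survival
is (1 − k_b)^t ≈ exp(−k·t).  Blinking is not modeled.

**Optics and camera.** The PSF is an isotropic 2-D Gaussian with
σ = 0.12 µm, roughly the diffraction limit at yellow-fluorescent-protein
emission; pixel values are centre-sampled (the integral over a pixel is
approximated by the PSF value at the pixel centre — exact to ~10⁻¹⁹ relative
at σ = 1.5 px by Poisson summation, and the PSF is truncated at 5σ).  Camera:
counts = offset + Gaussian read noise + Poisson(signal + autofluorescence) /
gain, with defaults 80 nm pixels, offset 100 counts, gain 2 photons/count,
read noise 2 counts — typical sCMOS values.  Cell autofluorescence
contributes a per-frame photon budget proportional to cell length (default
200 photons/µm), spread uniformly over the cell's interior pixels;
autofluorophore bleaching is not modeled.

**Photon budget.** Fluorophore brightness defaults to 400 expected photons
per frame.  Absolute brightness is a free parameter of the instrument, not a
calibrated value; all recovery tests are formulated relative to it (unit
intensity = photon rate / gain).

**Tracks.** 2-D Brownian displacements per axis ~ Normal(0, 2 D dt); reported
positions add independent Normal(0, σ_loc²) per axis.  `n_steps` counts time
points.  Motion blur within an exposure is not modeled, so recovered D has no
blur-induced bias term.  A reflecting-disc variant emulates
divisome-tethered confinement.

**Randomness.** Every generator accepts either an integer seed or a numpy
Generator; a given seed yields bit-identical output.  The pipelines derive
all randomness from the single config seed.

## 2. Spot quantification

Background is the median of the cell ROI excluding the fit window.  The spot
model is an elliptical Gaussian with free rotation θ ∈ [0, π) (an
axis-aligned mode exists), fitted by trust-region least squares with
moment-based initialization; σ_major ≥ σ_minor is enforced by relabeling.
The integrated intensity uses the analytic identity A·2π·σ_major·σ_minor, so
it never includes the fitted offset.  Amplitude ≤ 0 at the optimum flags
"no spot"; centres within 3 σ_major of the window edge are flagged, not
dropped.  The default 9 × 9 px window covers ±3σ of the default PSF.

For *dim single fluorophores* the free elliptical fit is biased (it latches
onto noise, overestimating amplitude and underestimating the minor width by
tens of percent at ~25-count spots); calibration therefore uses a circular
Gaussian with σ fixed to the PSF width, which is unbiased at the photon
budgets where single fluorophores are measured.  Calibration spots are
accepted only if their intensity trace disappears in one step, decided by a
BIC comparison of piecewise-constant models with 0, 1 and 2 changepoints
(exhaustive search; the step must be downward).

Whole-cell copy numbers integrate counts over the cell rectangle, subtract
camera offset × pixel count and the autofluorescence predicted by a linear
model in cell length (OLS on unlabelled cells), and divide by the unit
intensity.  Sums use the first frame; values may be legitimately negative
for empty cells and are reported as-is.

## 3. Periodicity spectrum

The stoichiometry distribution is smoothed with a Gaussian kernel
(bandwidth 0.7 molecules, comparable to the measured single-fluorophore
intensity spread) on a grid from 0 to max + 4 bandwidths with step
bandwidth/4.  Kernel mass below zero is reflected back and the density
renormalised on the grid, since molecule counts are nonnegative; this keeps
the density a proper distribution for any input.  The spectrum is the squared
modulus of the DFT of the mean-subtracted density (mean subtraction removes
only the DC term; no detrending), zero-padded 4× for interpolation
smoothness, reported against periodicity 1/f restricted to 2–20 molecules —
periodicities of 1 are meaningless for counts and longer periods are not
resolvable at n ≈ 100 spots.

The dominant peak is the largest *local* maximum in the range: a global
argmax sitting on a range edge is the tail of the distribution envelope, not
a periodicity, and is reported as no-peak.  The peak position is refined by a
parabola through the three surrounding points; the HWHM is the mean of the
left and right half-height crossings (one-sided if truncated).  Whether the
original analysis built its spectrum from a KDE, a histogram or pairwise
distances is not something this package asserts; the construction here is
validated by parameter recovery on the simulator, and HWHM values are
comparable only qualitatively across constructions.

With these defaults, 150 spots of 1–7 hexamers measured with 0.8-molecule
noise yield a peak in [5.5, 6.5] in ≥ 95% of seeds (the acceptance suite
recomputes this).

**A genuine limitation: the 50%-thinning control.**  For a spot of 6k
molecules thinned i.i.d. at p = ½, the surviving count X ~ Binomial(6k, ½)
has characteristic function |E e^{2πiX/3}| = 2^{−6k} ≤ 0.016, so the pooled
distribution carries essentially *no* period-3 structure: the coherent
period-3 amplitude (~N·0.016/7 for N spots) lies two orders of magnitude
below the √N sampling noise floor.  Subpopulation *means* do sit exactly at
multiples of 3 (E X = 3k, verified by test), but no spectral estimator can
recover a period-3 peak from the pooled i.i.d.-thinned values, and this
package's spectrum accordingly reports an envelope-dominated peak elsewhere
in the search range.  Observing a period-3 peak experimentally requires
survival to be correlated within a spot — e.g. bleaching each spot until
roughly half its own signal remains — which the i.i.d. thinning model
deliberately does not include.

## 4. Bleaching fits and extrapolation

The survival fit is linear in log space, constrained through S(0) = 1, with
weights w ∝ f/(1−f) (inverse variance of ln f̂ for binomial counts; capped
for f → 1).  Negative fitted rates (possible on noisy increasing series,
which warn) are clipped to zero.  The formal rate SE assumes independent
points; survival curves of a fixed ensemble are serially correlated, so
replicate spread is the honest uncertainty and the tests use it.
Extrapolation divides the observed count by fitted survival and refuses
survival < 10⁻⁹ rather than produce silently enormous numbers.  Thinning of
real-valued stoichiometries rounds to the nearest integer first, since
thinning is defined on molecules.

## 5. Tracking and diffusion

Detection: per-frame local maxima above median + 5 robust SDs (MAD-based),
refined by the Gaussian fit; detections carry integrated intensity so
monomer/dimer spots can be classified downstream.  Linking is greedy by
ascending distance with deterministic tie-breaks (frame, distance, detection
index), a search radius defaulting to 3·√(4 D_prior dt) with
D_prior = 0.1 µm²/s, and optional gap closing; greedy assignment is adequate
at the sparse densities of post-bleach single-molecule imaging and is *not*
globally optimal at high density.

The MSD uses all ordered pairs at each lag (time average), pooled across
tracks weighted by pair counts.  D = slope/4 of an OLS fit to the first four
lag points with a free intercept (2-D interpretation: positions are measured
in the image plane; the intercept absorbs 4σ_loc²).  |D| < 10⁻³ µm²/s is
flagged near-immobile.  At the study scale (30 tracks × 100 points,
dt = 10 ms, σ_loc = 20 nm) a single replicate of the immobile case has an
estimator SD of ≈ 2.6·10⁻⁴ µm²/s, so bound checks and recovery claims are
made on replicate means (30 replicates in the acceptance script, 10 in the
faster test variants); mean recovery is within a few percent for
D ∈ {0.005, 0.039, 0.061} µm²/s.

## 6. Problem sizes

Defaults throughout (150 spots × 100 seeds for periodicity; 30 tracks × 100
points × 30 replicates for diffusion; 50–60 rendered cells plus ~100
calibration spots for the image-route pipeline) were chosen as the smallest
sizes at which the estimators' sampling error is clearly below the effect
sizes of interest; everything completes in seconds on one CPU.

## 7. What passing tests do and do not show

The simulator shares its PSF, noise and photophysics models with the
estimators' assumptions, so recovery tests demonstrate *internal
consistency* — correct implementation of each estimator under its own model —
plus robustness to shot noise, read noise, autofluorescence and measurement
error at realistic levels.  They do not demonstrate robustness to real-data
features that are not modeled: focus drift, uneven illumination, blinking,
3-D PSF structure, segmentation errors in the supplied ROIs, motion blur, or
non-Poissonian camera artifacts.  Cell segmentation itself is out of scope:
ROIs are inputs.
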