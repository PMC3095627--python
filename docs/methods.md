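# Methods

## Measurement model

An excitation-scanned two-photon acquisition yields, at every pixel, an
intensity for each excitation wavelength λ_ex (default grid 710–920 nm in
5 nm steps, 43 values) in each of three simultaneously collected emission
bands (blue 350–505 nm, green 505–560 nm, red 560–650 nm). The detected
signal is modelled as a non-negative linear mixture of tissue signatures
under a multiplicative instrument envelope:

    F(λ_ex, b) = K(λ_ex) · Σ_j C_j · S_j(λ_ex, b),   C_j ≥ 0.

`S_j` lumps concentration-independent factors (quantum efficiency,
collection efficiency, two-photon cross-section) into one empirical
excitation–emission signature per tissue type; `K` collects the
wavelength-dependent systematics (laser power and pulse width, repetition
rate, dispersion, NA, and λ_ex itself). The model assumes linear mixing —
no inner-filter effects, no depth-dependent attenuation within one plane —
and treats each 2-D plane of a depth stack independently.

## Calibration

`K` is handled *empirically*: a homogeneous well of FAD is scanned, and
because FAD's two-photon excitation spectrum is approximately flat over
710–900 nm, the ROI-mean green-band spectrum of that scan is `K` up to a
scalar. Calibration divides any spectrum by this measured envelope and
multiplies each band by an LED-derived scale factor
(`scale[b] = reading[blue]/reading[b]`, blue ≡ 1) correcting
detector/filter response differences. Numerical guard: envelope values at or
below `1e-6 × max(envelope)` are floored to that value with a logged
warning, so division at range edges stays finite; the raw (unsmoothed) mean
spectrum is used.

Calibration exists for *interpretation* of signatures. Unmixing deliberately
consumes uncalibrated spectra: `K` multiplies the measured basis and the
measured data identically, so it cancels from the fit up to per-component
positive scalars (relative abundances are arbitrary-unit anyway), and
skipping the division avoids injecting the reference scan's noise. The
package enforces consistency — a calibrated basis cannot be fit against an
uncalibrated stack or vice versa.

A parametric envelope `K ∝ P(λ)²/(τ_p·f_p)·(NA²/λ)²`, normalized to unit
mean over the axis, is available in the simulator only, as an analytic
stand-in for generating realistic envelope shapes; the constant prefactor is
a convention, not a radiometric claim.

## Basis spectra

A basis spectrum is the ROI mean of a stack at every (λ_ex, band), with the
sample (n−1) standard deviation as its uncertainty (zero for one pixel —
and standard deviations below machine precision of the mean are reported as
exactly zero). Because absolute amplitude varies with imaging depth while
shape is stable, each per-site spectrum is normalized to the maximum of its
blue-band excitation spectrum *before* aggregation (the `normalized` flag
enforces this ordering); aggregation is the elementwise mean and sample
standard deviation across sites, pooling all sites equally while recording
site/animal counts. Tissue labels are open strings so additional components
can be introduced when residual maps reveal an unmodelled species; the
canonical four are shipped as named constants.

The packaged basis set (`canonical_basis`) is **synthetic**: smooth analytic
curves chosen to reproduce the qualitative physiology — epithelium
blue-dominant at short λ_ex (NADH) with a flat green term (FAD); lamina
propria with a short-λ_ex red peak (blood porphyrins); collagen essentially
blue-only and rising with λ_ex (SHG, suppressed below ~780 nm by tissue and
optics attenuation of the <390 nm harmonic); lymphatic tissue broad and
similar across bands (phospholipid-like). It is generated by code, not
digitized from any measurement, and exists so tests and demos have a
plausible, well-conditioned endmember set.

## Unmixing

The design matrix concatenates, per component, the excitation spectra of the
bands in use — **blue + green by default, red excluded**, because the red
band's relative amplitude varies most strongly with depth (hemoglobin
absorption differs sharply between the red and blue/green emission windows)
and spoils fits. Each component must be normalized to blue-band maximum 1
before fitting. Each pixel is solved independently by NNLS (Lawson–Hanson
active set via `scipy.optimize.nnls`); a vectorized fast path accepts the
unconstrained least-squares solution when it is already feasible, which
minimizes the same objective, so results are independent of path and pixel
order. The per-pixel squared Euclidean residual norm over all wavelengths
and used bands is the goodness-of-fit map. Numerical conventions: an
identically-zero pixel yields zero coefficients and zero residual; squared
residuals below `(1e3·eps·‖b‖)²` — pure rounding dust of an exact in-model
fit — are reported as exactly 0; a design-matrix condition number above 1e8
triggers a logged non-uniqueness warning, and the deterministic active-set
solution is returned.

An optional per-pixel *free band amplitude* mode fits one extra positive
multiplier per non-blue band (absorbing depth-dependent band attenuation) by
alternating NNLS over coefficients and closed-form multiplier updates,
initialized at 1, stopping when the squared residual decreases by less than
1e-8 or after 50 iterations. This is this package's design; it is opt-in
and off by default.

For display, all coefficient maps are divided by the maximum of the
epithelium map (configurable reference), so panel values are abundances
relative to epithelium = 1; each panel's maximum ("m.v.") is recorded for
annotation. The scaling is idempotent and preserves pixelwise ratios.

## Rendering

RGB merges average the selected excitation frames (unweighted), then scale
each channel independently: the clip value is the intensity at ascending
0-based rank `ceil((1−f)·N)` with `f = 0.0006` (the brightest 0.06 % of
pixels), values above it are clipped, the channel is divided by it, and
quantized to 8 bits with half-up rounding. On a strictly increasing 400×400
frame exactly `f·N = 96` pixels saturate; ties at the clip value all
saturate (deterministic). The threshold is computed on the averaged frame,
and merges are invariant to a global positive intensity scale. False-color
composites tint each component map (normalized to its own maximum) with a
fixed color — epithelium yellow, lamina propria white, collagen blue,
lymphatic green — sum, clip to [0, 1] and quantize.

## Synthetic phantoms

Since no real excitation-scanned GI data are deposited anywhere public, the
generator provides ground-truth scenes at the study's axis/band conventions:

- **checkerboard** — pure unit-concentration blocks of each component; no
  mixing zone, binary concentrations, for exact in-model tests.
- **crypts** — rings (annuli) of epithelium on a jittered grid, empty
  lumens, and a matrix of lamina propria / collagen / lymphatic whose
  smooth random weight fields sum to 1.
- **villi** — jittered elliptical cross-sections with an epithelial rim,
  lamina propria core and lymphatic speckle, on empty background.
- **peyer** — dense lymphatic speckle crossed by thin meandering collagen
  fibers over faint lamina propria.
- **lesion** — irregular epithelial overgrowth (thresholded smoothed
  noise), collagen strands, lamina propria background with lymphatic
  pockets.

Tissue presets receive a ≤ 2-pixel linear mixing zone at region boundaries
(3×3 box filter) so partial-volume behavior is exercised; sub-1e-9 filter
dust is snapped to exact zero so "pure region" remains well defined.
Everything is a deterministic function of (geometry, shape, seed).

The forward model multiplies concentrations by basis signatures and the
envelope, then applies noise: Poisson draws after rescaling the noiseless
signal so its brightest voxel equals `peak_counts` (shot noise on the
detected signal — the standard photon-counting assumption; no noise model
is prescribed by the source data), optionally plus zero-clipped Gaussian
read noise. Default `peak_counts = 1000` is a documented choice
representative of a 60 s wavelength scan at low milliwatt powers; it is not
a measured value. Recovery metrics gauge-fix each component by the
least-squares scalar onto truth before RMSE (abundances are relative), and
report per-component Pearson r plus dominant-label accuracy on pure-region
pixels.

What the phantoms do **not** emulate: optical sectioning and PSF blur,
depth-dependent attenuation, SHG polarization/orientation dependence,
sample motion during a scan, and detector offsets/afterpulsing. Passing
recovery tests therefore demonstrates correctness of the estimation chain
under the stated model, not robustness to those real-data effects — on real
tissue, orientation-dependent SHG and unmodelled constituents are expected
to dominate the residual map.

## Problem sizes and reproducibility

Tests and the acceptance script run at desk scale by choice: noisy-recovery
phantoms at 128×128 (three seeds), the noise-monotonicity sweep and
determinism runs at 64×64, oracle comparisons on 500 random 86×4 instances
(43 wavelengths × 2 bands × 4 components — the production fit geometry).
Full 400×400 frames run identically (the per-pixel fits are independent);
the rendering clip contract is checked at 400×400 where the 0.06 %
threshold equals a whole number of pixels. All randomness flows through
explicit seeds; full pipeline reruns with identical config and seeds are
byte-identical in their saved coefficient/residual TIFFs.

## Known limitations

- Stacks persist as float32 (or the original integer dtype); float
  round-trips are exact only to single precision.
- Negative raw values are clipped to zero at load with a logged count;
  amplifier-offset subtraction is out of scope.
- The alternating free-band-amplitude fit converges to a stationary point
  of a biconvex problem; it is not guaranteed to be the global optimum.
- No spatial regularization, sparsity, or blind endmember discovery; the
  basis is always supplied.
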