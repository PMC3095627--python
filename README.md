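# hyperunmix

Analysis pipeline for **excitation-scanning hyperspectral two-photon
microscopy** of intact tissue. A tunable laser is stepped across excitation
wavelengths (by default 710–920 nm in 5 nm increments) while three fixed
emission bands (blue 350–505 nm, green 505–560 nm, red 560–650 nm) are
collected simultaneously, so every pixel carries an excitation spectrum per
band. In fresh gastrointestinal tissue the contrast is entirely intrinsic —
NADH and FAD autofluorescence, porphyrins in blood, phospholipids in
lymphocytes, and second-harmonic generation from collagen — and the four
major tissue types (epithelium, lamina propria, collagen, lymphatic tissue)
have distinct excitation–emission signatures. Unmixing a stack against those
signatures segments tissue types without any staining, an "instant
histology" for fresh biopsies.

The package implements the full analysis chain for such data:

- **`hyperstack`** — the 4-D stack container (`[row, col, λ_ex, band]`) with
  lossless multi-page TIFF + JSON-sidecar I/O.
- **`calibration`** — empirical instrument-envelope estimation from a
  reference-fluorophore (FAD) well scan, per-band LED scale factors, and
  their application to spectra and stacks.
- **`basis`** — ROI extraction, blue-band-maximum normalization, and
  cross-site/cross-animal aggregation of tissue basis spectra, plus a
  packaged synthetic four-tissue basis set.
- **`unmix`** — pixel-by-pixel non-negative least squares against the
  concatenated blue+green excitation spectra, coefficient maps, residual
  (squared-norm) maps, and epithelium-referenced display scaling.
- **`render`** — thresholded RGB merges (hottest 0.06 % of pixels clipped),
  per-component grayscale panels with max-value annotation, and false-color
  composites.
- **`phantom`** — synthetic GI phantoms (crypts, villi, Peyer's patch,
  neoplastic lesion, checkerboard) with known ground truth, the linear
  forward model with instrument envelope and shot noise, and recovery
  metrics.
- **`pipeline` / CLI** — a configured, logged, reproducible end-to-end run.

## The model

The detected signal at each pixel is a non-negative linear mixture

```
F(λ_ex, band) = K(λ_ex) · Σ_j  C_j · S_j(λ_ex, band),      C_j ≥ 0
```

where `S_j` is the signature of tissue component *j*, `C_j` its relative
abundance, and `K(λ_ex)` a wavelength-dependent instrument envelope (laser
power, pulse width, repetition rate, NA, dispersion). Per pixel, the
abundances are the NNLS solution

```
min_{x ≥ 0} ‖ A x − b ‖²
```

with `A` the basis signatures concatenated over the bands in use and `b` the
pixel's concatenated spectrum; the minimized squared residual norm is mapped
as a goodness-of-fit surface. Because `K` multiplies basis and data
identically it cancels from the fit, so unmixing uses *uncalibrated* spectra;
the envelope (measured by dividing by a FAD well scan, whose two-photon
excitation spectrum is nearly flat over this range) is applied only when
signatures are interpreted or plotted. The red band is excluded from fitting
by default: its relative amplitude varies with depth through tissue
attenuation and degrades the fit.

## Worked example

```python
import hyperunmix as hu

basis = hu.canonical_basis()                       # synthetic 4-tissue set
norm  = basis.map(hu.normalize_basis)              # blue-band max -> 1
scene = hu.generate_phantom("crypts", (128, 128), basis, seed=0)
stack = hu.forward_simulate(scene, basis,
                            noise=hu.NoiseModel("poisson", peak_counts=1000),
                            seed=0)
maps, residual = hu.unmix_stack(stack, norm)       # pixelwise NNLS
report = hu.recovery_report(scene, maps)
print(round(report["pooled"]["min_pearson_r"], 4),
      report["pooled"]["argmax_accuracy"],
      round(float(residual.values.mean()), 1))
```

prints

```
0.996 1.0 22367.1
```

i.e. under shot noise at 1000 peak counts every recovered abundance map
correlates with its ground truth at r ≥ 0.996, the dominant-tissue label is
correct at 100 % of pure-region pixels, and the mean per-pixel squared
residual (counts²) reflects the injected photon noise. The same chain is
available from the shell:

```bash
hyperunmix simulate --geometry crypts --shape 128,128 --noise poisson --out stack.tif
hyperunmix basis --canonical basisdir/
hyperunmix unmix --stack stack.tif --basis basisdir/ --bands blue,green \
                 --reference epithelium --out outdir/
hyperunmix render --stack stack.tif --maps outdir/coefficients.tif --out img/
```

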