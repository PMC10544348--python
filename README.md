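# lfhsi — lightfield hyperspectral imaging at desk scale

`lfhsi` is a tested, desk-scale implementation of the acquisition-and-analysis
chain of a lenslet-array ("lightfield") snapshot hyperspectral imaging (HSI)
camera of the kind used intra-operatively in neurosurgery: a single exposure
through an array of 66 micro-lenses, each behind its own narrow Gaussian
band-pass filter (FWHM 10 nm, centres spanning 350–1000 nm), from which a
155-band reflectance hypercube is reconstructed. Because no raw clinical data
from such systems are publicly deposited, the package ships a physically
motivated simulator with exact ground truth, so every stage of the pipeline
can be validated end to end.

It is aimed at researchers prototyping snapshot-HSI processing — calibration,
reconstruction, colour validation, region-of-interest (ROI) spectroscopy —
who need a faithful, fully observable stand-in for the hardware.

## The model

**Acquisition.** Lenslet *i* sees the scene reflectance *r*(x, λ) through its
filter transmission *F_i*(λ) under illuminant *L*(λ), from a slightly shifted
viewpoint (parallax δ_i = K·b_i/Z px for baseline b_i at depth Z):

    m_i(x) = Σ_λ L(λ) · F_i(λ) · r(x + δ_i, λ) · Δλ,     DN = clip(round(g·m_i + ε), 0, 4095)

with 12-bit quantisation, optional Poisson shot noise and Gaussian read noise.
White (uniform reflector ρ_ref = 0.95) and dark reference stacks are acquired
with the sample.

**Reconstruction.** Per pixel: flat-field R_i = (S_i − D_i)/(W_i − D_i),
which cancels L(λ), g and the filter throughput; lenslet sub-images are then
shifted back by −δ_i (known geometry, or estimated by normalized
cross-correlation); finally the 66 band-integrated measurements are inverted
to a 155-band spectrum by Tikhonov-regularised least squares with a
second-difference smoothness prior:

    r̂ = argmin_r ‖A r − m‖² + λ_reg ‖Δ² r‖²,     A[i,k] ∝ F_i(λ_k) Δλ  (rows normalised)

The 66 → 155 oversampling is solvable only because of the prior; at
λ_reg = 0 the solver refuses rather than return an arbitrary spectrum.

**Validation.** Hypercube spectra are integrated against the CIE 1931 2°
observer (white-balanced/equal-energy convention, flat reflector mapped to
D65), converted to sRGB for display and CIELAB for comparison, and scored
with the full CIEDE2000 ΔE₀₀ formula: below 2 a colour difference is
imperceptible, below 6 commercially acceptable. ROI spectra are extracted
through integer label masks with specular/saturated pixels rejected, and
L1-normalised (each spectrum rescaled to sum to 1) for shape comparison.

## Worked example

The `demo` subcommand runs the whole noiseless chain — 24-tile synthetic
reference chart → 66-lenslet capture → hypercube → tile-centre spectra →
CIEDE2000 against the ground-truth palette:

```
$ lfhsi demo --seed 0
 label     name  delta_e       verdict
     1  label_1 0.011256 imperceptible
     2  label_2 0.012045 imperceptible
     3  label_3 0.017290 imperceptible
     ...
max dE00 = 0.0210 (imperceptible threshold: 2.0)
```

Every tile reconstructs to within ΔE₀₀ ≈ 0.02 of its known spectrum — far
inside the imperceptible band — confirming that referencing, registration and
spectral inversion compose without systematic colour error. The command exits
non-zero if any tile reaches ΔE₀₀ = 2.

The numbered drivers under `analysis/` run the full study sequence and write
their tables to `results/`:

```bash
python analysis/01_simulate_checker.py        # chart scene + raw captures (ENVI)
python analysis/02_reconstruct_and_validate.py  # hypercube, sRGB render, dE00 tables
python analysis/03_tissue_roi_spectra.py      # tissue phantom ROI + blood-tint sweep
python analysis/04_ripple_cancellation.py     # NIR illuminant-ripple experiment
```

Representative findings (seed 0): noisy-pipeline worst tile ΔE₀₀ = 0.197 over
five seeds; the vessel-class red/green band ratio grows 1.14 → 6.38 as blood
contamination rises from 0 to 75%; a matched white reference suppresses
illuminant ripple in 750–900 nm about 160-fold relative to a mismatched one.

Individual stages are also exposed as subcommands (`simulate`, `reconstruct`,
`render-srgb`, `extract-roi`, `validate-checker`) operating on ENVI cubes,
16-bit PNG masks and CSV tables.

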