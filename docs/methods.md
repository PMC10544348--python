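# Methods

This note documents the models behind `lfhsi`: what is simulated, how the
reconstruction and validation mathematics work, which parameters matter, and
what the synthetic experiments do and do not demonstrate.

## 1. Scene model (`lfhsi.phantom_scenes`)

A scene is per-pixel diffuse reflectance r(x, y, λ) ∈ [0, 1] on an explicit
uniform wavelength grid (default 155 points, 350–1000 nm), plus a depth map
(cm) and an integer ground-truth label mask whose labels index a palette of
reference spectra.

Two families stand in for physical validation targets:

- **Reference chart** — a rows×cols tiling of constant-spectrum patches.
  The palette generator produces chromatic patches as sums of 1–3 Gaussian
  bumps (centres 380–950 nm, σ 30–90 nm) on a low base level, clipped to
  [0.02, 0.95], and neutral patches as flat greys at evenly spaced levels.
  A real chart's tabulated spectra can be supplied instead via the CSV
  loader (`load_palette_csv`). Default working distance 25 cm, the typical
  desk acquisition distance for such charts; it is a plain config knob
  because clinical working distances differ (≈27 cm in hand-held use).
- **Tissue phantom** — a background class with seeded random elliptical
  blobs of other classes, emulating cortex-plus-vessel geometry. Optional
  blood contamination mixes every pixel as r′ = (1−f)·r + f·r_blood, where
  r_blood is a fixed logistic step (≈0.02 below 600 nm, ≈0.55 above 620 nm).
  The blood curve is illustrative, not physiological: it reproduces the
  qualitative red-shift mechanism, not haemoglobin's absorption bands.

Convex spectral mixing is the extent of the tissue optics; there is no
radiative-transfer modelling of scattering or absorption.

## 2. Camera model (`lfhsi.camera_model`)

- **Filter bank.** 66 unit-peak Gaussian band-pass filters, centres evenly
  spaced over 350–1000 nm (10 nm apart), FWHM 10 nm (σ = FWHM/(2√(2 ln 2))).
  The commercial device's measured band responses are proprietary; equal
  spacing and Gaussian shape are explicit, configurable assumptions.
  `measure_fwhm` checks the generated curves numerically (half-maximum
  crossings interpolated on a 0.1 nm grid) rather than trusting the σ
  relation.
- **Illuminant.** A xenon-arc-like source: a broad Gaussian hump
  (centre 580 nm, σ 230 nm, positive floor) plus seeded narrow emission
  peaks (σ 2–5 nm) confined to 750–900 nm and scaled by `ripple_amplitude`
  (default 0.3). The ripple is what corrupts NIR spectra when white
  referencing is skipped or mismatched.
- **Lenslet geometry.** A 6×11 centred lattice (66 lenslets) at 4 mm pitch.
  The actual lenslet arrangement is not published; the lattice is
  configurable. Disparity is the thin-baseline model δ_i = K·b_i/Z with
  K = 3.354 px·cm/mm chosen so the maximum disparity is ≈3 px at 25 cm.
  The true K, baselines and depth are recorded in every capture so
  known-geometry registration is possible.
- **Sensor.** mono12 (full scale 4095 DN). Exposure gain defaults to
  auto-exposure placing the white reference at 80% of full scale. Noise:
  Poisson shot noise on the expected DN plus Gaussian read noise
  (σ = 2 DN default), seeded. The dark stack has zero expected signal;
  clipping negative read-noise excursions at 0 DN slightly biases the dark
  mean upward, as in a real unsigned pipeline.
- **Utilities.** 2×2 binning (rounded block means; viewfinder mode),
  packed frame memory (width·height·bit_depth/8 — the full 7920×6008
  mono12 frame is 68 MiB), and the Brewster mount angle arctan(n) used to
  suppress reflections off the sterile drape window (56° for n = 1.5).

Simulated frames are small (≤256 px per side per lenslet); the physical
sensor dimensions enter only through the frame-memory utility.

## 3. Reconstruction (`lfhsi.reconstruction`)

1. **Reference correction.** R = (S − D)/max(W − D, ε) per pixel and
   lenslet, ε = 1 DN; pixels with W − D < ε are flagged invalid, not
   silently divided. This cancels the illuminant SPD, filter throughput
   and gain in one step, which is why the recovered spectra are free of
   source ripple when the white reference shares the sample's illuminant.
   Corrected values are relative to the white reflector; the orchestrator
   multiplies by ρ_ref = 0.95 so hypercubes are absolute reflectance.
2. **Registration.** With known geometry, each lenslet is shifted by −δ_i
   with subpixel bilinear resampling (`register_known`); otherwise integer
   shifts are estimated per lenslet by zero-mean normalized
   cross-correlation against a reference lenslet within ±max_shift px,
   ties broken toward zero (`register_estimate`). Both assume a planar
   scene (one global shift per lenslet); per-block disparity for
   non-planar scenes is out of scope, and the half-pixel quantisation of
   the estimator is reported as its residual disparity.
3. **Spectral inversion.** With A[i,k] = F_i(λ_k)Δλ row-normalised so a
   flat unit spectrum maps to unit measurements, each pixel solves
   min ‖Ar − m‖² + λ_reg‖Δ²r‖² via one Cholesky factorisation of the
   normal matrix shared by all pixels. Defaults: λ_reg = 1e-3,
   second-order difference penalty, 155 output bands on 350–1000 nm.
   λ_reg trades noise amplification against spectral blurring: the
   default recovers smooth spectra (bump σ ≥ 20 nm) to <0.02 absolute
   error while leaving flat spectra exact. The under-determined system is
   refused outright at λ_reg = 0. Optional non-negativity is enforced by
   clip-and-refit on offending pixels. Output is clipped to [0, 1.5] —
   super-unity values are kept visible for specular diagnostics — with the
   clip count logged in provenance.

The vendor's reconstruction algorithm is unpublished; this chain is the
package's own, and its invertibility claims are made only for its own
Gaussian filter bank.

## 4. Colorimetry (`lfhsi.colorimetry`)

Reflectance is integrated against the CIE 1931 2° observer at 5 nm over the
overlap of the spectrum and CMF supports, normalised by Σȳ Δλ so a flat
perfect reflector has Y = 1 exactly. The shipped CMF table is the
Wyman–Sloan–Shirley multi-Gaussian analytic fit to the standard observer
(ȳ peaks at 555 nm; equal-energy white lands at chromaticity 0.3330, 0.3335),
tabulated 360–830 nm.

Because hypercubes are white-balanced, their flat perfect reflector is the
scene's reference white. A diagonal (von Kries-style) scaling therefore maps
that flat reflector exactly onto D65 before display or Lab conversion, so
neutral spectra render neutral and sit on the L* axis; `adapt_white=None`
gives the raw equal-energy integrals. sRGB uses the IEC 61966-2-1 matrix and
piecewise gamma with clip-and-flag gamut handling; Lab uses D65 and the
standard cube-root function with its linear toe; CIEDE2000 is the full
formula (G factor, hue rotation R_T, S_L/S_C/S_H weights), verified in tests
against an independently coded formula oracle and against scikit-image,
which reproduces the published reference value for the canonical blue pair.

## 5. ROI analysis (`lfhsi.spectra_analysis`)

Mask-driven extraction computes, per label, the mean and **population**
standard deviation over valid labelled pixels per band (population because
the ROI is the full population of annotated pixels, not a sample from it).
Saturation rejection invalidates any pixel whose raw DN reaches
`saturation_fraction`×full-scale in any lenslet (flags are shifted onto the
registered frame when geometry is known); it is on by default for
extraction, since specular highlights otherwise corrupt mean spectra.
L1 normalisation rescales a non-negative spectrum to unit sum (shape-only
comparison) and rejects all-zero or negative input. Chart validation
samples each tile's centred box covering 50% of its bounding-box sides
(edge pixels are blurred by parallax resampling), and verdicts use
half-open bins [0,2) imperceptible, [2,6) acceptable, [6,∞) unacceptable —
boundary values go to the higher-severity bin.

## 6. Problem sizes and numerical choices

The shipped experiments use a 4×6 chart at 24 px tiles (96×144 px,
155-band scenes), 32–64 px tissue phantoms, and a 326-point (~2 nm) scene
grid where the forward model must resolve illuminant ripple: sizes at which
every stage's behaviour is already fully exercised and the complete suite
runs in seconds. Determinism: every random element (palette, blobs,
illuminant ripple placement, sensor noise) is driven by explicit
`numpy.random.default_rng` seeds, and identical config+seed reproduces
captures, hypercubes and CSV outputs byte-for-byte. Ties and degenerate
inputs are handled explicitly: zero-texture registration falls back to zero
shift with a warning; dead reference pixels are flagged; zero-band cubes,
mismatched shapes and out-of-range fractions raise.

## 7. What the synthetic experiments do and do not show

The simulator shares its filter model with the reconstruction's system
matrix (by design — the vendor calibration is unavailable), so end-to-end
fidelity results demonstrate the *consistency and conditioning* of the
chain, not robustness to band-response miscalibration. Real acquisitions
additionally contain focus variation, per-lenslet vignetting, non-planar
parallax, chromatic aberration and motion, none of which are modelled; the
planar global-shift registration is explicitly the simplification that the
NIR chromatic artifacts of hand-held systems are attributed to. ΔE₀₀
values from the noiseless pipeline (~0.02) therefore bound only the
algorithmic error of referencing + registration + inversion + colorimetry;
hardware-validation ΔE₀₀ values on physical charts are expected to be an
order of magnitude larger.
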