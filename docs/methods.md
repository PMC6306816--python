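# Methods

## The measurement

The package quantifies how strongly the content of a grayscale micrograph
— collagen fibrils, F-actin-labeled cells, or any oriented texture — is
aligned with a reference direction. Two statistics are computed:

**Angular content distribution I(φ).** The image is mean-subtracted,
Hann-windowed, and transformed with a 2D FFT. A straight structure at
real-space angle φ concentrates spectral power along the perpendicular
line through the origin of frequency space, so binning in-band power by
angle and rotating by 90° yields the percent of image content oriented at
each angle. Orientations are axial (φ and φ+180° are the same fibril) and
reported on [−90°, 90°), 0° being the image x-axis, counterclockwise
positive. I(φ) is normalised to sum to 100%.

**Orientation index OI(θ).** For a reference angle θ,

    OI(θ) = (2⟨cos²(φ − θ)⟩ − 1) · 100%,
    ⟨cos²(φ − θ)⟩ = Σ_φ I(φ) cos²(φ − θ) / Σ_φ I(φ),

a Riemann sum over the uniform angular bins. OI is +100% for content
fully parallel to θ, −100% for perpendicular, 0% for random. By the
double-angle identity OI also equals the I-weighted mean of
cos(2(φ − θ)) scaled by 100; every call evaluates both forms and requires
agreement to 1e-9 as a discretisation self-check. The antisymmetry
OI(θ+90°) = −OI(θ) is exact.

In the pipeline the default θ is 90° (vertically patterned collagen);
analyses of horizontally deposited substrates pass θ = 0°.

## Spectral estimator choices

- **Window.** Hann by default. Without it, the image border injects a
  cross of leakage along the frequency axes that reads as spurious 0°/90°
  alignment. `window="none"` is retained for exactly periodic test
  gratings.
- **Band.** An annulus excluding a 4-px-radius disc at DC (illumination
  and large-scale shading) and frequencies above 0.9 of Nyquist
  (pixel-level noise). A constant image has no in-band energy and raises
  `NoStructureError` rather than returning a fake uniform distribution.
- **Weighting.** Spectral power (|F|²) by default; amplitude (|F|) is
  available.
- **Binning.** 180 one-degree bins, centers at integer degrees from −90;
  each spectral sample is assigned to its nearest bin, no interpolation.
  `peak_orientation` is the plain argmax with ties broken toward the
  smallest angle (a uniform distribution reports −90° by convention).
- **Geometry.** Non-square inputs are padded with their mean to the next
  square power of two; padding preserves the angular metric where
  resampling would not.
- **Intensity invariances.** Multiplying the image by c > 0 leaves I(φ)
  unchanged (normalisation cancels scale); adding a constant moves only
  the excluded DC term.

An independent **structure-tensor estimator** computes the same
distribution from per-pixel Gaussian-derivative gradients (orientation =
gradient direction + 90°, weight = squared gradient magnitude, border of
3σ excluded). It shares only the binning contract with the FFT path and
serves as a cross-check in the test suite.

**Peak comparisons between estimators are made on seed-averaged peak
locations** (axial circular mean over 10 generated scenes). The
per-image argmax of a broad angular distribution is speckle-limited: at
concentration κ = 5 the density varies by under 8% across ±5° of the
mode, while a 1°-bin of the power spectrum carries ~10% relative noise,
so two unbiased estimators' single-image argmaxes legitimately disagree
by ~10°. The averaged peak location is the stable quantity both must
share; agreement there is within ~1° in practice.

## Synthetic scene generator

The generator emulates the study system — flow-deposited fibrillar
collagen imaged in grayscale, with cultured cells and a cryo-injury —
well enough that every downstream stage has exact ground truth:

- **Fibril orientations** follow a von Mises law on the doubled angle
  (the standard axial-data model): κ = 0 is the uniform "random"
  substrate, κ ≳ 50 the flow-aligned substrate. The sampled angles are
  stored in the raster provenance as per-scene ground truth. Deviation sd
  scales as 1/(2√κ) rad, i.e. ~2.9° at κ = 100; individual samples can
  exceed any fixed window at moderate κ, so "all samples within ±3°"
  holds only at very large concentration (κ ~ 1e4).
- **Waviness** displaces each fibril path sinusoidally perpendicular to
  its axis (defaults 3 px amplitude, 60 px wavelength, echoing the wavy,
  interwoven fibrils in electron micrographs of microfluidically
  deposited collagen). This is *not* cosmetic to the statistics: the
  tangent-angle distribution of a sinusoid is arcsine-shaped with horns
  at ±atan(2πA/λ) ≈ ±17°, which (i) caps the achievable OI of a
  perfectly concentrated mat at ≈91% (mean cos(2·atan(0.314 cos u)) =
  0.908) and (ii) flattens the top of I(φ) into twin horns that make the
  single-image argmax hop. End-to-end recovery tests therefore disable
  waviness when the quantity under test is the spectral/OI chain itself.
- **Rendering.** Fibrils are anti-aliased strokes (dense sub-pixel
  polyline points splatted with bilinear weights) composited by max, so
  crossings do not sum intensity; width is built from parallel offset
  passes. Background level, fibril intensity, and additive Gaussian noise
  (clipped to [0, 1]) complete the scene. One `numpy` Generator seeded
  per operation; identical spec + seed is bit-identical, no global state.
- **Cells** are silhouettes composited by max at a set intensity:
  dendritic (disk body with thin radiating processes; the serum-free
  keratocyte phenotype), elongated (ellipse of given axis ratio and
  orientation; the PDGF/TGFβ phenotypes), or circular. Elongation ratio 1
  degenerates exactly to the circular branch. The binary cell mask is
  returned alongside the raster.
- **Freeze wound.** A disc (default radius 500 µm — half the 1 mm probe)
  inside which cell pixels are replaced by a normalised-convolution
  estimate of the local substrate value (Gaussian average over non-cell
  pixels, σ = 8 px); everything else, including fibril content inside the
  disc, is untouched, matching the observation that freezing detaches
  cells without disturbing the collagen. A mask-free image passes through
  bit-identically.

What the generator does **not** emulate: DIC optics (shear shadows,
halos), fibril bundling and thickness variation, intensity texture along
fibrils, cell-induced matrix deformation, uneven illumination beyond a
constant background, or camera noise statistics (Poisson/read noise).
Passing tests show the measurement chain recovers known orientation
structure from fibril-like imagery; they do not certify performance on
real micrographs with those confounds.

## Region policy around wounds

Whole images are the default analysis unit (one OI observation per
image). The `tiles` policy splits the frame into non-overlapping squares
(≥64 px) labeled `wound` (fully inside the disc), `non-wound` (fully
outside), or `discarded` (straddling); straddling tiles are excluded
because a tile mixing the two regions would blur both FFTs. Counts of the
three labels always sum to the grid total.

A note on scales: at the 0.3 µm/px default pixel size a 1024 px frame
spans 307 µm, so a full 500 µm-radius wound cannot fit inside it — the
disc then covers the whole frame and every tile is labeled `wound`. Wound
demonstrations that need both regions in one frame use 1 µm/px and a
300 µm wound.

## Statistics

Per-image OI values are compared across conditions with classical one-way
fixed-effects ANOVA (hand sums of squares so the degenerate conventions
are explicit: identical means give F = 0, p = 1; zero within-group
variance with unequal means gives F = +inf, p = 0; p from the F
distribution, cross-checked against `scipy.stats.f_oneway`). Post-hoc
pairwise comparisons use two-sided t tests on the pooled within-group
error term over all condition pairs, adjusted by the Holm–Šidák
step-down: sort the m raw p ascending, adjust the i-th to
1 − (1 − p₍ᵢ₎)^(m−i+1), enforce the running maximum, unsort (implemented
via `statsmodels.multipletests`, verified against hand-computed cases).
Welch correction is deliberately off — the classical ANOVA is the named
method — and each analyzed image contributes one observation.

## Flow-to-shear utility

`wall_shear_rate(Q, w, h) = 6Q/(w·h²)` — the parallel-plate
approximation for a thin rectangular channel, valid for h ≤ w. For
7.5 µL/min in a 60 µm × 1500 µm channel it gives 138.9 s⁻¹; quoted
experimental values for this geometry (150 s⁻¹) differ by ~8%, consistent
with side-wall corrections and rounding, so the number is documented as
approximate rather than exact.

## Problem sizes and tolerances

Test and demonstration scenes use 128–512 px frames with 30–300 fibrils;
the headline aligned-substrate measurement uses the full default frame
(1024 px, 300 fibrils, κ = 50, 10 seeds). OI limiting cases are exact
(+100/−100) or discretisation-limited (uniform → 0 within 1e-6); the
double-angle self-check runs at 1e-9 and antisymmetry at 1e-12; peak
comparisons allow ±5° on seed-averaged locations; ANOVA calibration
accepts an empirical type-I error in [0.03, 0.07] at α = 0.05 over 1000
null replicates of three groups of eight.

## Known limitations

- OI is computed on raw image content, not segmented cells; bright
  fibrils and cells both contribute to a composite scene's index.
- The spectral estimator carries a few points of downward OI bias from
  window-induced angular leakage at low spatial frequencies (measured
  ~91% on wave-free κ = 100 mats whose tangent-limit is ~98%); compare
  OI values only within one estimator and parameter set.
- Multi-page TIFFs are analyzed frame-independently; no tracking,
  stitching, or per-cell statistics.
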