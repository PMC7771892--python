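# Methods

## Forward model

The specimen is a thin complex transmission object
`o(r) = A(r)·exp(iφ(r))` sampled on a square high-resolution (HR) grid of
pixel size `dx` µm. Illuminating with the plane wave of LED `j` — lateral
offset `(x, y)` mm at height `h` mm, so illumination NA
`NA_j = r/√(r²+h²)` and transverse frequency `k_j = NA_j/λ` — shifts the
object spectrum by `k_j`. The objective transmits a circular pupil of
radius `NA_obj/λ` (ideal, unit amplitude, no aberrations), and the camera
records the squared modulus on the low-resolution (LR) grid.

Discretely: the DC-centred HR spectrum is cropped to an `n_lr × n_lr`
window centred at `k_j` rounded to the nearest frequency pixel
(`df = 1/(n_hr·dx)`; the LR and HR frequency-pixel spacings coincide
because the LR pixel is `dx·n_hr/n_lr`), masked with the pupil disc, and
inverse-transformed. Intensities are normalized so a uniform
unit-amplitude object produces `intensity_scale` counts in the on-axis
frame. Configurations are rejected when the pupil radius falls below 2
frequency pixels or exceeds the LR Nyquist window, and when the largest
shift would wrap the crop window around the spectrum edge. The rounding
of `k_j` to whole frequency pixels introduces at most a half-pixel
passband placement error, small against the ≥ 15-pixel pupil radius used
everywhere here.

Frames are labelled brightfield (BF) when `NA_j ≤ NA_obj − b`, darkfield
(DF) when `NA_j ≥ NA_obj + b`, and HYBRID inside the band, with
`b = 0.02` NA by default. Real systems produce mixed BF/DF frames through
wavefront curvature; a geometric NA band is the model-level stand-in, and
HYBRID frames are excluded before correction and reconstruction (the
passband overlap of the default geometries leaves no coverage gap).

## Camera noise

`frame → clip(offset + Poisson(frame/g)·g + N(0, σ), 0)`, with the
Poisson draw on the photo-electron scale (gain `g` counts/e⁻) so the shot
noise SNR grows as the square root of the signal, plus additive white
Gaussian read noise σ and a constant offset modelling stray light and
dark current. One sub-stream per frame is derived from `(seed, frame
index)`, making every degradation bit-reproducible and every frame's
noise independent.

## Reconstruction

Sequential Gauss–Newton spectrum updates: per frame, the current HR
spectrum's passband is projected through the pupil, the real-space
modulus is replaced by √I, and the passband is updated with

    O(k) ← O(k) + |P|·conj(P)·(Ψ′ − Ψ) / (|P|_max·(|P|² + δ))

which for the ideal binary pupil reduces to `(Ψ′−Ψ)/(1+δ)` inside the
pupil; `δ = 10⁻³` guards the division in the general form and is exposed
as `ReconSchedule.regularizer`. Frames are visited centre-out (ascending
illumination NA), the initial spectrum is the Fourier-embedded on-axis BF
amplitude masked to the objective passband, and the per-iteration
residual `Σ‖√I − |Ψ|‖²` is recorded. `N = 10` iterations are the default;
on noise-free data the residual collapses by four orders of magnitude
within those ten. The SdA schedule substitutes stacks per iteration: S4
for iterations 1…N−1, S3 for the final pass.

Reconstructions are compared against the ground truth restricted to the
**union of sampled passbands** rather than the full synthetic-NA disc: a
square LED grid reaches its maximum NA only along the diagonals, so the
disc contains frequencies no measurement ever sampled. With the coverage
reference the noise-free round trip reaches amplitude SSIM > 0.999; with
the disc reference it plateaus near 0.86 even at zero residual, the gap
being exactly the unsampled corners. The global phase ambiguity is
resolved by anchoring to the reference's phase through the inner product
before any comparison.

## SdA parameters

| parameter | default | units | role |
|---|---|---|---|
| `s1_radius` | 20 | px | dilation of the coarse Otsu object class before taking the background complement M |
| `s2_radius` | 8 | px | dilation of the object map I_BF (fills bar gaps and weak edges) |
| `sbr_threshold` | 1 | — | S3 vs rescaled-S4 branch per frame; fixed by the method's definition |
| `s3_radius` (post-filter) | 3 | px | rim width around object edges eligible for median filtering |
| median window | 3×3 | px | smallest window that removes impulses without blurring |

The structuring-element defaults suit frames of a few hundred pixels (the
regime the radii were designed for); for other frame sizes they should be
scaled with the frame — the package's 96-px default scene uses s1 = 10,
s2 = 4, the same fractions of the frame side. Discs are discrete
Euclidean discs (pixel included iff its centre lies within the radius).
Otsu thresholds are computed on a 256-bin histogram over the frame's full
range; the darker class is taken as the object (absorbing samples),
switching to the smaller class when the dark class covers the majority of
the frame. After map construction M is reduced by I_BF so no pixel is
simultaneously background and object. Zero-valued pixels of the BF sum,
where the reciprocal diverges, are assigned the largest finite reciprocal
and logged. In Eq. step 7/8 the rescaling maximum is the pre-amplification
S2 frame maximum, returning rescaled frames to the physical intensity
scale, and `I_DF` enters at raw scale: only the surviving-pixel set
matters because step 6 restores original values.

## Baselines

`global_subtract` implements the `mean` (k=0) and `mean + 3σ` (k=3)
corrections over the same mask M; BF frames are never background-
subtracted. The rolling-ball background is the classical Sternberg
formulation — grayscale opening (erosion then dilation) with the
non-flat ball structuring function `√(r²−d²)`, nearest-edge boundary
handling — because the widely used single-pass apex variant is only the
erosion stage and differs measurably from the opening. The radius is a
tunable; as with any morphological background it must exceed the feature
scale.

## Synthetic scenes and the default study conditions

`make_bar_target` builds a resolution-chart-like object: rows of dark
bars (amplitude 0.2 on a background of 1) of graded pitch in two
orientations, confined to a central square covering 0.4 of the field side
— FPM test scenes (chart portions, stained smears) are sparse, and the
empty surround is where all methods estimate their background statistics.
Phase is the amplitude scaled to [0, π], coupling phase to structure.
`make_texture_object` supplies a seeded procedural texture (pink-noise
base plus thresholded step edges, amplitude spanning [0, 1]) with
natural-image spectral falloff for tests that need an unstructured scene.
The bar fixture also defines its canonical evaluation regions: a 36×36
homogeneous patch in the empty corner (the point of maximum toroidal
distance from the structure, so periodic-boundary ringing is minimal) for
SNR, one line profile per bar group for Michelson contrast, and a central
crop for MSE/SSIM.

The default experiment emulates a realistic acquisition at desk scale:
149 LEDs (15×15 grid, 5 mm pitch, restricted to a 35 mm-radius filled
circle) at 60 mm height, λ = 532 nm, NA 0.16, synthetic NA 0.66; 96-px LR
frames from a 288-px HR object at 0.27 µm pixels; 5·10⁴ counts at unit
intensity, offset 300 counts, unit Poisson gain, Gaussian σ swept over
{0, 500, 1000, 1500} with three noise seeds. At σ = 1000 the brightest
darkfield frames hold ~2·10⁴ counts and the extreme-angle frames sink to
the noise floor — the regime the method targets. These sizes keep a full
sweep (37 reconstructions) under a minute on one CPU.

## What the synthetic tests do and do not show

The generator reproduces the features the method's logic depends on —
coherent image formation, the BF/DF/hybrid split, signal-dependent shot
noise plus read noise, a constant background, sparse absorbing objects
with phase–amplitude coupling — so passing tests demonstrate the
classification, amplification and dual-stack mechanics work as designed.
It does not model vignetting, LED radiant-intensity fall-off with angle
(available only as an optional cos-power factor), partial coherence,
sample thickness, aberrated pupils, stray-light gradients, or sensor
nonuniformity; performance margins measured here do not transfer
quantitatively to real hardware. Two desk-scale caveats deserve note:
pupil-ringing tails occupy a larger fraction of small frames than of
production-sized ones, which inflates the cost of SdA's masked-out tail
energy, and with the operational SBR (both means over the
background-subtracted S2) few frames fall below 1, so the S4 rescaling
branch engages rarely at these sizes — it is exercised directly by unit
tests instead.

## Numerical choices and degenerate inputs

Spectra are DC-centred (`fftshift` convention) throughout. SSIM uses a
7-pixel window, the standard K constants, and the joint dynamic range of
the two images. SNR is `20·log₁₀(mean/std)` on amplitude images
(configurable to `10·log₁₀` for intensity conventions). Michelson
contrast is computed per bar period and averaged; the period defaults to
the profile's dominant Fourier component when not given. The radial power
spectrum averages annuli one frequency pixel wide with a floor of
10⁻¹⁵×peak before taking logs. Degenerate inputs fail loudly: constant
frames (Otsu undefined), empty masks, stacks left without BF frames,
negative noise parameters, oversized pupils and wrapped passbands all
raise typed errors; an all-zero `S2'` in the low-SBR branch emits an
all-zero frame with a logged warning rather than dividing by zero, and a
zero background mean makes SBR +∞ (the frame keeps its original values
via the S3 branch).
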