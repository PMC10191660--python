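# Methods

## LIV contrast

LIV is the per-pixel temporal variance of the dB-scaled OCT intensity over
the N repeated frames of one B-scan location, with divisor N (population
variance) exactly as defined — not the unbiased N − 1 form. The
(N − 1)/N factor matters when comparing with closed-form speckle
statistics: for intensity that decorrelates completely between frames,
I ~ Exp(μ), the dB value 10·log₁₀ I has variance (10/ln 10)²·π²/6 ≈
31.03 dB², so the *expected* divisor-N LIV is (N − 1)/N times that —
30.05 dB² at N = 32. Both numbers are exercised by the tests and the
acceptance script.

The dB transform is 10·log₁₀(max(I, floor)). The floor keeps speckle
nulls finite; in the pipeline it defaults to the noise-floor mean, which
is where the dB image stops carrying information anyway. A floor far
below the noise floor creates deep, narrow spikes at speckle nulls that
destabilize both registration and the interpolation steps (see below).

## Synthetic phantom

The phantom emulates the appearance of an alveolar organoid under
repeated-B-scan OCT. A scene is a label grid (depth × fast × locations)
with six classes: background, lumen, epithelium (high- and low-dynamics
variants), fibroblast, and hyper-scattering inclusion. Alveoli are
spheres in index space — a lumen wrapped in an epithelial annulus of
stated thickness; *tessellated* alveoli alternate high/low-dynamics
epithelium in angular sectors (default 8); *filled* alveoli carry a
static inclusion disk at 0.6× the lumen radius. Overlaps resolve by
listing order (later wins). Fibroblasts are random dilated line strands
per slice. An optional capsule layer (a thin scattering slab with
configurable tilt) marks the sample top so surface detection has a step
to find.

Per pixel, the complex amplitude follows a stationary AR(1) circular
Gaussian process: a₀ ~ CN(0, μ), aₜ = ρ·aₜ₋₁ + √(1 − ρ²)·wₜ with
wₜ ~ CN(0, μ). This is the simplest stationary process with exactly
tunable frame-to-frame correlation ρ and exponential intensity marginals
(fully developed speckle); ρ = 1 is a frozen field, ρ = 0 decorrelates
completely in one frame interval. Detected intensity adds an independent
noise-floor realization per frame.

Two realism ingredients proved load-bearing:

- **Speckle grain.** The complex field is low-pass filtered (Gaussian,
  σ = 2 px by default) before use; filtering a Gaussian field keeps it
  Gaussian, so the exponential marginal survives while the field becomes
  band-limited. Unfiltered (pixel-white) speckle sits at the Nyquist
  limit, where sub-pixel interpolation is ill-posed: registration
  degrades and shifts are not invertible. σ = 2 px corresponds to
  adequately sampled PSF-limited speckle (the small-FOV configuration of
  the instrument class modeled here).
- **Noise floor.** Modeled as weak background speckle: exponential
  intensity (mean 0.01, i.e. 20 dB below the epithelium signal),
  decorrelated every frame but carrying the same spatial grain.
  Spatially white noise would lose variance under every interpolation
  pass, biasing corrected stacks relative to untouched ones.

Default class parameters: epithelium ρ = 0.2 (fast dynamics),
low-dynamics epithelium sectors and fibroblasts ρ = 0.95, inclusions
ρ = 1 (static), lumen/background ρ = 0; mean intensities 1.0
(epithelium), 0.5 (fibroblast), 2.0 (inclusion), 0.3 (lumen), 0.05
(background). The ρ values are design choices that reproduce the
qualitative high-LIV-epithelium / low-LIV-fibroblast contrast; no
quantitative dynamics are published for these tissues. All phantom
geometry is in pixel units; physical pitches enter only in the en-face
and morphometry stages.

What the phantom does **not** model: wave-optic PSF formation, confocal
gating, attenuation/shadowing with depth, multiple scattering, A-line
reconstruction from fringes, and axial-lateral resolution anisotropy.
Passing tests therefore demonstrate the correctness of the *analysis*
given speckle with known dynamics, not instrument-level fidelity.

## Bulk-motion correction

Each stack is registered to a reference frame — index (N − 1)//2, i.e.
the 16th frame of 32, reading the ordinal convention as zero-based index
15. Shifts are estimated by upsampled-DFT phase cross-correlation
(default 1/10 px) and applied with third-order spline interpolation to
the dB frames. Estimated shifts are quantized to the 1/upsample grid
before application. Pixels whose source coordinate falls outside the
original frame are flagged invalid; the corrected stack's validity mask
is the intersection over frames, and LIV simply excludes invalid pixels
rather than inventing fluctuation values. Motion along the slow axis
(across B-scan locations) is not corrected. Frames that cannot be
registered (no spectral content) are kept unshifted with a warning by
default (`on_failure="raise"` to abort).

Numerical choices that matter:

- **Estimation domain.** By default shifts are estimated on the same dB
  image that is shifted, with values clipped at 30 dB below the frame
  median first: dB speckle nulls are deep negative spikes whose
  log-domain shape does not translate rigidly, and unclipped they bias
  the sub-pixel estimate by several tenths of a pixel. An alternative
  `estimation_domain="linear"` registers the de-logged intensity, which
  weights bright structure more heavily.
- **Estimation margin.** Frame borders do not translate with the scene
  (content enters and leaves the field), so shifts are estimated on an
  interior crop (adaptive, ≤ 16 px) while the full frame is shifted.
- **Jitter injection domain.** Rigid in-plane motion commutes with the
  pointwise log, so a translated dB image and the dB of a translated
  intensity image describe the same physical motion; the phantom injects
  motion on dB frames with the same spline family the correction uses,
  making inject → correct a same-domain round trip whose residual is
  pure interpolation error.

With these choices, on a static phantom with ±1.5 px jitter the
uncorrected LIV is ~6–10× the motion-free level while the corrected LIV
is within a few percent of it and statistically indistinguishable from
it (Welch test on interior pixels, α = 0.01), the quantitative analog of
the sub-field artifact demonstration that motivates the correction.

## Pseudo-color rendering

Hue maps clipped LIV linearly from 0° (red) to 120° (green) over a
configurable display range (default 0–10 dB²; the source images' exact
endpoints are not recoverable, so the range is explicit metadata).
Brightness is the clipped, normalized mean dB intensity; saturation is 1;
invalid pixels render black. Dark pixels therefore appear black whatever
their LIV — which is also why noise-dominated LIV (up to ~31 dB² at pure
noise pixels) does not clutter the display.

## Surface detection and en-face planes

The surface is the first depth sample opening a run of ≥ 3 consecutive
samples above a threshold (default: noise mean + 4σ, estimated from the
top 8 depth rows), median-filtered (3 × 3) across the en-face grid; the
run requirement keeps isolated noise excursions from reading as the
sample top, and a volume in which no A-line qualifies is an error. A
least-squares plane (depth = a·fast + b·location + c) is fitted to the
detected surface — the automated counterpart of manually tilting a flat
extraction plane — with a manual plane override available. En-face
images sample the volume at the plane displaced by round(offset/pitch)
depth pixels, nearest-depth only: axial interpolation would mix LIV
values across depths. The axial pixel pitch is a required configuration
parameter (µm per depth sample); it has no instrument-independent
default.

## Morphometry and statistics

Area is pixel count × pitch_fast × pitch_slow (mm²). Perimeter is
measured after resampling the mask to an isotropic grid at the finer
pitch (bilinear + 0.5 threshold; nearest-neighbour leaves staircase
blocks) and Gaussian smoothing with σ tied to the pitch ratio, then
tracing the 0.5-level marching-squares contour; on digitized disks of
radius 10–100 px this lands within 1% of 2πr, and a 1:4 anisotropic
sampling agrees with the isotropic one within 2% in area. Circularity is
4πA/P², clipped at 1.0 for reporting since perimeter underestimation on
small digitized disks can push the raw ratio slightly above 1. Border
exclusion flags any region touching the outermost row/column.
Tessellated/filled type codes are annotation inputs, not computed —
the classification is a manual call on the images (small alveoli without
a clear lumen are annotated as filled).

Group comparisons: Welch's two-tailed t-test (unequal variances,
Welch–Satterthwaite df) for means; the median-centered Levene
(Brown–Forsythe) variant for variances, the standard reading of
"median-based Levene". Marks are · / * / ** at P < 0.1 / 0.05 / 0.01.
Comparisons where either group has ≤ 7 members are computed but flagged
`skipped` and carry no mark.

## Problem sizes

The test suite and acceptance script run the phantom at desk scale —
96–160 px frames, 8–32 frames per stack, single or few locations, 50
registration trials, ≥ 10⁴ pixels for the statistical checks — sizes
chosen so every property is measured with comfortable Monte-Carlo margin
while the whole suite completes in well under ten minutes. The closed-
form speckle check uses grain-free (spatially uncorrelated) speckle to
maximize the number of independent samples per pixel grid.

## Known limitations

- The phantom's ρ defaults are plausible, not measured; only ordering
  claims (epithelium vs fibroblast) are tested, not absolute LIV levels.
- Corrected stacks are interpolated and motion-free ones are not, so
  their LIV distributions differ slightly near the noise floor and at
  speckle nulls in principle; the statistical-equivalence test operates
  at the level the contrast is used (interior-pixel means).
- Perimeter estimation assumes simply-connected, reasonably smooth
  regions; deeply concave or holed masks sum all boundary contours.
- The pipeline consumes segmentation masks; it does not segment.
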