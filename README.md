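# livoct

Dynamic-OCT analysis of alveolar organoids: **LIV** (logarithmic intensity
variance) contrast computation, sub-pixel bulk-motion correction,
pseudo-color rendering, surface-referenced en-face extraction, and
morphometry of segmented alveoli — together with a synthetic speckle
phantom that makes every stage testable without instrument data.

## The problem

Alveolar organoids (iPSC-derived alveolar epithelial cells co-cultured
with lung fibroblasts) form alveolus-like cysts whose cellular activity is
invisible to structural OCT. Dynamic OCT recovers that activity from the
*temporal fluctuation* of the speckle: at each B-scan location, N repeated
frames are acquired (N = 32, 0.23 s apart, 128 locations split into 8
sub-fields; 4,096 frames in 58.8 s), and each pixel is contrasted by the
variance of its dB-scaled intensity over time,

```
LIV(x, z) = (1/N) * Σᵢ [ I_dB(x, z; tᵢ) − ⟨I_dB(x, z)⟩ ]²     [dB²]
```

with ⟨·⟩ the average over time (divisor N, not N − 1). High LIV marks
strongly fluctuating (metabolically active) tissue — the alveolar
epithelium; mesh-like fibroblast regions and hyper-scattering static
masses read low. For display, the mean dB intensity drives image
brightness and LIV drives hue (red = low → green = high).

Because the scanner revisits a location for ~7 s, rigid bulk motion
between frames masquerades as dynamics. Each stack is therefore registered
to its central (16th) frame by phase cross-correlation at 1/10-pixel
accuracy and corrected with cubic-spline sub-pixel shifts before LIV is
computed.

Downstream, alveoli segmented on an en-face plane ~100 µm below the sample
surface are typed by epithelial appearance (non-tessellated/tessellated ×
non-filled/filled → T0F0, T0F1, T1F0, T1F1), measured for area and
circularity (4πA/P², 1 for a circle), and compared across groups with
Welch's t-test (means) and the median-based Levene test (variances), with
marks · / * / ** at P < 0.1 / 0.05 / 0.01 and groups of ≤ 7 alveoli
skipped.

## Worked example

`examples/03_motion_correction.py` freezes a phantom scene (every region's
frame-to-frame correlation ρ = 1), injects ±1.5 px rigid jitter, and
corrects it:

```
mean LIV motion-free :  0.836 dB^2
mean LIV jittered    :  7.889 dB^2  (9.4x inflated)
mean LIV corrected   :  0.834 dB^2  (1.00x)
largest estimated shift: 2.9 px
```

The jitter inflates the apparent dynamics ninefold; after registration the
LIV level returns to the motion-free value. `examples/02_simulate_and_liv.py`
shows the dynamics contrast itself:

```
epithelium_high    rho=0.20 mean LIV =  25.70 dB^2 over 784 px
fibroblast         rho=0.95 mean LIV =  16.75 dB^2 over 778 px
```

— rapidly decorrelating epithelium reads well above the slow fibroblast
mesh, the qualitative signature of the organoid images. The other
examples cover the protocol arithmetic, en-face extraction and the
morphometry/statistics stage.

A thin CLI wraps the same library: `livoct protocol | simulate | correct |
liv | enface | morph | run` (see `livoct --help`).

## Layout

- `src/livoct/scan_protocol.py` — raster protocol geometry/timing
- `src/livoct/phantom.py` — AR(1) complex-Gaussian speckle phantom
- `src/livoct/motion_correction.py` — sub-pixel registration of stacks
- `src/livoct/liv.py` — LIV, pseudo-color, surface and en-face planes
- `src/livoct/morphometry.py` — areas, circularity, tallies, group tests
- `src/livoct/io.py`, `src/livoct/cli.py` — containers, config, pipeline, CLI
- `docs/methods.md` — models, parameter choices, numerical details
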