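"""LIV contrast, pseudo-color fusion, and surface-referenced en-face planes.

The logarithmic-intensity-variance (LIV) is the per-pixel temporal variance
of the dB-scaled OCT intensity over the N repeated frames at one location,

    LIV(x, z) = (1/N) * sum_i [ I_dB(x, z; t_i) - <I_dB(x, z)> ]^2 ,

with divisor N (population variance) and <.> the average over time. High
LIV marks strong signal fluctuation, i.e. high intratissue/intracellular
dynamics; the hyper-scattering but static structures stay low. Display
images fuse the time-averaged dB intensity (brightness) with LIV (hue,
red = low to green = high). En-face planes are extracted at a fixed offset
below the detected sample surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.colors import hsv_to_rgb
from scipy import ndimage

from .stack import FrameStack


@dataclass
class LIVMap:
    """Per-pixel LIV (dB^2) and time-averaged dB intensity at one location."""

    liv: np.ndarray
    mean_db: np.ndarray
    n_frames: int
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    location: int = 0

    def __post_init__(self) -> None:
        self.liv = np.asarray(self.liv, dtype=float)
        self.mean_db = np.asarray(self.mean_db, dtype=float)
        if self.liv.shape != self.mean_db.shape:
            raise ValueError("LIV and mean maps must share a shape")
        if self.valid is None:
            self.valid = np.ones(self.liv.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if np.any(self.liv[self.valid] < 0):
            raise ValueError("LIV must be non-negative where valid")


@dataclass
class PseudoColorImage:
    """RGB composite: brightness = mean dB intensity, hue = LIV."""

    rgb: np.ndarray
    liv_range: tuple[float, float]
    db_range: tuple[float, float]

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=float)
        if self.rgb.ndim != 3 or self.rgb.shape[-1] != 3:
            raise ValueError("rgb must be (rows, cols, 3)")
        if np.any(self.rgb < 0) or np.any(self.rgb > 1):
            raise ValueError("rgb channels must lie in [0, 1]")


def to_db(linear_intensity: np.ndarray, floor_linear: float = 1e-6) -> np.ndarray:
    """dB-scale a linear intensity: ``10 * log10(max(I, floor))``.

    The floor keeps zero-intensity pixels finite; negative intensities are
    rejected (linear OCT intensity is a magnitude squared).
    """
    intensity = np.asarray(linear_intensity, dtype=float)
    if floor_linear <= 0:
        raise ValueError("floor must be positive")
    if np.any(intensity < 0):
        raise ValueError("linear intensity must be non-negative")
    return 10.0 * np.log10(np.maximum(intensity, floor_linear))


def stack_to_db(stack: FrameStack, floor_linear: float = 1e-6) -> FrameStack:
    """Convert a linear-intensity stack to dB scale (no-op if already dB)."""
    if stack.scale == "db":
        return stack
    out = stack.copy()
    out.data = to_db(stack.data, floor_linear)
    out.scale = "db"
    return out


def compute_liv(stack: FrameStack) -> LIVMap:
    """Temporal variance of the dB intensity (divisor N) and its time mean.

    The divisor-N (population) variance is used deliberately; its
    (N-1)/N bias relative to the unbiased estimator is part of the
    contrast's definition and matters when comparing with closed-form
    speckle statistics.
    """
    if stack.scale != "db":
        raise ValueError("LIV is defined on dB-scaled stacks; convert first")
    if stack.n_frames < 2:
        raise ValueError("LIV needs at least 2 frames")
    mean_db = stack.data.mean(axis=0)
    liv = np.mean((stack.data - mean_db) ** 2, axis=0)
    return LIVMap(liv=liv, mean_db=mean_db, n_frames=stack.n_frames,
                  valid=stack.valid.copy(), location=stack.location)


def fuse_pseudo_color(
    liv_map: LIVMap,
    liv_range: tuple[float, float] = (0.0, 10.0),
    db_range: tuple[float, float] | None = None,
) -> PseudoColorImage:
    """Fuse LIV (hue, red -> green) with mean dB intensity (brightness).

    LIV is clipped to ``liv_range`` and mapped linearly onto hue angles
    0 deg (red) to 120 deg (green); the mean dB intensity is clipped and
    normalized to ``db_range`` as the HSV value channel with saturation 1.
    Invalid pixels render black.
    """
    lo, hi = liv_range
    if hi <= lo:
        raise ValueError("LIV display range must have positive width")
    if db_range is None:
        sel = liv_map.valid
        db_range = (float(liv_map.mean_db[sel].min()),
                    float(liv_map.mean_db[sel].max())) if sel.any() else (0.0, 1.0)
    dlo, dhi = db_range
    if dhi <= dlo:
        raise ValueError("dB display range must have positive width")
    if not (np.all(np.isfinite(liv_map.liv[liv_map.valid]))
            and np.all(np.isfinite(liv_map.mean_db[liv_map.valid]))):
        raise ValueError("maps must be finite where valid")

    hue = np.clip((liv_map.liv - lo) / (hi - lo), 0.0, 1.0) * (120.0 / 360.0)
    value = np.clip((liv_map.mean_db - dlo) / (dhi - dlo), 0.0, 1.0)
    hsv = np.stack([hue, np.ones_like(hue), value], axis=-1)
    rgb = hsv_to_rgb(hsv)
    rgb[~liv_map.valid] = 0.0
    return PseudoColorImage(rgb=rgb, liv_range=(lo, hi), db_range=(dlo, dhi))


class SurfaceNotFoundError(ValueError):
    """No A-line crosses the surface threshold."""


def detect_surface(
    mean_db_volume: np.ndarray,
    threshold_db: float | None = None,
    noise_rows: int = 8,
    k_sigma: float = 4.0,
    median_size: int = 3,
    min_run: int = 3,
) -> np.ndarray:
    """Locate the sample surface depth (px) on every A-line.

    ``mean_db_volume`` has axes (depth, fast, location). The surface is the
    first depth sample opening a run of ``min_run`` consecutive samples
    above a threshold — by default the noise mean plus ``k_sigma`` standard
    deviations, with noise statistics estimated from the top ``noise_rows``
    depth rows — then median-filtered across the en-face grid. Requiring a
    sustained run keeps isolated noise excursions from being mistaken for
    the sample top.
    """
    vol = np.asarray(mean_db_volume, dtype=float)
    if vol.ndim == 2:
        vol = vol[:, :, None]
    if vol.ndim != 3:
        raise ValueError("volume must be (depth, fast, location)")
    if threshold_db is None:
        noise = vol[:noise_rows]
        threshold_db = float(noise.mean() + k_sigma * noise.std())
    above = vol > threshold_db
    if min_run > 1:
        run = above[: above.shape[0] - min_run + 1].copy()
        for k in range(1, min_run):
            run &= above[k: above.shape[0] - min_run + 1 + k]
        above = run
    crossed = above.any(axis=0)
    if not crossed.any():
        raise SurfaceNotFoundError(
            f"no A-line exceeds threshold {threshold_db:.2f} dB")
    surface = np.argmax(above, axis=0).astype(float)
    if not crossed.all():
        surface[~crossed] = np.median(surface[crossed])
    if median_size > 1:
        surface = ndimage.median_filter(surface, size=median_size,
                                        mode="nearest")
    return surface


def fit_surface_plane(surface_depths: np.ndarray) -> tuple[float, float, float]:
    """Least-squares plane ``depth = a*fast + b*location + c`` through the
    detected surface (fast, location) grid. Mirrors the manual tilt of a
    flat en-face extraction plane to the sample surface."""
    surf = np.asarray(surface_depths, dtype=float)
    if surf.ndim != 2:
        raise ValueError("surface must be a (fast, location) grid")
    nx, nl = surf.shape
    xx, ll = np.meshgrid(np.arange(nx), np.arange(nl), indexing="ij")
    design = np.column_stack([xx.ravel(), ll.ravel(), np.ones(surf.size)])
    coef, *_ = np.linalg.lstsq(design, surf.ravel(), rcond=None)
    return float(coef[0]), float(coef[1]), float(coef[2])


def extract_enface(
    volume: np.ndarray,
    plane: tuple[float, float, float],
    depth_offset_um: float = 0.0,
    axial_pitch_um: float = 1.0,
) -> np.ndarray:
    """Sample a volume on a tilted flat plane offset below the surface.

    ``plane`` is ``(a, b, c)`` with depth ``a*fast + b*location + c``; the
    plane is displaced deeper by ``round(depth_offset_um / axial_pitch_um)``
    pixels and the volume is sampled at the nearest depth pixel (no axial
    interpolation, so LIV values are never mixed across depths). Raises if
    any sample point leaves the depth range.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim == 2:
        vol = vol[:, :, None]
    if axial_pitch_um <= 0:
        raise ValueError("axial pitch must be positive")
    nz, nx, nl = vol.shape
    a, b, c = plane
    offset_px = int(round(depth_offset_um / axial_pitch_um))
    xx, ll = np.meshgrid(np.arange(nx), np.arange(nl), indexing="ij")
    depth = np.rint(a * xx + b * ll + c).astype(int) + offset_px
    if depth.min() < 0 or depth.max() > nz - 1:
        raise ValueError(
            f"en-face plane leaves the depth range [0, {nz - 1}] "
            f"(sampled depths {depth.min()}..{depth.max()})")
    return vol[depth, xx, ll]
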