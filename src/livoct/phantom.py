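"""Synthetic dynamic-OCT phantom with known region dynamics.

The phantom emulates the appearance of an alveolar organoid under
repeated-B-scan OCT: cystic alveoli whose epithelial borders carry rapidly
decorrelating speckle (high temporal fluctuation), a mesh of fibroblast
strands with slow dynamics, optional hyper-scattering static inclusions
inside "filled" alveoli, an additive noise floor, and per-frame rigid bulk
motion. Every region's frame-to-frame correlation and mean intensity is
specified, so each downstream stage (motion correction, LIV, en-face
extraction, morphometry) can be tested against ground truth.

Dynamics model
--------------
Each pixel's complex OCT amplitude follows a stationary AR(1) circular
Gaussian process,

    a_0 ~ CN(0, mu),   a_t = rho * a_{t-1} + sqrt(1 - rho^2) * w_t,

with ``w_t ~ CN(0, mu)`` independent per frame and pixel. The marginal
intensity ``|a_t|^2`` is exponential with mean ``mu`` (fully developed
speckle) and the frame-to-frame amplitude correlation is exactly ``rho``:
``rho = 1`` is a frozen field, ``rho = 0`` decorrelates completely between
frames. Detected intensity adds an independent exponential noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .stack import FrameStack, MotionTrace

# Integer class labels partitioning the phantom grid.
CLASS_LABELS = {
    "background": 0,
    "lumen": 1,
    "epithelium_high": 2,   # rapidly decorrelating epithelium
    "epithelium_low": 3,    # slow sectors of tessellated epithelium
    "fibroblast": 4,
    "inclusion": 5,         # hyper-scattering static mass in filled alveoli
}

_LABEL_NAMES = {v: k for k, v in CLASS_LABELS.items()}


@dataclass
class Alveolus:
    """One cystic alveolus: a lumen disk wrapped in an epithelial annulus.

    ``center`` is (depth, fast, location) in pixel indices; geometry is a
    sphere in index space (a disk for single-location grids). ``tessellated``
    alternates high/low-dynamics labels in angular sectors of the annulus;
    ``filled`` places a static hyper-scattering inclusion inside the lumen.
    """

    center: tuple[float, float, float]
    lumen_radius_px: float
    epithelium_thickness_px: float
    filled: bool = False
    tessellated: bool = False

    def __post_init__(self) -> None:
        if self.lumen_radius_px <= 0:
            raise ValueError("lumen radius must be positive")
        if self.epithelium_thickness_px <= 0:
            raise ValueError("epithelium thickness must be positive")

    @property
    def outer_radius_px(self) -> float:
        return self.lumen_radius_px + self.epithelium_thickness_px

    @property
    def type_code(self) -> str:
        return f"T{int(self.tessellated)}F{int(self.filled)}"


@dataclass
class PhantomSpec:
    """Geometric and dynamic description of a synthetic organoid scene."""

    grid_shape: tuple[int, int, int] = (128, 128, 1)  # (depth, fast, locations)
    alveoli: Sequence[Alveolus] = field(default_factory=list)
    mesh_strands_per_slice: float = 0.0
    mesh_strand_width_px: float = 2.0
    # Mean linear intensity per class (arbitrary units > 0).
    class_intensity: dict[str, float] = field(default_factory=lambda: {
        "background": 1e-4,
        "lumen": 0.01,
        "epithelium_high": 1.0,
        "epithelium_low": 1.0,
        "fibroblast": 0.5,
        "inclusion": 2.0,
    })
    # Frame-to-frame amplitude correlation per class.
    class_correlation: dict[str, float] = field(default_factory=lambda: {
        "background": 0.0,
        "lumen": 0.0,
        "epithelium_high": 0.2,
        "epithelium_low": 0.95,
        "fibroblast": 0.95,
        "inclusion": 1.0,
    })
    noise_floor_mean: float = 0.01
    speckle_grain_px: float = 2.0
    tessellation_sectors: int = 8
    inclusion_radius_frac: float = 0.6
    # optional organoid capsule: a continuous scattering layer marking the
    # sample top, so surface detection has a step to find
    surface_depth_px: Optional[float] = None
    surface_layer_thickness_px: float = 3.0
    surface_tilt_fast: float = 0.0   # px of depth per fast-axis px
    surface_tilt_slow: float = 0.0   # px of depth per location
    bulk_motion: Optional[MotionTrace] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be three positive counts")
        for name in CLASS_LABELS:
            mu = self.class_intensity.get(name)
            rho = self.class_correlation.get(name)
            if mu is None or mu <= 0:
                raise ValueError(f"class {name!r} needs a positive mean intensity")
            if rho is None or not (0.0 <= rho <= 1.0):
                raise ValueError(f"class {name!r} correlation must lie in [0, 1]")
        if self.noise_floor_mean < 0:
            raise ValueError("noise floor mean must be >= 0")
        if self.mesh_strands_per_slice < 0:
            raise ValueError("mesh strand density must be >= 0")
        if self.speckle_grain_px < 0:
            raise ValueError("speckle grain must be >= 0")
        if self.tessellation_sectors < 2:
            raise ValueError("tessellation needs at least 2 sectors")
        if not (0 < self.inclusion_radius_frac <= 1):
            raise ValueError("inclusion radius fraction must be in (0, 1]")


def build_label_map(spec: PhantomSpec) -> np.ndarray:
    """Rasterize the phantom geometry into an integer class-label grid.

    Returns an int array of shape ``grid_shape`` = (depth, fast, locations).
    Fibroblast strands are drawn first; alveoli are painted in listing order
    (later alveoli overwrite earlier ones). An alveolus lying entirely
    outside the grid is an error.
    """
    nz, nx, nl = spec.grid_shape
    labels = np.zeros(spec.grid_shape, dtype=np.int8)

    if spec.surface_depth_px is not None:
        thick = max(1, int(round(spec.surface_layer_thickness_px)))
        xs = np.arange(nx)[:, None]
        ls = np.arange(nl)[None, :]
        top = np.rint(spec.surface_depth_px + spec.surface_tilt_fast * xs
                      + spec.surface_tilt_slow * ls).astype(int)
        if top.min() < 0 or top.max() + thick > nz:
            raise ValueError("surface layer leaves the depth range")
        zs = np.arange(nz)[:, None, None]
        layer = (zs >= top[None]) & (zs < (top + thick)[None])
        labels[layer] = CLASS_LABELS["fibroblast"]

    if spec.mesh_strands_per_slice > 0:
        _draw_mesh(labels, spec)

    zz, xx = np.meshgrid(np.arange(nz), np.arange(nx), indexing="ij")
    for k, alv in enumerate(spec.alveoli):
        cz, cx, cl = alv.center
        r_out = alv.outer_radius_px
        if (cz + r_out < 0 or cz - r_out > nz - 1
                or cx + r_out < 0 or cx - r_out > nx - 1
                or cl + r_out < 0 or cl - r_out > nl - 1):
            raise ValueError(f"alveolus {k} lies entirely outside the grid")
        for loc in range(max(0, int(np.floor(cl - r_out))),
                         min(nl, int(np.ceil(cl + r_out)) + 1)):
            dl2 = (loc - cl) ** 2
            r2 = zz * 0.0 + (zz - cz) ** 2 + (xx - cx) ** 2 + dl2
            lumen = r2 <= alv.lumen_radius_px ** 2
            epi = (r2 <= r_out ** 2) & ~lumen
            labels[:, :, loc][lumen] = CLASS_LABELS["lumen"]
            if alv.tessellated:
                theta = np.arctan2(xx - cx, zz - cz)  # (-pi, pi]
                sector = np.floor((theta + np.pi) / (2 * np.pi)
                                  * spec.tessellation_sectors).astype(int)
                sector = np.clip(sector, 0, spec.tessellation_sectors - 1)
                high = sector % 2 == 0
                labels[:, :, loc][epi & high] = CLASS_LABELS["epithelium_high"]
                labels[:, :, loc][epi & ~high] = CLASS_LABELS["epithelium_low"]
            else:
                labels[:, :, loc][epi] = CLASS_LABELS["epithelium_high"]
            if alv.filled:
                r_inc = spec.inclusion_radius_frac * alv.lumen_radius_px
                inc = r2 <= r_inc ** 2
                labels[:, :, loc][inc] = CLASS_LABELS["inclusion"]
    return labels


def _draw_mesh(labels: np.ndarray, spec: PhantomSpec) -> None:
    """Draw random fibroblast strands (dilated line segments) per slice."""
    from skimage.draw import line as sk_line

    nz, nx, nl = spec.grid_shape
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xF1B]))
    width = max(1, int(round(spec.mesh_strand_width_px)))
    n_strands = int(round(spec.mesh_strands_per_slice))
    for loc in range(nl):
        strand = np.zeros((nz, nx), dtype=bool)
        for _ in range(n_strands):
            z0, z1 = rng.integers(0, nz, size=2)
            x0, x1 = rng.integers(0, nx, size=2)
            rr, cc = sk_line(int(z0), int(x0), int(z1), int(x1))
            strand[rr, cc] = True
        if width > 1:
            strand = ndimage.binary_dilation(strand, iterations=width - 1)
        labels[:, :, loc][strand] = CLASS_LABELS["fibroblast"]


def _class_maps(labels: np.ndarray, spec: PhantomSpec):
    """Per-pixel mean intensity and correlation from the label grid."""
    mu = np.empty(labels.shape, dtype=float)
    rho = np.empty(labels.shape, dtype=float)
    for name, lab in CLASS_LABELS.items():
        sel = labels == lab
        mu[sel] = spec.class_intensity[name]
        rho[sel] = spec.class_correlation[name]
    return mu, rho


def simulate_timeseries(
    labels: np.ndarray,
    spec: PhantomSpec,
    n_frames: int = 32,
    seed: int | None = None,
    frame_interval_s: float = 0.23,
) -> list[FrameStack]:
    """Simulate linear-intensity repeated-frame stacks, one per location.

    Per pixel the complex amplitude follows the AR(1) circular-Gaussian
    process described in the module docstring, with class-specific mean
    intensity and frame-to-frame correlation; an independent exponential
    noise-floor realization is added per frame. Deterministic for a fixed
    (spec, seed).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if seed is None:
        seed = spec.seed
    if not isinstance(seed, (int, np.integer)):
        raise TypeError("seed must be an integer")
    labels = np.asarray(labels)
    if labels.shape != spec.grid_shape:
        raise ValueError("label map shape does not match spec grid shape")

    mu, rho = _class_maps(labels, spec)
    nz, nx, nl = labels.shape
    times = np.arange(n_frames) * frame_interval_s
    grain = spec.speckle_grain_px
    if grain > 0:
        # l2 norm of the smoothing kernel: filtering white noise scales the
        # std by this gain
        impulse = np.zeros((nz, nx))
        impulse[nz // 2, nx // 2] = 1.0
        gain = np.sqrt((ndimage.gaussian_filter(
            impulse, grain, mode="wrap") ** 2).sum())

    def unit_field(rng: np.random.Generator) -> np.ndarray:
        """Unit-variance circular complex Gaussian field with the spec's
        speckle grain (PSF-like spatial correlation). Low-pass filtering a
        Gaussian field keeps it Gaussian, so the intensity marginal stays
        exponential (fully developed speckle)."""
        w = (rng.normal(size=(nz, nx)) + 1j * rng.normal(size=(nz, nx))) \
            / np.sqrt(2.0)
        if grain > 0:
            w = (ndimage.gaussian_filter(w.real, grain, mode="wrap")
                 + 1j * ndimage.gaussian_filter(w.imag, grain, mode="wrap")) / gain
        return w

    stacks: list[FrameStack] = []
    for loc in range(nl):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), loc]))
        m = mu[:, :, loc]
        r = rho[:, :, loc]
        innov_scale = np.sqrt(np.maximum(0.0, 1.0 - r ** 2))
        amp = np.sqrt(m)  # E|a|^2 = m
        a = amp * unit_field(rng)
        frames = np.empty((n_frames, nz, nx), dtype=float)
        for t in range(n_frames):
            if t > 0:
                a = r * a + innov_scale * amp * unit_field(rng)
            intensity = np.abs(a) ** 2
            if spec.noise_floor_mean > 0:
                # noise floor: weak background speckle, fully decorrelated
                # between frames but PSF-correlated in space (exponential
                # intensity marginal of mean noise_floor_mean)
                intensity = intensity + spec.noise_floor_mean * \
                    np.abs(unit_field(rng)) ** 2
            frames[t] = intensity
        stacks.append(FrameStack(frames, times, scale="linear", location=loc))
    return stacks


def enface_footprints(spec: PhantomSpec) -> tuple[np.ndarray, dict[int, str]]:
    """Plan-view alveolus footprints on the (fast, location) en-face grid.

    Returns a label image (one positive integer per alveolus, later-listed
    alveoli overwrite earlier ones) and a mapping from label to the
    tessellated/filled type code — the ground-truth segmentation the
    morphometry stage would otherwise receive from a human operator.
    """
    _, nx, nl = spec.grid_shape
    label_img = np.zeros((nx, nl), dtype=np.int32)
    types: dict[int, str] = {}
    xx, ll = np.meshgrid(np.arange(nx), np.arange(nl), indexing="ij")
    for k, alv in enumerate(spec.alveoli, start=1):
        _, cx, cl = alv.center
        footprint = (xx - cx) ** 2 + (ll - cl) ** 2 <= alv.outer_radius_px ** 2
        if footprint.any():
            label_img[footprint] = k
            types[k] = alv.type_code
    types = {k: t for k, t in types.items() if (label_img == k).any()}
    return label_img, types


def inject_bulk_motion(stack: FrameStack, trace: MotionTrace) -> FrameStack:
    """Rigidly translate each frame by its trace entry (depth, fast) pixels.

    Uses the same third-order spline interpolation family as the motion
    correction stage, so correction can undo injection up to interpolation
    error. Frames with an exactly zero shift are passed through untouched.
    """
    if len(trace) != stack.n_frames:
        raise ValueError("trace length must equal the number of frames")
    out = stack.copy()
    for i, (dz, dx) in enumerate(trace.shifts):
        if dz == 0.0 and dx == 0.0:
            continue
        shifted = ndimage.shift(stack.data[i], (dz, dx), order=3, mode="nearest")
        if stack.scale == "linear":
            # cubic-spline overshoot can dip below zero near sharp speckle;
            # physical intensity cannot
            np.maximum(shifted, 0.0, out=shifted)
        out.data[i] = shifted
    return out
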