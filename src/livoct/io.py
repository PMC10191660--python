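"""File formats, pipeline configuration, and the end-to-end pipeline.

Interchange format: multi-page TIFF (frame-major for stacks, depth-major
for volumes) with a JSON sidecar carrying axes, scale flag (linear/dB),
timing and seed metadata. The pipeline runs simulate/ingest -> register ->
LIV -> en-face -> morphometry -> statistics and writes a manifest JSON
listing every product with its parameters and SHA-256 checksum; all
randomness flows from a single config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import phantom as ph
from .liv import (
    compute_liv, detect_surface, extract_enface, fit_surface_plane,
    fuse_pseudo_color, stack_to_db, LIVMap,
)
from .morphometry import compare_groups, records_from_labels, tally_alveoli
from .motion_correction import register_stack
from .scan_protocol import ScanProtocolParams, enface_pixel_pitch, protocol_report
from .stack import FrameStack, MotionTrace


# ---------------------------------------------------------------------------
# containers on disk

def write_stack(path: str | Path, stack: FrameStack) -> None:
    """Write a frame stack as multi-page TIFF + JSON sidecar (lossless)."""
    path = Path(path)
    tifffile.imwrite(path, stack.data, photometric="minisblack")
    sidecar = {
        "axes": "tzx",
        "scale": stack.scale,
        "location": stack.location,
        "times_s": stack.times.tolist(),
        "n_frames": stack.n_frames,
        "valid_all": bool(stack.valid.all()),
    }
    if not stack.valid.all():
        tifffile.imwrite(_valid_path(path), stack.valid.astype(np.uint8))
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_stack(path: str | Path) -> FrameStack:
    """Read a frame stack written by :func:`write_stack`."""
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"missing sidecar {side}")
    meta = json.loads(side.read_text())
    if meta.get("axes") != "tzx":
        raise ValueError(f"not a frame stack (axes={meta.get('axes')!r})")
    data = tifffile.imread(path)
    if data.ndim != 3:
        raise ValueError(f"expected 3 axes (t, z, x), got {data.ndim}")
    valid = None
    if not meta.get("valid_all", True):
        valid = tifffile.imread(_valid_path(path)).astype(bool)
    return FrameStack(data, np.asarray(meta["times_s"]), scale=meta["scale"],
                      location=int(meta["location"]), valid=valid)


def write_volume(path: str | Path, volume: np.ndarray,
                 meta: dict[str, Any] | None = None) -> None:
    """Write a (depth, fast, location) volume as TIFF + JSON sidecar."""
    path = Path(path)
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("volume must have axes (depth, fast, location)")
    tifffile.imwrite(path, volume, photometric="minisblack")
    sidecar = {"axes": "zxl", **(meta or {})}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_volume(path: str | Path) -> tuple[np.ndarray, dict[str, Any]]:
    """Read a volume written by :func:`write_volume`; returns (data, meta)."""
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"missing sidecar {side}")
    meta = json.loads(side.read_text())
    if meta.get("axes") != "zxl":
        raise ValueError(f"not a volume container (axes={meta.get('axes')!r})")
    data = tifffile.imread(path)
    if data.ndim != 3:
        raise ValueError(f"expected 3 axes (z, x, location), got {data.ndim}")
    return data, meta


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _valid_path(path: Path) -> Path:
    return path.with_name(path.stem + "_valid" + path.suffix)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, with explicit defaults."""

    protocol: ScanProtocolParams = field(default_factory=ScanProtocolParams)
    phantom: Optional[ph.PhantomSpec] = None
    n_frames: int = 32
    jitter_px: float = 0.0               # uniform +/- bulk-motion amplitude
    reference_index: Optional[int] = None
    upsample_factor: int = 10
    liv_display_range: tuple[float, float] = (0.0, 10.0)
    db_display_range: Optional[tuple[float, float]] = None
    db_floor_linear: Optional[float] = None  # default: phantom noise floor
    axial_pitch_um: Optional[float] = None
    enface_offset_um: float = 0.0
    seed: int = 0
    output_dir: str = "livoct_out"

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.upsample_factor < 1:
            raise ValueError("upsample_factor must be >= 1")
        if self.jitter_px < 0:
            raise ValueError("jitter amplitude must be >= 0")
        if self.enface_offset_um != 0.0 and self.axial_pitch_um is None:
            raise ValueError(
                "an en-face offset in um requires axial_pitch_um in the config")
        if self.axial_pitch_um is not None and self.axial_pitch_um <= 0:
            raise ValueError("axial pitch must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        if "protocol" in raw and isinstance(raw["protocol"], dict):
            raw["protocol"] = ScanProtocolParams(**raw["protocol"])
        if "phantom" in raw and isinstance(raw["phantom"], dict):
            p = dict(raw["phantom"])
            if "alveoli" in p:
                p["alveoli"] = [
                    a if isinstance(a, ph.Alveolus) else ph.Alveolus(
                        center=tuple(a["center"]),
                        lumen_radius_px=a["lumen_radius_px"],
                        epithelium_thickness_px=a["epithelium_thickness_px"],
                        filled=a.get("filled", False),
                        tessellated=a.get("tessellated", False))
                    for a in p["alveoli"]]
            if "grid_shape" in p:
                p["grid_shape"] = tuple(p["grid_shape"])
            raw["phantom"] = ph.PhantomSpec(**p)
        for key in ("liv_display_range", "db_display_range"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, MotionTrace):
                return obj.shifts.tolist()
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, list):
                return [enc(v) for v in obj]
            return obj
        return {f.name: enc(getattr(self, f.name))
                for f in dataclasses.fields(self)}


# ---------------------------------------------------------------------------
# pipeline

class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage and location index."""


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run simulate -> register -> LIV -> en-face -> morphometry end to end.

    Returns the manifest (also written to ``manifest.json`` in the output
    directory) listing every artifact with parameters and checksums.
    Deterministic for a fixed config + seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_root = np.random.SeedSequence(config.seed)
    child = {name: s for name, s in zip(
        ("simulate", "jitter"), rng_root.spawn(2))}

    spec = config.phantom
    if spec is None:
        raise PipelineError("stage=simulate: config has no phantom spec "
                            "and no input volume")
    artifacts: dict[str, str] = {}

    # -- simulate -----------------------------------------------------------
    sim_seed = int(child["simulate"].generate_state(1)[0] % (2 ** 31))
    labels = ph.build_label_map(spec)
    stacks = ph.simulate_timeseries(
        labels, spec, n_frames=config.n_frames, seed=sim_seed,
        frame_interval_s=config.protocol.frame_repeat_time_s)
    tifffile.imwrite(out / "labels.tif", labels.astype(np.int8),
                     photometric="minisblack")
    artifacts["labels"] = str(out / "labels.tif")

    # -- bulk motion + registration ----------------------------------------
    jit_rng = np.random.default_rng(child["jitter"])
    liv_vol = np.zeros(spec.grid_shape, dtype=float)
    mean_vol = np.zeros(spec.grid_shape, dtype=float)
    valid_vol = np.ones(spec.grid_shape, dtype=bool)
    trace_rows = []
    db_floor = config.db_floor_linear
    if db_floor is None:
        db_floor = spec.noise_floor_mean if spec.noise_floor_mean > 0 else 1e-6
    for loc, stack in enumerate(stacks):
        try:
            db_stack = stack_to_db(stack, db_floor)
            if config.jitter_px > 0:
                # rigid in-plane motion commutes with the pointwise dB
                # transform, so it is injected on the dB frames with the
                # same interpolation family the correction uses
                trace = MotionTrace(jit_rng.uniform(
                    -config.jitter_px, config.jitter_px,
                    size=(stack.n_frames, 2)))
                db_stack = ph.inject_bulk_motion(db_stack, trace)
            corrected, est = register_stack(
                db_stack, reference_index=config.reference_index,
                upsample_factor=config.upsample_factor)
            liv_map = compute_liv(corrected)
        except Exception as err:
            raise PipelineError(f"stage=register/liv location={loc}: {err}") from err
        liv_vol[:, :, loc] = liv_map.liv
        mean_vol[:, :, loc] = liv_map.mean_db
        valid_vol[:, :, loc] = liv_map.valid
        for i, (dz, dx) in enumerate(est.shifts):
            trace_rows.append({"location": loc, "frame_index": i,
                               "dz_px": dz, "dx_px": dx})

    write_volume(out / "liv.tif", liv_vol.astype(np.float32),
                 {"quantity": "LIV", "units": "dB^2", "n_frames": config.n_frames})
    write_volume(out / "mean_db.tif", mean_vol.astype(np.float32),
                 {"quantity": "mean intensity", "units": "dB"})
    pd.DataFrame(trace_rows).to_csv(out / "motion_trace.csv", index=False)
    artifacts["liv_volume"] = str(out / "liv.tif")
    artifacts["mean_volume"] = str(out / "mean_db.tif")
    artifacts["motion_trace"] = str(out / "motion_trace.csv")

    # -- en-face ------------------------------------------------------------
    try:
        surface = detect_surface(mean_vol)
        plane = fit_surface_plane(surface)
        pitch = config.axial_pitch_um or 1.0
        enface_liv = extract_enface(liv_vol, plane,
                                    config.enface_offset_um, pitch)
        enface_mean = extract_enface(mean_vol, plane,
                                     config.enface_offset_um, pitch)
    except Exception as err:
        raise PipelineError(f"stage=enface: {err}") from err
    tifffile.imwrite(out / "enface_liv.tif", enface_liv.astype(np.float32))
    artifacts["enface_liv"] = str(out / "enface_liv.tif")

    pseudo = fuse_pseudo_color(
        LIVMap(enface_liv, enface_mean, config.n_frames),
        liv_range=config.liv_display_range,
        db_range=config.db_display_range)
    import imageio.v3 as iio
    iio.imwrite(out / "enface_pseudocolor.png",
                (pseudo.rgb * 255).astype(np.uint8))
    artifacts["enface_pseudocolor"] = str(out / "enface_pseudocolor.png")

    # -- morphometry --------------------------------------------------------
    label_img, types = ph.enface_footprints(spec)
    records = []
    if types:
        pf, ps = enface_pixel_pitch(config.protocol)
        records = records_from_labels(label_img, types, pf, ps,
                                      source="phantom en-face")
        counts = tally_alveoli(records)
        pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
            out / "alveoli.csv", index=False)
        (out / "counts.json").write_text(json.dumps(counts, indent=1))
        artifacts["alveoli"] = str(out / "alveoli.csv")
        artifacts["counts"] = str(out / "counts.json")

    manifest = {
        "config": config.to_dict(),
        "n_locations": spec.grid_shape[2],
        "artifacts": {k: {"path": v, "sha256": sha256_of(v)}
                      for k, v in artifacts.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
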