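"""Containers for repeated-B-scan time series and in-plane motion traces."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class FrameStack:
    """The N repeated frames acquired at one B-scan location.

    Parameters
    ----------
    data
        Array of shape ``(N, n_depth, n_fast)``; frame index is time order.
    times
        Acquisition time of each frame in seconds, strictly increasing.
    scale
        ``"linear"`` for linear OCT intensity, ``"db"`` for dB-scaled.
    location
        Index of the B-scan location this stack belongs to.
    valid
        Boolean mask ``(n_depth, n_fast)``; ``False`` marks pixels
        invalidated by shifting (drawn from outside the original support).
    """

    data: np.ndarray
    times: np.ndarray
    scale: str = "linear"
    location: int = 0
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be (N, z, x), got shape {self.data.shape}")
        if self.data.shape[0] < 2:
            raise ValueError("a frame stack needs at least 2 frames")
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (self.data.shape[0],):
            raise ValueError("times must have one entry per frame")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.scale not in ("linear", "db"):
            raise ValueError(f"scale must be 'linear' or 'db', got {self.scale!r}")
        if self.valid is None:
            self.valid = np.ones(self.data.shape[1:], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.data.shape[1:]:
                raise ValueError("valid mask must match frame shape")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]  # type: ignore[return-value]

    def copy(self) -> "FrameStack":
        return replace(
            self,
            data=self.data.copy(),
            times=self.times.copy(),
            valid=self.valid.copy(),
        )


@dataclass
class MotionTrace:
    """Per-frame in-plane rigid shift (depth, fast) in pixels."""

    shifts: np.ndarray  # (N, 2) = (dz, dx) per frame

    def __post_init__(self) -> None:
        self.shifts = np.atleast_2d(np.asarray(self.shifts, dtype=float))
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must be an (N, 2) array of (dz, dx) pairs")
        if not np.all(np.isfinite(self.shifts)):
            raise ValueError("motion trace must be finite")

    def __len__(self) -> int:
        return self.shifts.shape[0]

    def __neg__(self) -> "MotionTrace":
        return MotionTrace(-self.shifts)
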