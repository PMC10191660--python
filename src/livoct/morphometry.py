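"""Morphometry of segmented alveoli on en-face LIV images.

Alveoli are manually segmented regions classified into four types by their
epithelial LIV appearance (non-tessellated T0 / tessellated T1) and mass
encapsulation (non-filled F0 / filled F1). This module measures each
region's area (mm^2) and circularity (4*pi*A/P^2, 1.0 for a perfect
circle), tallies counts per type, and compares normal vs model groups:
Welch's two-tailed t-test on means and the median-based Levene
(Brown-Forsythe) test on variances, with significance marks at
P < 0.1 / 0.05 / 0.01 and a skip rule for groups of 7 or fewer alveoli.

En-face pixels are strongly anisotropic (the slow-axis pitch is 4x the
fast-axis pitch on the standard grid), so shape measures are computed on a
nearest-neighbour resampling of the mask to an isotropic grid at the finer
pitch; perimeter on an anisotropic grid is ill-defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage, stats
from skimage import measure

ALVEOLUS_TYPES = ("T0F0", "T0F1", "T1F0", "T1F1")


@dataclass
class AlveolusRecord:
    """One segmented alveolus."""

    id: int
    type: str
    area_mm2: float
    circularity: float
    touches_border: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        if self.type not in ALVEOLUS_TYPES:
            raise ValueError(
                f"unknown alveolus type {self.type!r}; expected one of {ALVEOLUS_TYPES}")
        if self.area_mm2 <= 0:
            raise ValueError("area must be positive")
        if not (0 < self.circularity <= 1.0 + 1e-9):
            raise ValueError("circularity must lie in (0, 1]")


@dataclass
class GroupComparisonResult:
    """Outcome of one normal-vs-model comparison on a metric."""

    metric: str
    test: str            # "welch_t" or "brown_forsythe"
    statistic: float
    p_value: float
    mark: str            # "", ".", "*", "**"
    n_a: int
    n_b: int
    skipped: bool


def region_area(mask: np.ndarray, pitch_fast_um: float, pitch_slow_um: float) -> float:
    """Area of a binary mask in mm^2: pixel count x pixel area."""
    mask = np.asarray(mask, dtype=bool)
    count = int(mask.sum())
    if count == 0:
        raise ValueError("empty mask has no area")
    if pitch_fast_um <= 0 or pitch_slow_um <= 0:
        raise ValueError("pitches must be positive")
    return count * pitch_fast_um * pitch_slow_um * 1e-6


def _isotropic_mask(mask: np.ndarray, pitch_fast_um: float,
                    pitch_slow_um: float) -> tuple[np.ndarray, float]:
    """Nearest-neighbour resample onto an isotropic grid at min(pitch)."""
    pmin = min(pitch_fast_um, pitch_slow_um)
    zoom = (pitch_fast_um / pmin, pitch_slow_um / pmin)
    if zoom == (1.0, 1.0):
        return np.asarray(mask, dtype=bool), pmin
    # linear interpolation + 0.5 threshold reconstructs the boundary between
    # coarse samples; nearest-neighbour would leave staircase blocks that
    # inflate the perimeter
    iso = ndimage.zoom(np.asarray(mask, dtype=float), zoom, order=1) > 0.5
    return iso, pmin


def region_perimeter(mask: np.ndarray, pitch_fast_um: float = 1.0,
                     pitch_slow_um: float = 1.0) -> float:
    """Boundary length of a binary mask in micrometres.

    The mask (axes fast x slow) is resampled to an isotropic grid at the
    finer pitch, lightly smoothed to suppress the staircase bias of binary
    rasterization, and traced with a marching-squares contour at the 0.5
    level; the perimeter is the total length of all boundary contours.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no perimeter")
    iso, pmin = _isotropic_mask(mask, pitch_fast_um, pitch_slow_um)
    # smooth before contouring: suppresses the staircase bias of binary
    # rasterization, with the scale tied to the coarsest original pitch
    sigma = max(1.0, max(pitch_fast_um, pitch_slow_um) / pmin / 2.0)
    pad = int(np.ceil(2 * sigma)) + 1
    padded = np.pad(iso.astype(float), pad)
    smoothed = ndimage.gaussian_filter(padded, sigma=sigma)
    contours = measure.find_contours(smoothed, 0.5)
    if not contours:
        contours = measure.find_contours(padded, 0.5)
    total = 0.0
    for contour in contours:
        seg = np.diff(contour, axis=0)
        total += float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    return total * pmin


def circularity(area: float, perimeter: float) -> float:
    """Shape factor 4*pi*A/P^2, clipped to 1.0 (exact circle) for reporting.

    ``area`` and ``perimeter`` must be in consistent units (e.g. um^2, um).
    """
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return min(1.0, 4.0 * np.pi * area / perimeter ** 2)


def touches_border(mask: np.ndarray) -> bool:
    """True when any mask pixel lies on the outermost row or column."""
    mask = np.asarray(mask, dtype=bool)
    return bool(mask[0, :].any() or mask[-1, :].any()
                or mask[:, 0].any() or mask[:, -1].any())


def measure_region(
    mask: np.ndarray,
    pitch_fast_um: float,
    pitch_slow_um: float,
) -> tuple[float, float]:
    """Area (mm^2) and circularity of one binary region mask."""
    area_mm2 = region_area(mask, pitch_fast_um, pitch_slow_um)
    perim_um = region_perimeter(mask, pitch_fast_um, pitch_slow_um)
    circ = circularity(area_mm2 * 1e6, perim_um)
    return area_mm2, circ


def records_from_labels(
    label_image: np.ndarray,
    types: dict[int, str],
    pitch_fast_um: float,
    pitch_slow_um: float,
    source: str = "",
) -> list[AlveolusRecord]:
    """Build one record per labelled region of a segmentation mask.

    ``label_image`` holds one positive integer label per alveolus (0 =
    unsegmented); ``types`` maps each label to its Table-style type code
    (the tessellated/filled call is a manual annotation, not automated).
    """
    label_image = np.asarray(label_image)
    records = []
    for lab in np.unique(label_image):
        if lab == 0:
            continue
        if int(lab) not in types:
            raise KeyError(f"label {int(lab)} has no type annotation")
        mask = label_image == lab
        area_mm2, circ = measure_region(mask, pitch_fast_um, pitch_slow_um)
        records.append(AlveolusRecord(
            id=int(lab), type=types[int(lab)], area_mm2=area_mm2,
            circularity=circ, touches_border=touches_border(mask),
            source=source))
    return records


def tally_alveoli(
    records: Iterable[AlveolusRecord],
    exclude_border: bool = True,
) -> dict[str, int]:
    """Counts per type plus combined tessellated / non-tessellated totals.

    Alveoli overlaying the image periphery are excluded by default.
    """
    counts = {t: 0 for t in ALVEOLUS_TYPES}
    for rec in records:
        if exclude_border and rec.touches_border:
            continue
        counts[rec.type] += 1
    counts["tessellated"] = counts["T1F0"] + counts["T1F1"]
    counts["non_tessellated"] = counts["T0F0"] + counts["T0F1"]
    counts["total"] = counts["tessellated"] + counts["non_tessellated"]
    return counts


def significance_mark(p: float) -> str:
    """Mark for a p-value: '**' (<0.01), '*' (<0.05), '.' (<0.1), else ''."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return ""


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    metric_kind: str,
    metric_name: str = "",
    min_count: int = 7,
) -> GroupComparisonResult:
    """Compare two groups on a metric's mean or variance.

    ``metric_kind = "mean"`` runs a two-tailed Welch's t-test (unequal
    variances, Welch-Satterthwaite degrees of freedom); ``"variance"`` runs
    the median-based Levene (Brown-Forsythe) test. Groups with
    ``min_count`` or fewer samples (default 7) are too small to discuss:
    the comparison is flagged skipped and carries no significance mark.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if metric_kind not in ("mean", "variance"):
        raise ValueError("metric_kind must be 'mean' or 'variance'")
    skipped = len(a) <= min_count or len(b) <= min_count
    if not skipped and (len(a) < 2 or len(b) < 2):
        raise ValueError("each group needs at least 2 samples")

    if len(a) < 2 or len(b) < 2:
        stat, p = float("nan"), float("nan")
    elif metric_kind == "mean":
        stat, p = stats.ttest_ind(a, b, equal_var=False)
    else:
        stat, p = stats.levene(a, b, center="median")
    test = "welch_t" if metric_kind == "mean" else "brown_forsythe"
    mark = "" if (skipped or not np.isfinite(p)) else significance_mark(float(p))
    return GroupComparisonResult(
        metric=metric_name or metric_kind, test=test,
        statistic=float(stat), p_value=float(p), mark=mark,
        n_a=len(a), n_b=len(b), skipped=skipped)
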