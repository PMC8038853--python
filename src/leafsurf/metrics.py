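"""Leaf area, distortion statistics and time-series stability measures.

Leaf area is the strip-rectangle sum: each rolled strip contributes
(w_max - w_min) x (flattened bending-skeleton chord length). Distortion
at any pipeline stage is the mean/std of |h| — the distance of points
from the wl-plane. Series stability is quantified by consecutive-frame
area differences and the R^2 of a linear fit of area against frame
index (leaf growth within a phenological stage is near-linear, so a
stable reconstruction tracks a line closely).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .flattening import FlattenedSkeleton
from .pointcloud_io import LEAF, PointCloud3

__all__ = [
    "AreaResult",
    "DistortionStats",
    "SeriesStats",
    "leaf_area",
    "distortion_stats",
    "consecutive_diff_stats",
    "linear_fit_r2",
]

MM2_PER_CM2 = 100.0


@dataclass
class AreaResult:
    """Strip-rectangle leaf area; internal unit mm^2."""

    area_mm2: float
    per_strip: list = field(default_factory=list)   # (width, length, rect area)

    @property
    def area_cm2(self) -> float:
        return self.area_mm2 / MM2_PER_CM2


@dataclass
class DistortionStats:
    """Mean/std of the distance |h| from the wl-plane at one stage."""

    mean: float
    std: float
    stage: str


@dataclass
class SeriesStats:
    diffs_mean: float
    diffs_std: float
    r2: float = float("nan")
    slope: float = float("nan")
    intercept: float = float("nan")


def leaf_area(
    strips: list, bending_skeleton: FlattenedSkeleton
) -> AreaResult:
    """Sum of per-strip rectangles.

    ``strips`` are the rolled strips (``None`` or empty entries — strips
    skipped for sparsity — contribute zero area); the k-th rectangle is
    the strip's w-extent times the k-th flattened bending-skeleton chord
    length.
    """
    lengths = bending_skeleton.segment_lengths
    if len(strips) != len(lengths):
        raise ValueError(
            f"{len(strips)} strips vs {len(lengths)} skeleton segments"
        )
    per_strip = []
    total = 0.0
    for strip, length in zip(strips, lengths):
        if strip is None or len(strip) == 0:
            per_strip.append((0.0, float(length), 0.0))
            continue
        w = strip.coords[:, 1]
        width = float(w.max() - w.min())
        rect = width * float(length)
        per_strip.append((width, float(length), rect))
        total += rect
    if total == 0.0:
        warnings.warn("no strips contributed area; returning 0", stacklevel=2)
    return AreaResult(total, per_strip)


def distortion_stats(cloud: PointCloud3, stage: str) -> DistortionStats:
    """Mean and population standard deviation of |h| over the cloud."""
    if cloud.frame != LEAF:
        raise ValueError("distortion is measured in the leaf frame")
    if len(cloud) == 0:
        raise ValueError("empty cloud has no distortion statistics")
    d = np.abs(cloud.coords[:, 2])
    return DistortionStats(float(d.mean()), float(d.std()), stage)


def consecutive_diff_stats(areas) -> SeriesStats:
    """Mean and sample std of |area_{t+1} - area_t| over a time-ordered
    series (frame-to-frame jump magnitude; a stability measure)."""
    areas = np.asarray(areas, dtype=float)
    if len(areas) < 2:
        raise ValueError("need at least 2 frames for consecutive differences")
    diffs = np.abs(np.diff(areas))
    std = float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0
    return SeriesStats(float(diffs.mean()), std)


def linear_fit_r2(areas, frames=None) -> SeriesStats:
    """OLS line area = slope * frame + intercept and its R^2.

    A zero-variance series is a perfect constant fit: R^2 is defined as
    1 with a warning.
    """
    areas = np.asarray(areas, dtype=float)
    if len(areas) < 3:
        raise ValueError("need at least 3 frames for a regression")
    if frames is None:
        frames = np.arange(len(areas), dtype=float)
    frames = np.asarray(frames, dtype=float)
    diffs = consecutive_diff_stats(areas)
    if np.ptp(areas) == 0.0:
        warnings.warn("constant area series; R^2 defined as 1", stacklevel=2)
        return SeriesStats(diffs.diffs_mean, diffs.diffs_std, 1.0, 0.0, float(areas[0]))
    fit = stats.linregress(frames, areas)
    return SeriesStats(
        diffs.diffs_mean,
        diffs.diffs_std,
        float(fit.rvalue**2),
        float(fit.slope),
        float(fit.intercept),
    )
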