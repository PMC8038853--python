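"""End-to-end orchestration: preprocessing -> axes -> bending -> rolling
-> shape -> metrics, plus directory-level time-series runs.

Everything here is deterministic for a fixed input and configuration;
reports carry a hash of the configuration used to produce them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import axes as axes_mod
from .errors import LeafSurfError, PipelineError
from .flattening import (
    BendingResult,
    LeafSurface2D,
    RollingResult,
    acquire_shape,
    flatten_bending,
    flatten_rolling,
)
from .metrics import AreaResult, distortion_stats, leaf_area, linear_fit_r2
from .pointcloud_io import (
    PointCloud3,
    filter_z_threshold,
    read_ply,
    remove_statistical_outliers,
    write_ply,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "LeafFlatteningResult", "flatten_leaf", "run_flatten", "run_series"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the reconstruction.

    Geometry defaults follow the method's reference settings: a 100x100
    projection grid swept in 1-degree steps for the h-axis, 50 skeleton
    points, a 5-point strip-discard threshold, quadratic bending /
    cubic rolling fits and a 5% bending sampling expansion.
    """

    grid_m: int = 100
    theta_step_deg: float = 1.0
    skeleton_n: int = 50
    delta: int = 5
    degree_bending: int = 2
    degree_rolling: int = 3
    degree_alignment: int = 3
    expand_frac_bending: float = 0.05
    outlier_k: int = 50
    outlier_std_mult: float = 1.0
    z_min: float | None = None
    apply_outlier_filter: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("grid_m", "skeleton_n", "delta", "degree_bending",
                     "degree_rolling", "degree_alignment", "outlier_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.theta_step_deg <= 0 or self.expand_frac_bending < 0:
            raise ValueError("theta_step_deg must be positive; expansion non-negative")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class LeafFlatteningResult:
    """Everything one leaf run produces."""

    axes: axes_mod.LeafAxes
    leaf_cloud: PointCloud3          # P  (leaf frame)
    bending: BendingResult           # P', strips, S'_lh
    rolling: RollingResult           # P'', per-strip skeletons
    shape: LeafSurface2D
    area: AreaResult
    distortion: dict                 # stage -> DistortionStats
    config: PipelineConfig
    preprocessing: dict = field(default_factory=dict)

    def report(self) -> dict:
        """JSON-serializable per-run report (no timestamps: runs are
        reproducible and reports byte-comparable)."""
        strip_counts = [len(s) if s is not None else 0 for s in self.rolling.strips]
        return {
            "config_hash": self.config.config_hash,
            "area_mm2": self.area.area_mm2,
            "area_cm2": self.area.area_cm2,
            "theta_opt_deg": self.axes.theta_opt,
            "points": {
                "input": self.preprocessing.get("input", len(self.leaf_cloud)),
                "after_preprocessing": len(self.leaf_cloud),
                "flattened": len(self.rolling.flattened),
            },
            "strips": {
                "count": len(strip_counts),
                "skipped": self.rolling.skipped,
                "points_per_strip": strip_counts,
                "dropped_bending": self.bending.strips.dropped_count,
                "dropped_rolling": self.rolling.dropped_count,
            },
            "distortion_mm": {
                stage: {"mean": st.mean, "std": st.std}
                for stage, st in self.distortion.items()
            },
        }


def flatten_leaf(
    cloud: PointCloud3,
    config: PipelineConfig | None = None,
    preprocess: bool = False,
) -> LeafFlatteningResult:
    """Run the full reconstruction on a world-frame leaf cloud.

    Stages: optional preprocessing (z-threshold, statistical outlier
    removal), leaf-axis determination, bending flattening, rolling
    flattening with midline alignment, wl-projection and metrics
    (strip-rectangle area + per-stage distortion).
    """
    config = config or PipelineConfig()
    pre = {"input": len(cloud)}
    stage = "preprocessing"
    try:
        if preprocess:
            cloud = filter_z_threshold(cloud, config.z_min)
            if config.apply_outlier_filter and len(cloud) > config.outlier_k:
                cloud = remove_statistical_outliers(
                    cloud, config.outlier_k, config.outlier_std_mult
                )
            pre["after_preprocessing"] = len(cloud)

        stage = "leaf axis determination"
        leaf_axes = axes_mod.determine_axes(
            cloud, m=config.grid_m, theta_step_deg=config.theta_step_deg
        )
        p_cloud = axes_mod.to_leaf_frame(cloud, leaf_axes)

        stage = "bending flattening"
        bending = flatten_bending(
            p_cloud,
            n_points=config.skeleton_n,
            degree=config.degree_bending,
            expand_frac=config.expand_frac_bending,
            delta=config.delta,
        )

        stage = "rolling flattening"
        rolling = flatten_rolling(
            bending.strips,
            p_cloud,
            n_points=config.skeleton_n,
            degree=config.degree_rolling,
            alignment_degree=config.degree_alignment,
            delta=config.delta,
        )

        stage = "shape acquisition"
        shape = acquire_shape(
            rolling.flattened, bending.skeleton, rolling.strip_skeletons
        )

        stage = "metrics"
        area = leaf_area(rolling.strips, bending.skeleton)
        distortion = {
            "P": distortion_stats(p_cloud, "P"),
            "P'": distortion_stats(bending.flattened, "P'"),
            "P''": distortion_stats(rolling.flattened, "P''"),
        }
    except LeafSurfError as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    return LeafFlatteningResult(
        leaf_axes, p_cloud, bending, rolling, shape, area, distortion, config, pre
    )


# ---------------------------------------------------------------------------
# File-level entry points
# ---------------------------------------------------------------------------

def run_flatten(
    input_ply: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Flatten one PLY leaf and write artifacts.

    Outputs in ``out_dir``: ``flattened.ply`` (P'' with h as z),
    ``shape.ply`` (z = 0), ``shape.csv`` (w, l columns),
    ``skeleton.json`` and ``report.json``. Returns the report dict.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cloud = read_ply(input_ply)
    result = flatten_leaf(cloud, config, preprocess=True)

    flat = result.rolling.flattened
    write_ply(
        PointCloud3(flat.coords[:, [0, 1, 2]], frame="world", index=flat.index),
        out_dir / "flattened.ply",
    )
    shape_pts = result.shape.points
    shape3 = np.column_stack([shape_pts, np.zeros(len(shape_pts))])
    write_ply(PointCloud3(shape3), out_dir / "shape.ply")
    pd.DataFrame(
        {"w_mm": shape_pts[:, 1], "l_mm": shape_pts[:, 0]}
    ).to_csv(out_dir / "shape.csv", index=False)
    (out_dir / "skeleton.json").write_text(result.bending.raw_skeleton.to_json())
    report = result.report()
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def run_series(
    input_dir: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    manifest: list | None = None,
) -> dict:
    """Flatten every PLY frame in a directory (lexicographic order, or
    the order given by ``manifest``), then compute series statistics.

    Failing frames are logged and skipped; the summary lists them.
    Writes ``frames.csv`` and ``series.json``.
    """
    config = config or PipelineConfig()
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = (
        [input_dir / name for name in manifest]
        if manifest is not None
        else sorted(input_dir.glob("*.ply"))
    )
    if len(files) < 2:
        raise PipelineError("a series needs at least 2 frames")

    rows, skipped = [], []
    for frame, path in enumerate(files):
        try:
            cloud = read_ply(path)
            result = flatten_leaf(cloud, config, preprocess=True)
        except (LeafSurfError, OSError) as exc:
            logger.warning("frame %s skipped: %s", path.name, exc)
            skipped.append(path.name)
            continue
        rows.append(
            {
                "frame": frame,
                "file": path.name,
                "area_cm2": result.area.area_cm2,
                "mean_h_mm": result.distortion["P''"].mean,
                "std_h_mm": result.distortion["P''"].std,
                "dropped_points": result.bending.strips.dropped_count
                + result.rolling.dropped_count,
            }
        )
    if len(rows) < 2:
        raise PipelineError("fewer than 2 frames succeeded")
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "frames.csv", index=False)
    series = linear_fit_r2(df["area_cm2"].to_numpy(), df["frame"].to_numpy())
    summary = {
        "config_hash": config.config_hash,
        "n_frames": len(rows),
        "skipped_frames": skipped,
        "diffs_mean_cm2": series.diffs_mean,
        "diffs_std_cm2": series.diffs_std,
        "r2": series.r2,
        "slope_cm2_per_frame": series.slope,
        "intercept_cm2": series.intercept,
    }
    (out_dir / "series.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
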