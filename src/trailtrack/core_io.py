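"""Domain types, calibration config, and readers/writers for detection and
trajectory tables.

Coordinate convention: origin at the top-left of the video frame, x rightward,
y downward, continuous pixel coordinates, 0-based frame indices.

Detection CSV dialect: ``frame,x,y[,confidence][,a0..aK]`` — one row per
detection, no ID column (MOT-challenge-like detector output).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Detection",
    "FrameSet",
    "TrailConfig",
    "Trajectory",
    "MetricRecord",
    "ConfigError",
    "read_detections",
    "write_trajectories",
    "read_trajectories",
    "load_config",
    "parse_clock",
    "format_clock",
]


class ConfigError(ValueError):
    """Raised when a configuration file fails validation."""


@dataclass(frozen=True)
class Detection:
    """One detected ant in one frame (pixel coordinates)."""

    frame: int
    x_px: float
    y_px: float
    confidence: float = 1.0
    appearance: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError(f"frame must be >= 0, got {self.frame}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0,1], got {self.confidence}")


@dataclass
class FrameSet:
    """Per-frame detections plus the view geometry they live in.

    ``frames`` maps frame index -> list of Detection; frames with no
    detections may be absent from the map but are treated as empty.
    """

    frames: dict[int, list[Detection]]
    view_width_px: int
    view_height_px: int
    fps: float

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.view_width_px <= 0 or self.view_height_px <= 0:
            raise ValueError("view dimensions must be positive")

    @property
    def frame_indices(self) -> list[int]:
        return sorted(self.frames)

    @property
    def n_detections(self) -> int:
        return sum(len(v) for v in self.frames.values())

    def get(self, frame: int) -> list[Detection]:
        return self.frames.get(frame, [])

    def span(self) -> tuple[int, int]:
        """(first, last) frame index with any detection; (0, -1) when empty."""
        if not self.frames:
            return 0, -1
        idx = self.frame_indices
        return idx[0], idx[-1]


def parse_clock(value: str | float | int) -> float:
    """Parse a wall-clock time to seconds since midnight.

    Accepts ``"HH:MM"``, ``"HH:MM:SS"`` or a bare number of seconds.
    """
    if isinstance(value, (int, float)):
        return float(value)
    parts = str(value).strip().split(":")
    if len(parts) not in (2, 3):
        raise ConfigError(f"cannot parse clock time {value!r}")
    try:
        nums = [float(p) for p in parts]
    except ValueError as exc:
        raise ConfigError(f"cannot parse clock time {value!r}") from exc
    h, m = nums[0], nums[1]
    s = nums[2] if len(nums) == 3 else 0.0
    return h * 3600.0 + m * 60.0 + s


def format_clock(seconds: float) -> str:
    """Format seconds-since-midnight as HH:MM:SS (wraps past midnight)."""
    s = int(round(seconds)) % 86400
    return f"{s // 3600:02d}:{(s % 3600) // 60:02d}:{s % 60:02d}"


@dataclass
class TrailConfig:
    """Calibration and geometry for one filmed trail.

    ``cm_per_px`` comes from the in-video ruler; ``start_clock`` is the
    wall-clock time of frame 0 (seconds since midnight, or "HH:MM:SS").
    ``nest_side`` states which end of the trail axis leads to the nest.
    """

    cm_per_px: float
    fps: float
    start_clock: float = 0.0
    nest_side: str = "low"
    trail_axis: str = "x"
    edge_margin_frac: float = 0.05
    cell_size_cm: float = 1.0
    view_width_px: int | None = None
    view_height_px: int | None = None

    def __post_init__(self) -> None:
        errors = []
        if self.cm_per_px <= 0:
            errors.append("cm_per_px")
        if self.fps <= 0:
            errors.append("fps")
        if self.nest_side not in ("low", "high"):
            errors.append("nest_side")
        if self.trail_axis not in ("x", "y"):
            errors.append("trail_axis")
        if not (0.0 < self.edge_margin_frac < 0.5):
            errors.append("edge_margin_frac")
        if self.cell_size_cm <= 0:
            errors.append("cell_size_cm")
        if errors:
            raise ConfigError(f"invalid config keys: {', '.join(errors)}")
        if isinstance(self.start_clock, str):
            object.__setattr__(self, "start_clock", parse_clock(self.start_clock))

    def view_extent_px(self, fs: FrameSet | None = None) -> tuple[float, float]:
        """(trail-axis extent, cross-axis extent) in pixels."""
        w = self.view_width_px if self.view_width_px else (fs.view_width_px if fs else None)
        h = self.view_height_px if self.view_height_px else (fs.view_height_px if fs else None)
        if w is None or h is None:
            raise ConfigError("view dimensions unavailable: set view_width_px/view_height_px")
        return (float(w), float(h)) if self.trail_axis == "x" else (float(h), float(w))


@dataclass
class Trajectory:
    """An identified ant's sequence of positions across frames.

    Pixel-space arrays are always present; calibrated arrays (``t_s``,
    ``clock_s``, ``x_cm``, ``y_cm``) are populated by
    :func:`trailtrack.preprocess.calibrate_trajectory`.
    """

    ant_id: int
    frames: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    interpolated: np.ndarray | None = None
    t_s: np.ndarray | None = None
    clock_s: np.ndarray | None = None
    x_cm: np.ndarray | None = None
    y_cm: np.ndarray | None = None
    complete: bool = False
    uturn_part: str = "none"
    direction: str = "unknown"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.frames), dtype=bool)
        else:
            self.interpolated = np.asarray(self.interpolated, dtype=bool)
        if len(self.frames) < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing within a trajectory")
        if self.uturn_part not in ("none", "first", "second"):
            raise ValueError(f"invalid uturn_part {self.uturn_part!r}")
        if self.direction not in ("outbound", "inbound", "unknown"):
            raise ValueError(f"invalid direction {self.direction!r}")

    @property
    def n_samples(self) -> int:
        return len(self.frames)

    @property
    def calibrated(self) -> bool:
        return self.x_cm is not None

    def axis_px(self, axis: str) -> np.ndarray:
        return self.x_px if axis == "x" else self.y_px

    def axis_cm(self, axis: str) -> np.ndarray:
        if not self.calibrated:
            raise ValueError("trajectory is not calibrated")
        return self.x_cm if axis == "x" else self.y_cm

    def copy_with(self, **changes) -> "Trajectory":
        return replace(self, **changes)


@dataclass
class MetricRecord:
    """Per-trajectory movement metrics."""

    ant_id: int
    d_cm: float
    L_cm: float
    ST: float
    mean_speed_cm_s: float
    direction: str = "unknown"
    EI: float = float("nan")
    AEI: float = float("nan")
    uturn_part: str = "none"
    complete: bool = False
    start_clock: float = float("nan")
    end_clock: float = float("nan")

    def __post_init__(self) -> None:
        if self.L_cm > 0 and not np.isclose(self.ST, self.d_cm / self.L_cm):
            raise ValueError("ST must equal d_cm / L_cm")
        if not (0.0 <= self.ST <= 1.0 + 1e-12):
            raise ValueError(f"ST must lie in [0,1], got {self.ST}")


_REQUIRED_DET_COLS = ("frame", "x", "y")


def read_detections(path: str | os.PathLike, view: tuple[int, int], fps: float) -> FrameSet:
    """Read a detection CSV into a :class:`FrameSet`.

    Parameters
    ----------
    path
        CSV with columns ``frame,x,y`` plus optional ``confidence`` and
        appearance columns ``a0..aK``.
    view
        (width_px, height_px) bounds detections must fall inside.
    fps
        Frame rate of the source video.
    """
    width, height = view
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return FrameSet(frames={}, view_width_px=width, view_height_px=height, fps=fps)
    missing = [c for c in _REQUIRED_DET_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    app_cols = sorted(
        (c for c in df.columns if c.startswith("a") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    for col in (*_REQUIRED_DET_COLS, *(["confidence"] if "confidence" in df.columns else []), *app_cols):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"{path}: malformed value in column {col!r} at line {line}")
        df[col] = coerced

    out_x = (df["x"] < 0) | (df["x"] > width)
    out_y = (df["y"] < 0) | (df["y"] > height)
    if (out_x | out_y).any():
        line = int((out_x | out_y).idxmax()) + 2
        raise ValueError(f"{path}: coordinates outside view bounds at line {line}")
    if (df["frame"] < 0).any():
        line = int((df["frame"] < 0).idxmax()) + 2
        raise ValueError(f"{path}: negative frame index at line {line}")

    frames: dict[int, list[Detection]] = {}
    has_conf = "confidence" in df.columns
    for row in df.itertuples(index=False):
        d = Detection(
            frame=int(getattr(row, "frame")),
            x_px=float(getattr(row, "x")),
            y_px=float(getattr(row, "y")),
            confidence=float(getattr(row, "confidence")) if has_conf else 1.0,
            appearance=tuple(float(getattr(row, c)) for c in app_cols) if app_cols else None,
        )
        frames.setdefault(d.frame, []).append(d)
    return FrameSet(frames=frames, view_width_px=width, view_height_px=height, fps=fps)


_SAMPLE_COLS = ["ant_id", "frame", "t_s", "clock", "x_cm", "y_cm", "x_px", "y_px", "interpolated"]
_METRIC_COLS = [
    "ant_id", "d_cm", "L_cm", "ST", "mean_speed_cm_s", "direction",
    "EI", "AEI", "uturn_part", "complete", "start_clock", "end_clock",
]


def write_trajectories(
    trajs: list[Trajectory],
    records: list[MetricRecord],
    path: str | os.PathLike,
) -> tuple[str, str]:
    """Write a long-format samples table and a per-trajectory metrics table.

    ``path`` is a directory; ``samples.csv`` and ``metrics.csv`` are created
    inside it. Every metric record's ant_id must refer to a trajectory.
    Returns the two file paths.
    """
    traj_ids = {t.ant_id for t in trajs}
    orphans = [r.ant_id for r in records if r.ant_id not in traj_ids]
    if orphans:
        raise ValueError(f"metric records reference unknown ant_ids: {sorted(set(orphans))}")

    os.makedirs(path, exist_ok=True)
    rows = []
    for t in trajs:
        n = t.n_samples
        nan = np.full(n, np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "ant_id": np.full(n, t.ant_id, dtype=np.int64),
                    "frame": t.frames,
                    "t_s": t.t_s if t.t_s is not None else nan,
                    "clock": t.clock_s if t.clock_s is not None else nan,
                    "x_cm": t.x_cm if t.x_cm is not None else nan,
                    "y_cm": t.y_cm if t.y_cm is not None else nan,
                    "x_px": t.x_px,
                    "y_px": t.y_px,
                    "interpolated": t.interpolated.astype(int),
                }
            )
        )
    samples = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=_SAMPLE_COLS)
    flags = pd.DataFrame(
        {
            "ant_id": [t.ant_id for t in trajs],
            "complete": [int(t.complete) for t in trajs],
            "uturn_part": [t.uturn_part for t in trajs],
            "direction": [t.direction for t in trajs],
        }
    )
    metrics = pd.DataFrame(
        [
            {
                "ant_id": r.ant_id,
                "d_cm": r.d_cm,
                "L_cm": r.L_cm,
                "ST": r.ST,
                "mean_speed_cm_s": r.mean_speed_cm_s,
                "direction": r.direction,
                "EI": r.EI,
                "AEI": r.AEI,
                "uturn_part": r.uturn_part,
                "complete": int(r.complete),
                "start_clock": r.start_clock,
                "end_clock": r.end_clock,
            }
            for r in records
        ],
        columns=_METRIC_COLS,
    )
    samples_path = os.path.join(path, "samples.csv")
    metrics_path = os.path.join(path, "metrics.csv")
    flags_path = os.path.join(path, "trajectory_flags.csv")
    samples.to_csv(samples_path, index=False, float_format="%.12g")
    metrics.to_csv(metrics_path, index=False, float_format="%.12g")
    flags.to_csv(flags_path, index=False)
    return samples_path, metrics_path


def read_trajectories(path: str | os.PathLike) -> tuple[list[Trajectory], list[MetricRecord]]:
    """Read back trajectories written by :func:`write_trajectories`."""
    samples = pd.read_csv(os.path.join(path, "samples.csv"))
    metrics = pd.read_csv(os.path.join(path, "metrics.csv"))
    flags_file = os.path.join(path, "trajectory_flags.csv")
    flags = pd.read_csv(flags_file) if os.path.exists(flags_file) else pd.DataFrame(columns=["ant_id"])
    flag_map = {int(r.ant_id): r for r in flags.itertuples(index=False)}

    trajs = []
    if len(samples):
        for ant_id, grp in samples.groupby("ant_id", sort=True):
            grp = grp.sort_values("frame")
            f = flag_map.get(int(ant_id))
            calibrated = not grp["x_cm"].isna().all()
            trajs.append(
                Trajectory(
                    ant_id=int(ant_id),
                    frames=grp["frame"].to_numpy(),
                    x_px=grp["x_px"].to_numpy(),
                    y_px=grp["y_px"].to_numpy(),
                    interpolated=grp["interpolated"].to_numpy().astype(bool),
                    t_s=grp["t_s"].to_numpy() if calibrated else None,
                    clock_s=grp["clock"].to_numpy() if calibrated else None,
                    x_cm=grp["x_cm"].to_numpy() if calibrated else None,
                    y_cm=grp["y_cm"].to_numpy() if calibrated else None,
                    complete=bool(f.complete) if f is not None else False,
                    uturn_part=str(f.uturn_part) if f is not None else "none",
                    direction=str(f.direction) if f is not None else "unknown",
                )
            )
    records = [
        MetricRecord(
            ant_id=int(r.ant_id),
            d_cm=float(r.d_cm),
            L_cm=float(r.L_cm),
            ST=float(r.ST),
            mean_speed_cm_s=float(r.mean_speed_cm_s),
            direction=str(r.direction),
            EI=float(r.EI),
            AEI=float(r.AEI),
            uturn_part=str(r.uturn_part),
            complete=bool(r.complete),
            start_clock=float(r.start_clock),
            end_clock=float(r.end_clock),
        )
        for r in metrics.itertuples(index=False)
    ]
    return trajs, records


_CONFIG_DEFAULTS = {
    "start_clock": 0.0,
    "nest_side": "low",
    "trail_axis": "x",
    "edge_margin_frac": 0.05,
    "cell_size_cm": 1.0,
    "view_width_px": None,
    "view_height_px": None,
}


def load_config(path: str | os.PathLike) -> TrailConfig:
    """Load a YAML/JSON trail configuration.

    Required keys: ``cm_per_px``, ``fps``. All other keys take documented
    defaults. Unknown keys raise :class:`ConfigError`.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {"cm_per_px", "fps", *_CONFIG_DEFAULTS}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {', '.join(unknown)}")
    missing = sorted(k for k in ("cm_per_px", "fps") if k not in raw)
    if missing:
        raise ConfigError(f"{path}: missing required keys: {', '.join(missing)}")
    kwargs = dict(_CONFIG_DEFAULTS)
    kwargs.update(raw)
    return TrailConfig(**kwargs)
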