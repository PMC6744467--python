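"""Calibration into physical units, edge-start filtering, U-turn splitting,
and travel-direction assignment."""

from __future__ import annotations

import numpy as np

from .core_io import TrailConfig, Trajectory

__all__ = [
    "calibrate_trajectory",
    "filter_edge_starts",
    "split_uturns",
    "assign_direction",
]


def calibrate_trajectory(t: Trajectory, cfg: TrailConfig) -> Trajectory:
    """Attach seconds, wall-clock time, and cm coordinates to every sample."""
    t_s = t.frames / cfg.fps
    return t.copy_with(
        t_s=t_s,
        clock_s=cfg.start_clock + t_s,
        x_cm=t.x_px * cfg.cm_per_px,
        y_cm=t.y_px * cfg.cm_per_px,
    )


def _entry_exit_boundaries(
    t: Trajectory, cfg: TrailConfig
) -> tuple[str | None, str | None]:
    """Boundary ('low'/'high') nearest each endpoint, or None when the
    endpoint lies outside the edge margin (mid-view)."""
    extent_px, _ = cfg.view_extent_px()
    margin = cfg.edge_margin_frac * extent_px
    axis = t.axis_px(cfg.trail_axis)

    def _boundary(pos: float) -> str | None:
        if pos <= margin:
            return "low"
        if pos >= extent_px - margin:
            return "high"
        return None

    return _boundary(float(axis[0])), _boundary(float(axis[-1]))


def filter_edge_starts(
    trajs: list[Trajectory], cfg: TrailConfig
) -> tuple[list[Trajectory], list[tuple[Trajectory, str]]]:
    """Keep only trajectories that both start and end at a trail-axis edge.

    Mid-view starts or ends mark partial tracks (the ant did not cross the
    whole view); kept trajectories are flagged ``complete``. Returns
    ``(kept, removed)`` with a reason per removed trajectory.
    """
    kept: list[Trajectory] = []
    removed: list[tuple[Trajectory, str]] = []
    for t in trajs:
        entry, exit_ = _entry_exit_boundaries(t, cfg)
        if entry is None:
            removed.append((t, "midview_start"))
        elif exit_ is None:
            removed.append((t, "midview_end"))
        else:
            kept.append(t.copy_with(complete=True))
    return kept, removed


def split_uturns(t: Trajectory, cfg: TrailConfig) -> list[Trajectory]:
    """Split a U-turning trajectory at its deepest penetration of the trail.

    A trajectory entering and exiting at the same trail-axis boundary is cut
    at the sample attaining the global extremum of the trail-axis
    coordinate; the split sample belongs to both parts. Non-U-turns (and
    trajectories with fewer than 3 samples) are returned unchanged.
    """
    if t.n_samples < 3:
        return [t]
    entry, exit_ = _entry_exit_boundaries(t, cfg)
    if entry is None or exit_ is None or entry != exit_:
        return [t]
    axis = t.axis_cm(cfg.trail_axis) if t.calibrated else t.axis_px(cfg.trail_axis)
    pivot = int(np.argmax(axis)) if entry == "low" else int(np.argmin(axis))
    if pivot == 0 or pivot == t.n_samples - 1:
        return [t]  # degenerate: extremum at an endpoint, nothing to split

    def _slice(sl: slice, part: str) -> Trajectory:
        arr = lambda a: None if a is None else a[sl]
        return Trajectory(
            ant_id=t.ant_id,
            frames=t.frames[sl],
            x_px=t.x_px[sl],
            y_px=t.y_px[sl],
            interpolated=t.interpolated[sl],
            t_s=arr(t.t_s),
            clock_s=arr(t.clock_s),
            x_cm=arr(t.x_cm),
            y_cm=arr(t.y_cm),
            complete=t.complete,
            uturn_part=part,
            direction=t.direction,
        )

    return [_slice(slice(0, pivot + 1), "first"), _slice(slice(pivot, None), "second")]


def assign_direction(t: Trajectory, cfg: TrailConfig) -> Trajectory:
    """Label a trajectory inbound (towards the nest) or outbound.

    Whole crossings are labelled from the boundary where the ant exited;
    U-turn parts, whose inner endpoint is mid-view by construction, are
    labelled from the sign of their net trail-axis displacement.
    """
    axis = t.axis_px(cfg.trail_axis)
    if t.uturn_part != "none":
        delta = float(axis[-1] - axis[0])
        if delta == 0:
            return t.copy_with(direction="unknown")
        heading = "high" if delta > 0 else "low"
        return t.copy_with(direction="inbound" if heading == cfg.nest_side else "outbound")
    _, exit_ = _entry_exit_boundaries(t, cfg)
    if exit_ is None:
        return t.copy_with(direction="unknown")
    return t.copy_with(direction="inbound" if exit_ == cfg.nest_side else "outbound")
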