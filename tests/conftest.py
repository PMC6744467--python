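import math

import numpy as np
import pytest

from trailtrack.core_io import Detection, FrameSet, TrailConfig, Trajectory


@pytest.fixture
def cfg() -> TrailConfig:
    """600x120 px view of a 15x3 cm trail at 25 fps, nest on the low side."""
    return TrailConfig(
        cm_per_px=0.025,
        fps=25.0,
        start_clock="19:30:00",
        nest_side="low",
        trail_axis="x",
        view_width_px=600,
        view_height_px=120,
    )


def make_frameset(rows, width=600, height=120, fps=25.0) -> FrameSet:
    """rows: iterable of (frame, x, y) or Detection."""
    frames: dict[int, list[Detection]] = {}
    for r in rows:
        d = r if isinstance(r, Detection) else Detection(frame=r[0], x_px=r[1], y_px=r[2])
        frames.setdefault(d.frame, []).append(d)
    return FrameSet(frames=frames, view_width_px=width, view_height_px=height, fps=fps)


def make_trajectory(points_cm, ant_id=0, fps=25.0, cm_per_px=0.025, start_clock=70200.0,
                    **flags) -> Trajectory:
    """Calibrated trajectory through the given (x_cm, y_cm) points, one per frame."""
    pts = np.asarray(points_cm, dtype=float)
    frames = np.arange(len(pts))
    t_s = frames / fps
    return Trajectory(
        ant_id=ant_id,
        frames=frames,
        x_px=pts[:, 0] / cm_per_px,
        y_px=pts[:, 1] / cm_per_px,
        t_s=t_s,
        clock_s=start_clock + t_s,
        x_cm=pts[:, 0],
        y_cm=pts[:, 1],
        **flags,
    )


def straight_line_detections(n_frames, x0, y0, vx, vy, start_frame=0):
    """(frame, x, y) rows for a constant-velocity ant."""
    return [
        (start_frame + k, x0 + vx * k, y0 + vy * k)
        for k in range(n_frames)
    ]


def brute_force_assignment(cost: np.ndarray, bd: float) -> float:
    """Minimum total cost over every one-to-one partial matching.

    Exhaustive enumeration (feasible for n, m <= 6); infeasible pairs are
    np.inf entries in ``cost``. Each unmatched supplier or receiver costs
    ``bd``.
    """
    n, m = cost.shape
    best = math.inf

    def rec(i: int, used: frozenset, acc: float) -> None:
        nonlocal best
        if acc >= best:
            return
        if i == n:
            total = acc + bd * (m - len(used))
            best = min(best, total)
            return
        rec(i + 1, used, acc + bd)  # supplier i dies
        for j in range(m):
            if j not in used and math.isfinite(cost[i, j]):
                rec(i + 1, used | {j}, acc + cost[i, j])

    rec(0, frozenset(), 0.0)
    return best
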