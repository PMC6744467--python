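"""Per-trajectory movement metrics and trail-occupancy analysis.

The straightness index is net displacement over path length (1 = perfectly
straight, 0 = returned to start). Trail occupancy is summarized on a square
grid (default 1 cm cells): the visiting map counts, per cell, either the
number of distinct trajectories passing through (``trajectories`` mode) or
the number of cell-entry events (``entries`` mode). The exploration index
scores a trajectory by how rarely-visited its cells are relative to the
busiest cell of the map.

NOTE: the per-cell exploration score s(c) = (V_max - V(c)) / (V_max - 1) and
the normalization of AEI by the count of distinct cells traversed are this
package's concrete choices; they satisfy the documented bounds (AEI in
[0,1], 1 = sole-visitor cells only, 0 = maximally shared cells only) but
other scorings with the same bounds exist.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np

from .core_io import MetricRecord, TrailConfig, Trajectory

__all__ = [
    "VisitingMap",
    "path_length_and_displacement",
    "straightness",
    "average_speed",
    "segment_cells",
    "trajectory_cells",
    "visiting_map",
    "exploration_index",
    "export_heatmap",
    "compute_metrics",
]


@dataclass
class VisitingMap:
    """Grid-cell visit counts over the trail view.

    ``counts[row, col]`` covers the half-open square
    ``[col*s, (col+1)*s) x [row*s, (row+1)*s)`` in cm, with ``s =
    cell_size_cm`` and the origin at the view's top-left corner.
    """

    cell_size_cm: float
    n_cols: int
    n_rows: int
    mode: str
    counts: np.ndarray
    origin_cm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.mode not in ("entries", "trajectories"):
            raise ValueError(f"unknown visiting-map mode {self.mode!r}")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.n_rows, self.n_cols):
            raise ValueError("counts shape must be (n_rows, n_cols)")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def v_max(self) -> int:
        """Maximum count over visited cells (0 when nothing is visited)."""
        return int(self.counts.max(initial=0))


def path_length_and_displacement(t: Trajectory) -> tuple[float, float]:
    """(L, d): total path length and net start-to-end displacement, in cm."""
    if not t.calibrated:
        raise ValueError("trajectory must be calibrated first")
    if t.n_samples < 2:
        raise ValueError("need at least 2 samples")
    dx, dy = np.diff(t.x_cm), np.diff(t.y_cm)
    L = float(np.hypot(dx, dy).sum())
    d = float(math.hypot(t.x_cm[-1] - t.x_cm[0], t.y_cm[-1] - t.y_cm[0]))
    return L, d


def straightness(t: Trajectory) -> float:
    """d / L. Undefined (ValueError) for stationary trajectories."""
    L, d = path_length_and_displacement(t)
    if L <= 0:
        raise ValueError("straightness undefined for a stationary trajectory (L = 0)")
    return min(d / L, 1.0)


def average_speed(t: Trajectory) -> float:
    """Path length over elapsed time, cm/s."""
    if t.t_s is None:
        raise ValueError("trajectory must be calibrated first")
    duration = float(t.t_s[-1] - t.t_s[0])
    if duration <= 0:
        raise ValueError("zero-duration trajectory")
    L, _ = path_length_and_displacement(t)
    return L / duration


def segment_cells(
    x0: float, y0: float, x1: float, y1: float, s: float
) -> list[tuple[int, int]]:
    """Ordered (col, row) cells traversed by the segment (x0,y0)->(x1,y1).

    Grid traversal crossing every cell boundary in order; ties (exact corner
    hits) advance diagonally, so consecutive cells always share at least a
    corner and no cell is skipped regardless of segment length.
    """
    c, r = int(math.floor(x0 / s)), int(math.floor(y0 / s))
    c_end, r_end = int(math.floor(x1 / s)), int(math.floor(y1 / s))
    cells = [(c, r)]
    dx, dy = x1 - x0, y1 - y0
    step_c = 1 if dx > 0 else -1
    step_r = 1 if dy > 0 else -1
    if dx > 0:
        t_max_x, t_dx = ((c + 1) * s - x0) / dx, s / dx
    elif dx < 0:
        t_max_x, t_dx = (c * s - x0) / dx, -s / dx
    else:
        t_max_x = t_dx = math.inf
    if dy > 0:
        t_max_y, t_dy = ((r + 1) * s - y0) / dy, s / dy
    elif dy < 0:
        t_max_y, t_dy = (r * s - y0) / dy, -s / dy
    else:
        t_max_y = t_dy = math.inf

    guard = 4 * (abs(c_end - c) + abs(r_end - r) + 2)
    while (c, r) != (c_end, r_end) and guard > 0:
        guard -= 1
        # never step an axis past its destination cell: endpoints landing
        # exactly on a boundary belong to the half-open end cell
        can_x = c != c_end
        can_y = r != r_end
        if t_max_x < t_max_y:
            take_x, take_y = (True, False) if can_x else (False, True)
        elif t_max_y < t_max_x:
            take_x, take_y = (False, True) if can_y else (True, False)
        else:  # exact corner: advance both feasible axes
            take_x, take_y = can_x, can_y
        if take_x:
            c += step_c
            t_max_x += t_dx
        if take_y:
            r += step_r
            t_max_y += t_dy
        cells.append((c, r))
    return cells


def _grid_shape(cfg: TrailConfig) -> tuple[int, int, float]:
    if cfg.view_width_px is None or cfg.view_height_px is None:
        raise ValueError("config must carry view_width_px/view_height_px to build a map")
    w_cm = cfg.view_width_px * cfg.cm_per_px
    h_cm = cfg.view_height_px * cfg.cm_per_px
    s = cfg.cell_size_cm
    return max(1, math.ceil(w_cm / s)), max(1, math.ceil(h_cm / s)), s


def trajectory_cells(t: Trajectory, cfg: TrailConfig) -> list[tuple[int, int]]:
    """Ordered cell sequence visited by a calibrated trajectory (duplicates
    kept so entry events can be counted; junction cells not repeated)."""
    if not t.calibrated:
        raise ValueError("trajectory must be calibrated first")
    n_cols, n_rows, s = _grid_shape(cfg)
    eps = 1e-9
    xs = np.clip(t.x_cm, 0.0, n_cols * s - eps)
    ys = np.clip(t.y_cm, 0.0, n_rows * s - eps)
    seq: list[tuple[int, int]] = []
    for k in range(len(xs) - 1):
        part = segment_cells(float(xs[k]), float(ys[k]), float(xs[k + 1]), float(ys[k + 1]), s)
        if seq and part and part[0] == seq[-1]:
            part = part[1:]
        seq.extend(part)
    if not seq:  # single point or all samples in one cell
        seq = [(int(xs[0] // s), int(ys[0] // s))]
    return [(min(max(c, 0), n_cols - 1), min(max(r, 0), n_rows - 1)) for c, r in seq]


def visiting_map(
    trajs: list[Trajectory], cfg: TrailConfig, mode: str = "trajectories"
) -> VisitingMap:
    """Build the per-cell visit-count grid over the view.

    ``trajectories`` mode counts distinct trajectories per cell;
    ``entries`` mode counts entry events (the first cell of a trajectory
    counts as one entry, and every transition into a different cell counts
    again — re-entries included).
    """
    n_cols, n_rows, s = _grid_shape(cfg)
    counts = np.zeros((n_rows, n_cols), dtype=np.int64)
    for t in trajs:
        seq = trajectory_cells(t, cfg)
        if mode == "trajectories":
            for c, r in set(seq):
                counts[r, c] += 1
        elif mode == "entries":
            prev = None
            for cell in seq:
                if cell != prev:
                    counts[cell[1], cell[0]] += 1
                prev = cell
        else:
            raise ValueError(f"unknown visiting-map mode {mode!r}")
    return VisitingMap(cell_size_cm=s, n_cols=n_cols, n_rows=n_rows, mode=mode, counts=counts)


def exploration_index(t: Trajectory, vm: VisitingMap) -> tuple[float, float]:
    """(EI, AEI) of one trajectory against a trajectories-mode visiting map.

    Each distinct cell contributes s(c) = (V_max - V(c)) / (V_max - 1)
    (1 when V_max == 1); EI is the sum over the trajectory's distinct cells
    and AEI the mean, so AEI is 1 on sole-visitor cells and 0 on cells every
    trajectory shares.
    """
    if vm.mode != "trajectories":
        raise ValueError("exploration_index requires a trajectories-mode map")
    cells = set(trajectory_cells(t, vm_cfg_stub(vm)))
    if not cells:
        raise ValueError("trajectory traverses zero cells")
    v_max = vm.v_max
    if v_max < 1:
        raise ValueError("visiting map is empty")
    ei = 0.0
    for c, r in cells:
        v = vm.counts[r, c]
        if v < 1:
            raise ValueError("trajectory visits a cell absent from the map")
        ei += 1.0 if v_max == 1 else (v_max - v) / (v_max - 1)
    return ei, ei / len(cells)


def vm_cfg_stub(vm: VisitingMap) -> TrailConfig:
    """Minimal config matching a map's grid, for re-rasterizing trajectories."""
    return TrailConfig(
        cm_per_px=1.0,
        fps=1.0,
        cell_size_cm=vm.cell_size_cm,
        view_width_px=int(round(vm.n_cols * vm.cell_size_cm)),
        view_height_px=int(round(vm.n_rows * vm.cell_size_cm)),
    )


def export_heatmap(vm: VisitingMap, path: str | os.PathLike) -> tuple[str, str]:
    """Write the visit grid as ``<path>.csv`` and ``<path>.png``.

    The image uses a monotone colormap (darker = more visits) scaled to this
    map's own maximum, so scales differ between maps by design.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    base = os.fspath(path)
    csv_path, png_path = base + ".csv", base + ".png"
    np.savetxt(csv_path, vm.counts, fmt="%d", delimiter=",")
    vmax = max(vm.v_max, 1)
    plt.imsave(png_path, vm.counts, cmap="Greys", vmin=0, vmax=vmax)
    return csv_path, png_path


def compute_metrics(
    t: Trajectory, vm: VisitingMap | None = None
) -> MetricRecord:
    """Assemble the full metric record for one calibrated trajectory."""
    L, d = path_length_and_displacement(t)
    st = straightness(t)
    speed = average_speed(t)
    if vm is not None:
        ei, aei = exploration_index(t, vm)
    else:
        ei = aei = float("nan")
    return MetricRecord(
        ant_id=t.ant_id,
        d_cm=d,
        L_cm=L,
        ST=st,
        mean_speed_cm_s=speed,
        direction=t.direction,
        EI=ei,
        AEI=aei,
        uturn_part=t.uturn_part,
        complete=t.complete,
        start_clock=float(t.clock_s[0]) if t.clock_s is not None else float("nan"),
        end_clock=float(t.clock_s[-1]) if t.clock_s is not None else float("nan"),
    )
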