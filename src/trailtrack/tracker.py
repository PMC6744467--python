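"""Frame-to-frame data association by minimum-cost assignment.

Consecutive frames are linked by solving a rectangular assignment problem in
which detections in frame K are suppliers and detections in frame K+1 are
receivers. Dummy nodes charge a fixed ``birth_death_cost`` for every
unmatched detection, so the solver trades off matching against track
birth/death globally per frame pair. Costs are gated: pairs farther apart
than ``gate_px`` can never match.

On top of the per-pair solver, :func:`build_trajectories` maintains active
tracklets across the whole video with constant-velocity miss recovery,
linear gap interpolation, and post-hoc pruning of short or low-displacement
tracklets (false-positive suppression).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core_io import Detection, FrameSet, TrailConfig, Trajectory

__all__ = [
    "TrackParams",
    "AssignmentResult",
    "CueRecord",
    "pairwise_cost",
    "solve_frame_assignment",
    "build_trajectories",
    "extract_cues",
    "select_training_frames",
]

_BIG = 1e9  # stand-in for an infeasible edge inside the LAP matrix


@dataclass(frozen=True)
class TrackParams:
    """Knobs of the tracker.

    ``gate_px`` bounds the plausible per-frame displacement; costs are
    normalized by it so ``birth_death_cost`` is scale-free. Tracklets
    shorter than ``min_track_frames`` samples or moving less than
    ``min_track_disp_px`` net are discarded as probable false positives.
    """

    gate_px: float = 30.0
    w_app: float = 1.0
    birth_death_cost: float = 1.5
    max_gap_frames: int = 5
    min_track_frames: int = 13
    min_track_disp_px: float = 10.0

    def __post_init__(self) -> None:
        if self.gate_px <= 0:
            raise ValueError("gate_px must be > 0")
        if self.birth_death_cost <= 0:
            raise ValueError("birth_death_cost must be > 0")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")


@dataclass
class AssignmentResult:
    """Solution of one frame-pair assignment."""

    matches: list[tuple[int, int, float]]
    births: list[int]
    deaths: list[int]
    total_cost: float
    margins: dict[tuple[int, int], float] = field(default_factory=dict)


@dataclass(frozen=True)
class CueRecord:
    """A location flagged as a likely detection/tracking difficulty."""

    cue_type: str  # speed | interior_termination | ambiguity
    frame: int
    x_px: float
    y_px: float
    magnitude: float

    def __post_init__(self) -> None:
        if self.cue_type not in ("speed", "interior_termination", "ambiguity"):
            raise ValueError(f"unknown cue_type {self.cue_type!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")


def _appearance_distance(
    a: tuple[float, ...],
    b: tuple[float, ...],
    ranges: np.ndarray | None,
) -> float:
    va = np.asarray(a, dtype=float)
    vb = np.asarray(b, dtype=float)
    r = np.ones(len(va)) if ranges is None else np.asarray(ranges, dtype=float)
    diff = (va - vb) / np.where(r > 0, r, 1.0)
    # normalized by sqrt(dim) so the term stays in [0, 1] for range-scaled features
    return float(np.linalg.norm(diff) / math.sqrt(len(va)))


def pairwise_cost(
    a: Detection,
    b: Detection,
    p: TrackParams,
    app_ranges: np.ndarray | None = None,
) -> float:
    """Dissimilarity between a supplier and a receiver detection.

    ``euclidean(a, b) / gate_px + w_app * appdist(a, b)``; ``math.inf`` when
    the spatial distance exceeds the gate. ``app_ranges`` holds per-dimension
    feature ranges (from the pooled frame pair) used to scale the appearance
    term into [0, 1]; without them raw differences are used.
    """
    if (a.appearance is None) != (b.appearance is None):
        raise ValueError("both detections must have appearance vectors, or neither")
    if a.appearance is not None and len(a.appearance) != len(b.appearance):
        raise ValueError(
            f"appearance length mismatch: {len(a.appearance)} vs {len(b.appearance)}"
        )
    dist = math.hypot(a.x_px - b.x_px, a.y_px - b.y_px)
    if dist > p.gate_px:
        return math.inf
    cost = dist / p.gate_px
    if a.appearance is not None:
        cost += p.w_app * _appearance_distance(a.appearance, b.appearance, app_ranges)
    return cost


def _appearance_ranges(dets: list[Detection]) -> np.ndarray | None:
    vecs = [d.appearance for d in dets if d.appearance is not None]
    if not vecs:
        return None
    arr = np.asarray(vecs, dtype=float)
    return arr.max(axis=0) - arr.min(axis=0)


def _cost_matrix(
    k_dets: list[Detection], k1_dets: list[Detection], p: TrackParams
) -> np.ndarray:
    ranges = _appearance_ranges([*k_dets, *k1_dets])
    n, m = len(k_dets), len(k1_dets)
    c = np.full((n, m), _BIG)
    for i, a in enumerate(k_dets):
        for j, b in enumerate(k1_dets):
            cij = pairwise_cost(a, b, p, app_ranges=ranges)
            if math.isfinite(cij):
                c[i, j] = cij
    return c


def _solve_padded(c: np.ndarray, bd: float) -> tuple[list[tuple[int, int, float]], float]:
    """Solve the assignment with birth/death dummies; return matches and total cost."""
    n, m = c.shape
    big = np.full((n + m, n + m), _BIG)
    big[:n, :m] = c
    big[n:, m:] = 0.0
    for i in range(n):
        big[i, m + i] = bd  # death of supplier i
    for j in range(m):
        big[n + j, j] = bd  # birth of receiver j
    rows, cols = linear_sum_assignment(big)
    matches = []
    n_unmatched = 0
    for r, cidx in zip(rows, cols):
        if r < n and cidx < m:
            if c[r, cidx] >= _BIG:  # infeasible edge chosen never expected, guard anyway
                n_unmatched += 2
            else:
                matches.append((int(r), int(cidx), float(c[r, cidx])))
        elif r < n or cidx < m:
            n_unmatched += 1
    matches.sort()
    total = sum(cost for _, _, cost in matches) + bd * n_unmatched
    return matches, total


def solve_frame_assignment(
    k_dets: list[Detection],
    k1_dets: list[Detection],
    p: TrackParams,
    compute_margins: bool = False,
) -> AssignmentResult:
    """Globally optimal one-to-one partial matching between two frames.

    Every unmatched detection (birth or death) is charged
    ``p.birth_death_cost``. With ``compute_margins`` each match also gets the
    increase in total cost incurred if that match were forbidden — low
    margins mark ambiguous associations.
    """
    n, m = len(k_dets), len(k1_dets)
    if n == 0 or m == 0:
        return AssignmentResult(
            matches=[],
            births=list(range(m)),
            deaths=list(range(n)),
            total_cost=p.birth_death_cost * (n + m),
        )
    c = _cost_matrix(k_dets, k1_dets, p)
    matches, total = _solve_padded(c, p.birth_death_cost)
    matched_i = {i for i, _, _ in matches}
    matched_j = {j for _, j, _ in matches}
    result = AssignmentResult(
        matches=matches,
        births=[j for j in range(m) if j not in matched_j],
        deaths=[i for i in range(n) if i not in matched_i],
        total_cost=total,
    )
    if compute_margins:
        for i, j, _ in matches:
            forbidden = c.copy()
            forbidden[i, j] = _BIG
            _, alt_total = _solve_padded(forbidden, p.birth_death_cost)
            result.margins[(i, j)] = max(0.0, alt_total - total)
    return result


@dataclass
class _Tracklet:
    samples: list[tuple[int, float, float]]  # (frame, x, y) observed only
    appearance: tuple[float, ...] | None
    misses: int = 0

    def head(self, frame: int) -> Detection:
        """Constant-velocity prediction of the tracklet position at ``frame``.

        Velocity is averaged over the last few observed steps, which damps
        both detector jitter and per-frame heading noise.
        """
        f_last, x, y = self.samples[-1]
        if len(self.samples) >= 2:
            back = min(4, len(self.samples) - 1)
            f_prev, xp, yp = self.samples[-1 - back]
            dt = f_last - f_prev
            vx, vy = (x - xp) / dt, (y - yp) / dt
        else:
            vx = vy = 0.0
        lead = frame - f_last
        return Detection(
            frame=frame, x_px=x + vx * lead, y_px=y + vy * lead, appearance=self.appearance
        )


def _finalize(tracklet: _Tracklet, ant_id: int) -> Trajectory:
    obs = tracklet.samples
    frames, xs, ys, interp = [], [], [], []
    for idx, (f, x, y) in enumerate(obs):
        if idx > 0:
            f0, x0, y0 = obs[idx - 1]
            for g in range(f0 + 1, f):  # bridge the gap linearly
                w = (g - f0) / (f - f0)
                frames.append(g)
                xs.append(x0 + w * (x - x0))
                ys.append(y0 + w * (y - y0))
                interp.append(True)
        frames.append(f)
        xs.append(x)
        ys.append(y)
        interp.append(False)
    return Trajectory(
        ant_id=ant_id, frames=np.array(frames), x_px=np.array(xs), y_px=np.array(ys),
        interpolated=np.array(interp),
    )


def build_trajectories(fs: FrameSet, p: TrackParams) -> list[Trajectory]:
    """Link a whole FrameSet into trajectories.

    Active tracklet heads compete against each new frame's detections in the
    per-pair assignment; a tracklet that misses its match survives up to
    ``max_gap_frames`` frames on a constant-velocity prediction before it is
    closed. Closed tracklets failing the length or displacement floors are
    dropped. Surviving trajectories receive sequential ids in order of first
    appearance, with bridged samples flagged as interpolated.
    """
    first, last = fs.span()
    if last < first:
        return []
    active: list[_Tracklet] = []
    closed: list[_Tracklet] = []

    for frame in range(first, last + 1):
        dets = fs.get(frame)
        suppliers = [t.head(frame) for t in active]
        res = solve_frame_assignment(suppliers, dets, p)
        next_active: list[_Tracklet] = []
        for i, j, _ in res.matches:
            t = active[i]
            d = dets[j]
            t.samples.append((frame, d.x_px, d.y_px))
            t.appearance = d.appearance
            t.misses = 0
            next_active.append(t)
        for i in res.deaths:
            t = active[i]
            t.misses += 1
            if t.misses > p.max_gap_frames:
                closed.append(t)
            else:
                next_active.append(t)
        for j in res.births:
            d = dets[j]
            next_active.append(
                _Tracklet(samples=[(frame, d.x_px, d.y_px)], appearance=d.appearance)
            )
        active = next_active
    closed.extend(active)

    kept = []
    for t in closed:
        if len(t.samples) < 2:
            continue
        f0, x0, y0 = t.samples[0]
        f1, x1, y1 = t.samples[-1]
        n_frames = f1 - f0 + 1
        disp = math.hypot(x1 - x0, y1 - y0)
        if n_frames < p.min_track_frames or disp < p.min_track_disp_px:
            continue
        kept.append(t)
    kept.sort(key=lambda t: (t.samples[0][0], t.samples[0][1], t.samples[0][2]))
    return [_finalize(t, ant_id) for ant_id, t in enumerate(kept)]


def extract_cues(
    fs: FrameSet,
    trajs: list[Trajectory],
    cfg: TrailConfig,
    p: TrackParams,
    speed_percentile: float = 99.5,
    ambiguity_margin: float = 0.05,
) -> list[CueRecord]:
    """Flag likely tracking errors for hard-frame mining.

    Three cue families: (i) per-frame steps above the ``speed_percentile`` of
    all observed step lengths; (ii) trajectories starting or ending in the
    view interior (farther than ``edge_margin_frac`` of the extent from every
    boundary); (iii) assignment matches whose cost margin is below
    ``ambiguity_margin`` while a competing detection sits within the gate of
    the same receiver.
    """
    cues: list[CueRecord] = []
    w = cfg.view_width_px or fs.view_width_px
    h = cfg.view_height_px or fs.view_height_px
    mx, my = cfg.edge_margin_frac * w, cfg.edge_margin_frac * h

    # (i) speed cues
    steps = []
    for t in trajs:
        obs = ~t.interpolated
        f, x, y = t.frames[obs], t.x_px[obs], t.y_px[obs]
        if len(f) < 2:
            continue
        d = np.hypot(np.diff(x), np.diff(y)) / np.diff(f)
        steps.append((t, f[1:], x[1:], y[1:], d))
    all_steps = np.concatenate([s[4] for s in steps]) if steps else np.array([])
    if len(all_steps):
        thresh = float(np.percentile(all_steps, speed_percentile))
        for _, f, x, y, d in steps:
            for k in np.nonzero(d > thresh)[0]:
                cues.append(CueRecord("speed", int(f[k]), float(x[k]), float(y[k]), float(d[k])))

    # (ii) interior start/termination cues
    def _interior(x: float, y: float) -> float | None:
        dist = min(x, w - x, y, h - y)
        inside = (mx < x < w - mx) and (my < y < h - my)
        return dist if inside else None

    first, last = fs.span()
    for t in trajs:
        for idx, endpoint_frame in ((0, first), (-1, last)):
            f = int(t.frames[idx])
            if f == endpoint_frame:
                continue  # truncated by the video itself, not by tracking
            dist = _interior(float(t.x_px[idx]), float(t.y_px[idx]))
            if dist is not None:
                cues.append(
                    CueRecord("interior_termination", f, float(t.x_px[idx]), float(t.y_px[idx]), dist)
                )

    # (iii) ambiguity cues
    for frame in range(first, last):
        k_dets, k1_dets = fs.get(frame), fs.get(frame + 1)
        if len(k_dets) < 1 or len(k1_dets) < 2:
            continue
        res = solve_frame_assignment(k_dets, k1_dets, p, compute_margins=True)
        for i, j, _ in res.matches:
            margin = res.margins[(i, j)]
            if margin >= ambiguity_margin:
                continue
            rx, ry = k1_dets[j].x_px, k1_dets[j].y_px
            competitor = any(
                math.hypot(d.x_px - rx, d.y_px - ry) <= p.gate_px
                for jj, d in enumerate(k1_dets)
                if jj != j
            )
            if competitor:
                cues.append(CueRecord("ambiguity", frame + 1, float(rx), float(ry), float(margin)))
    return cues


def select_training_frames(
    fs: FrameSet,
    cues: list[CueRecord],
    n: int,
    mode: str = "random",
    seed: int | None = None,
) -> list[int]:
    """Pick frames to annotate.

    ``random`` draws a uniform sample without replacement; ``hard`` ranks
    frames by cue count (ties broken by earliest frame).
    """
    first, last = fs.span()
    frames = list(range(first, last + 1)) if last >= first else []
    if n > len(frames):
        raise ValueError(f"requested {n} frames but only {len(frames)} available")
    if n == 0:
        return []
    if mode == "random":
        rng = np.random.default_rng(seed)
        return sorted(int(f) for f in rng.choice(frames, size=n, replace=False))
    if mode == "hard":
        counts: dict[int, int] = {}
        for c in cues:
            counts[c.frame] = counts.get(c.frame, 0) + 1
        ranked = sorted(frames, key=lambda f: (-counts.get(f, 0), f))
        return ranked[:n]
    raise ValueError(f"unknown mode {mode!r}")
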