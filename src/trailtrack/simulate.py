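"""Seeded synthetic trail scenes with ground truth, detector-noise
corruption, and tracking evaluation.

Ants arrive at either end of a ~15 cm trail view by a Poisson process and
walk a goal-directed correlated random walk: each frame the heading points
at the exit end plus von Mises noise whose concentration is set per
straightness group. The concentration for a target straightness m is the
closed-form inversion of E[cos(noise)] = I1(kappa)/I0(kappa) = m, which
makes realized d/L distributions center near the group means (lateral
reflection at the trail edges adds mild extra tortuosity).

Detection corruption (jitter, misses, uniform false positives, merging of
close pairs) emulates an imperfect detector; tracking output is compared
against ground truth with per-trajectory error-free rates, ID-switch counts
and per-ant recall.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize, special, stats

from .core_io import Detection, FrameSet, Trajectory

__all__ = [
    "SimParams",
    "NoiseParams",
    "GroundTruthAnt",
    "SimulationScene",
    "TrackEvalReport",
    "kappa_for_straightness",
    "simulate_scene",
    "corrupt_detections",
    "evaluate_tracking",
    "write_scene",
    "truth_to_trajectories",
]

# straightness-group mixing weights and target mean straightness of the
# four observed forager groups (straight .. curvy)
DEFAULT_GROUP_WEIGHTS = (0.370, 0.262, 0.300, 0.068)
DEFAULT_GROUP_ST = (0.94, 0.88, 0.77, 0.49)


@dataclass(frozen=True)
class SimParams:
    """Scene generation parameters (defaults follow the field observations:
    15 cm view, mean speed 5.15 +/- 1.63 cm/s truncated above 0.5)."""

    n_ants: int = 50
    view_len_cm: float = 15.0
    trail_width_cm: float = 3.0
    px_per_cm: float = 40.0
    fps: float = 25.0
    arrival_rate: float = 0.5  # ants per second (Poisson)
    min_arrival_gap_s: float = 0.0  # force temporal separation when > 0
    speed_mean: float = 5.15
    speed_sd: float = 1.63
    speed_min: float = 0.5
    group_weights: tuple[float, ...] = DEFAULT_GROUP_WEIGHTS
    group_st_targets: tuple[float, ...] = DEFAULT_GROUP_ST
    uturn_prob: float = 0.05
    nest_side: str = "low"
    start_clock: float = 70200.0  # 19:30
    stratified_speeds: bool = False  # stratified truncnorm draws (variance reduction)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ants < 1:
            raise ValueError("n_ants must be >= 1")
        for name in ("view_len_cm", "trail_width_cm", "px_per_cm", "fps",
                     "arrival_rate", "speed_mean", "speed_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if len(self.group_weights) != len(self.group_st_targets):
            raise ValueError("group_weights and group_st_targets must align")
        if not math.isclose(sum(self.group_weights), 1.0, abs_tol=1e-9):
            raise ValueError("group_weights must sum to 1")
        if not (0.0 <= self.uturn_prob <= 1.0):
            raise ValueError("uturn_prob must be in [0,1]")

    @property
    def view_width_px(self) -> int:
        return int(round(self.view_len_cm * self.px_per_cm))

    @property
    def view_height_px(self) -> int:
        return int(round(self.trail_width_cm * self.px_per_cm))


@dataclass(frozen=True)
class NoiseParams:
    """Detector imperfection model."""

    jitter_px: float = 0.0
    miss_rate: float = 0.0
    fp_rate: float = 0.0  # expected false positives per frame
    merge_dist_px: float = 0.0

    def __post_init__(self) -> None:
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be >= 0")
        if not (0.0 <= self.miss_rate <= 1.0):
            raise ValueError("miss_rate must be in [0,1]")
        if self.fp_rate < 0 or self.merge_dist_px < 0:
            raise ValueError("fp_rate and merge_dist_px must be >= 0")


@dataclass
class GroundTruthAnt:
    """One simulated ant's true path."""

    ant_id: int
    frames: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    group: int
    speed_cm_s: float
    uturn: bool
    entry_side: str  # low | high

    @property
    def n_samples(self) -> int:
        return len(self.frames)


@dataclass
class SimulationScene:
    """Ground truth plus (optionally corrupted) observations of one scene."""

    truth: list[GroundTruthAnt]
    clean: FrameSet
    params: SimParams
    seed: int
    corrupted: FrameSet | None = None

    @property
    def detections(self) -> FrameSet:
        return self.corrupted if self.corrupted is not None else self.clean


def kappa_for_straightness(st: float) -> float | None:
    """Von Mises concentration whose mean resultant length equals ``st``.

    Solves I1(kappa)/I0(kappa) = st. Returns None for st >= 0.999
    (effectively noise-free heading).
    """
    if not (0.0 < st < 1.0):
        raise ValueError("st must be in (0,1)")
    if st >= 0.999:
        return None

    def f(kappa: float) -> float:
        return special.i1e(kappa) / special.i0e(kappa) - st

    return float(optimize.brentq(f, 1e-8, 1e6))


def _walk_ant(
    rng: np.random.Generator,
    p: SimParams,
    arrival_frame: int,
    entry_side: str,
    speed_cm_s: float,
    kappa: float | None,
    uturn: bool,
    turn_frac: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Step one ant through the view; returns (frames, x_px, y_px)."""
    w = float(p.view_width_px)
    h = float(p.view_height_px)
    step = speed_cm_s * p.px_per_cm / p.fps
    x = 0.0 if entry_side == "low" else w
    y = float(rng.uniform(0.15 * h, 0.85 * h))
    goal_high = entry_side == "low"  # initially heading to the far end
    turn_x = turn_frac * w
    turned = False
    max_frames = int(20 * w / step) + 1000  # hard stop for very curvy walks

    frames = [arrival_frame]
    xs = [min(max(x, 0.0), w)]
    ys = [y]
    for k in range(1, max_frames):
        base = 0.0 if goal_high else math.pi
        noise = float(rng.vonmises(0.0, kappa)) if kappa is not None else 0.0
        theta = base + noise
        x += step * math.cos(theta)
        y += step * math.sin(theta)
        # reflect at trail edges
        if y < 0.0:
            y = -y
        elif y > h:
            y = 2.0 * h - y
        y = min(max(y, 0.0), h)
        if uturn and not turned:
            passed = x >= turn_x if entry_side == "low" else x <= turn_x
            if passed:
                goal_high = not goal_high
                turned = True
        if x < 0.0 or x > w:
            frames.append(arrival_frame + k)
            xs.append(min(max(x, 0.0), w))
            ys.append(y)
            break
        frames.append(arrival_frame + k)
        xs.append(x)
        ys.append(y)
    return np.asarray(frames, dtype=np.int64), np.asarray(xs), np.asarray(ys)


def simulate_scene(p: SimParams) -> SimulationScene:
    """Generate a ground-truth scene with clean detections (no corruption)."""
    rng = np.random.default_rng(p.seed)
    kappas = [kappa_for_straightness(st) for st in p.group_st_targets]

    # Poisson arrivals, optionally spaced by a minimum gap
    gaps = rng.exponential(1.0 / p.arrival_rate, size=p.n_ants)
    if p.min_arrival_gap_s > 0:
        gaps = np.maximum(gaps, p.min_arrival_gap_s)
    arrival_s = np.cumsum(gaps)
    arrival_frames = np.round(arrival_s * p.fps).astype(np.int64)

    a_trunc = (p.speed_min - p.speed_mean) / p.speed_sd
    if p.stratified_speeds:
        # one draw per equal-probability stratum: same marginal distribution,
        # near-zero variance of the sample mean
        u = (np.arange(p.n_ants) + rng.uniform(size=p.n_ants)) / p.n_ants
        speeds = rng.permutation(
            stats.truncnorm.ppf(u, a_trunc, np.inf, loc=p.speed_mean, scale=p.speed_sd)
        )
    else:
        speeds = stats.truncnorm.rvs(
            a_trunc, np.inf, loc=p.speed_mean, scale=p.speed_sd,
            size=p.n_ants, random_state=rng,
        )
    groups = rng.choice(len(p.group_weights), size=p.n_ants, p=np.asarray(p.group_weights))
    sides = np.where(rng.random(p.n_ants) < 0.5, "low", "high")
    uturns = rng.random(p.n_ants) < p.uturn_prob
    turn_fracs = rng.uniform(0.3, 0.7, size=p.n_ants)

    truth: list[GroundTruthAnt] = []
    frames_map: dict[int, list[Detection]] = {}
    for i in range(p.n_ants):
        f, xs, ys = _walk_ant(
            rng, p, int(arrival_frames[i]), str(sides[i]), float(speeds[i]),
            kappas[groups[i]], bool(uturns[i]), float(turn_fracs[i]),
        )
        if len(f) < 2:
            continue
        ant = GroundTruthAnt(
            ant_id=i, frames=f, x_px=xs, y_px=ys, group=int(groups[i]),
            speed_cm_s=float(speeds[i]), uturn=bool(uturns[i]), entry_side=str(sides[i]),
        )
        truth.append(ant)
        for frame, x, y in zip(f, xs, ys):
            frames_map.setdefault(int(frame), []).append(
                Detection(frame=int(frame), x_px=float(x), y_px=float(y))
            )
    clean = FrameSet(
        frames=frames_map,
        view_width_px=p.view_width_px,
        view_height_px=p.view_height_px,
        fps=p.fps,
    )
    return SimulationScene(truth=truth, clean=clean, params=p, seed=p.seed)


def corrupt_detections(
    scene: SimulationScene, n: NoiseParams, seed: int | None = None
) -> FrameSet:
    """Apply jitter, misses, false positives, and close-pair merging."""
    rng = np.random.default_rng(scene.seed + 1 if seed is None else seed)
    p = scene.params
    w, h = float(p.view_width_px), float(p.view_height_px)
    out: dict[int, list[Detection]] = {}
    first, last = scene.clean.span()
    for frame in range(first, last + 1):
        dets = []
        for d in scene.clean.get(frame):
            if n.miss_rate > 0 and rng.random() < n.miss_rate:
                continue
            x, y = d.x_px, d.y_px
            if n.jitter_px > 0:
                x += rng.normal(0.0, n.jitter_px)
                y += rng.normal(0.0, n.jitter_px)
            dets.append((min(max(x, 0.0), w), min(max(y, 0.0), h)))
        if n.fp_rate > 0:
            for _ in range(rng.poisson(n.fp_rate)):
                dets.append((float(rng.uniform(0, w)), float(rng.uniform(0, h))))
        if n.merge_dist_px > 0 and len(dets) > 1:
            dets = _merge_close(dets, n.merge_dist_px)
        if dets:
            out[frame] = [
                Detection(frame=frame, x_px=float(x), y_px=float(y)) for x, y in dets
            ]
    fs = FrameSet(
        frames=out,
        view_width_px=p.view_width_px,
        view_height_px=p.view_height_px,
        fps=p.fps,
    )
    scene.corrupted = fs
    return fs


def _merge_close(dets: list[tuple[float, float]], dist: float) -> list[tuple[float, float]]:
    """Greedily merge detection pairs closer than ``dist`` into midpoints."""
    pts = list(dets)
    merged = True
    while merged and len(pts) > 1:
        merged = False
        best = None
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                d = math.hypot(pts[i][0] - pts[j][0], pts[i][1] - pts[j][1])
                if d < dist and (best is None or d < best[0]):
                    best = (d, i, j)
        if best is not None:
            _, i, j = best
            mid = ((pts[i][0] + pts[j][0]) / 2.0, (pts[i][1] + pts[j][1]) / 2.0)
            pts = [q for k, q in enumerate(pts) if k not in (i, j)] + [mid]
            merged = True
    return pts


@dataclass
class TrackEvalReport:
    """Tracking quality against ground truth.

    ``frac_error_free`` counts trajectories whose every sample (including
    gap-bridged ones) stays on a single true ant; ``frac_no_wrong_ant``
    relaxes this by ignoring interpolated samples, matching an error
    taxonomy where only a label on a wrong ant (or on no ant) counts.
    """

    n_truth: int
    n_recovered: int
    frac_error_free: float
    frac_no_wrong_ant: float
    n_id_switches: int
    frac_wrong_samples: float
    per_ant_recall: dict[int, float]
    error_free_ids: list[int] = field(default_factory=list)

    @property
    def mean_recall(self) -> float:
        if not self.per_ant_recall:
            return 0.0
        return float(np.mean(list(self.per_ant_recall.values())))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mean_recall"] = self.mean_recall
        return d


def evaluate_tracking(
    truth: list[GroundTruthAnt],
    recovered: list[Trajectory],
    match_dist_px: float = 20.0,
) -> TrackEvalReport:
    """Score recovered trajectories against ground truth.

    Each recovered sample is matched to the set of true ants within
    ``match_dist_px`` at that frame. A trajectory's owner is the truth ant
    consistent with the most samples; a sample is correct when the owner is
    among its candidates (so two correctly-tracked ants crossing paths do
    not count as errors). ID switches count transitions where the owner
    leaves the candidate set and a different ant takes over.
    """
    if not truth or not recovered:
        raise ValueError("both truth and recovered must be nonempty")
    by_frame: dict[int, list[tuple[int, float, float]]] = {}
    for ant in truth:
        for f, x, y in zip(ant.frames, ant.x_px, ant.y_px):
            by_frame.setdefault(int(f), []).append((ant.ant_id, float(x), float(y)))

    n_error_free = 0
    n_no_wrong_ant = 0
    n_switches = 0
    n_samples = 0
    n_wrong_samples = 0
    error_free_ids: list[int] = []
    covered: dict[int, set[int]] = {ant.ant_id: set() for ant in truth}

    for traj in recovered:
        cands_per_sample: list[dict[int, float]] = []
        for f, x, y in zip(traj.frames, traj.x_px, traj.y_px):
            cands = {
                ant_id: d
                for ant_id, tx, ty in by_frame.get(int(f), [])
                if (d := math.hypot(tx - x, ty - y)) <= match_dist_px
            }
            cands_per_sample.append(cands)
        votes: dict[int, int] = {}
        for cands in cands_per_sample:
            for ant_id in cands:
                votes[ant_id] = votes.get(ant_id, 0) + 1
        majority = max(votes, key=lambda a: (votes[a],)) if votes else None

        ok = [majority is not None and majority in c for c in cands_per_sample]
        interp = traj.interpolated
        all_ok = all(ok)
        obs_ok = all(o for o, i in zip(ok, interp) if not i)
        n_error_free += all_ok
        if all_ok:
            error_free_ids.append(traj.ant_id)
        n_no_wrong_ant += obs_ok and majority is not None
        n_samples += len(ok)
        n_wrong_samples += sum(1 for o in ok if not o)

        # attribution sequence: owner while consistent, else nearest candidate
        seq = []
        for o, cands in zip(ok, cands_per_sample):
            if o:
                seq.append(majority)
            elif cands:
                seq.append(min(cands, key=cands.get))
        n_switches += sum(1 for a, b in zip(seq, seq[1:]) if a != b)
        if majority is not None:
            for o, f in zip(ok, traj.frames):
                if o:
                    covered[majority].add(int(f))

    recall = {
        ant.ant_id: len(covered[ant.ant_id]) / ant.n_samples for ant in truth
    }
    n_rec = len(recovered)
    return TrackEvalReport(
        n_truth=len(truth),
        n_recovered=n_rec,
        frac_error_free=n_error_free / n_rec,
        frac_no_wrong_ant=n_no_wrong_ant / n_rec,
        n_id_switches=n_switches,
        frac_wrong_samples=n_wrong_samples / max(n_samples, 1),
        per_ant_recall=recall,
        error_free_ids=error_free_ids,
    )


def truth_to_trajectories(truth: list[GroundTruthAnt]) -> list[Trajectory]:
    """View ground-truth ants as (uncalibrated) trajectories."""
    return [
        Trajectory(ant_id=a.ant_id, frames=a.frames, x_px=a.x_px, y_px=a.y_px)
        for a in truth
        if a.n_samples >= 2
    ]


NIGHT_START_S = 70200.0  # 19:30
NIGHT_SPAN_S = 4.5 * 3600.0  # 19:30 -> 00:00


def synthetic_speed_table(
    n: int = 5000,
    slope_per_night: float = -0.45,
    mean_speed: float = 5.15,
    n_colonies: int = 4,
    n_dates: int = 4,
    re_sd: float = 0.3,
    resid_sd: float = 1.5,
    seed: int = 0,
):
    """Per-trajectory speeds with a linear nightly decline and crossed
    colony/date random intercepts, for mixed-model recovery tests.

    ``night_frac`` runs 0 -> 1 over 19:30-00:00, so a model coefficient on it
    is the change per night span.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    colony_re = rng.normal(0.0, re_sd, n_colonies)
    date_re = rng.normal(0.0, re_sd, n_dates)
    colony = rng.integers(0, n_colonies, n)
    date = rng.integers(0, n_dates, n)
    night_frac = rng.uniform(0.0, 1.0, n)
    speed = (
        mean_speed
        + slope_per_night * night_frac
        + colony_re[colony]
        + date_re[date]
        + rng.normal(0.0, resid_sd, n)
    )
    return pd.DataFrame(
        {
            "speed": speed,
            "night_frac": night_frac,
            "time_h": night_frac * NIGHT_SPAN_S / 3600.0,
            "start_clock": NIGHT_START_S + night_frac * NIGHT_SPAN_S,
            "colony": colony,
            "date": date,
        }
    )


def synthetic_aei_table(
    n: int = 2000,
    st_slope: float = -0.11,
    interval_effects: dict[str, float] | None = None,
    base: float = 0.3,
    re_sd: float = 0.05,
    resid_sd: float = 0.08,
    n_colonies: int = 4,
    n_dates: int = 4,
    seed: int = 0,
):
    """Synthetic AEI records with an optional ST dependence and per-interval
    shifts, spanning 19:30-00:00 with colony/date random intercepts."""
    import pandas as pd

    from .stats.lmm import bin_half_hour

    rng = np.random.default_rng(seed)
    colony_re = rng.normal(0.0, re_sd, n_colonies)
    date_re = rng.normal(0.0, re_sd, n_dates)
    colony = rng.integers(0, n_colonies, n)
    date = rng.integers(0, n_dates, n)
    clock = NIGHT_START_S + rng.uniform(0.0, NIGHT_SPAN_S, n)
    st = rng.beta(8, 2, n)
    aei = base + st_slope * st + colony_re[colony] + date_re[date] + rng.normal(0, resid_sd, n)
    if interval_effects:
        labels = bin_half_hour(clock)
        aei = aei + np.array([interval_effects.get(lab, 0.0) for lab in labels])
    return pd.DataFrame(
        {
            "AEI": np.clip(aei, 0.0, 1.0),
            "ST": st,
            "start_clock": clock,
            "colony": colony,
            "date": date,
        }
    )


def write_scene(scene: SimulationScene, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write a scene bundle: ground-truth CSV, detections CSV, params JSON."""
    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    truth_rows = []
    for a in scene.truth:
        for f, x, y in zip(a.frames, a.x_px, a.y_px):
            truth_rows.append(
                {
                    "ant_id": a.ant_id, "frame": int(f), "x": float(x), "y": float(y),
                    "group": a.group, "uturn": int(a.uturn),
                    "speed_cm_s": a.speed_cm_s, "entry_side": a.entry_side,
                }
            )
    truth_path = os.path.join(out_dir, "ground_truth.csv")
    pd.DataFrame(truth_rows).to_csv(truth_path, index=False, float_format="%.6f")

    det_rows = []
    fs = scene.detections
    for frame in fs.frame_indices:
        for d in fs.get(frame):
            det_rows.append({"frame": frame, "x": d.x_px, "y": d.y_px})
    det_path = os.path.join(out_dir, "detections.csv")
    pd.DataFrame(det_rows, columns=["frame", "x", "y"]).to_csv(
        det_path, index=False, float_format="%.6f"
    )

    params_path = os.path.join(out_dir, "params.json")
    with open(params_path, "w") as fh:
        json.dump({"sim_params": asdict(scene.params), "seed": scene.seed}, fh, indent=2)
    return {"truth": truth_path, "detections": det_path, "params": params_path}
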