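"""End-to-end pipeline: read detections -> track -> calibrate -> filter ->
split U-turns -> metrics -> statistics, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import __version__
from .core_io import TrailConfig, Trajectory, load_config, read_detections, write_trajectories
from .metrics import compute_metrics, export_heatmap, visiting_map
from .preprocess import assign_direction, calibrate_trajectory, filter_edge_starts, split_uturns
from .stats import classify_groups, fit_lmm, group_value_summary, interval_comparison, select_k_bic
from .tracker import TrackParams, build_trajectories, extract_cues

__all__ = ["PipelineError", "run_pipeline"]

log = logging.getLogger("trailtrack")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(
    detections_path: str,
    config_path: str,
    out_dir: str,
    seed: int = 0,
    track_params: TrackParams | None = None,
    k_max: int = 4,
    with_stats: bool = True,
) -> dict:
    """Run the full analysis and write all artifacts under ``out_dir``.

    Returns a summary dict (also written as ``manifest.json``) with stage
    counts and artifact paths. Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    p = track_params or TrackParams()
    os.makedirs(out_dir, exist_ok=True)

    cfg = _stage("load_config")(load_config)(config_path)
    if cfg.view_width_px is None or cfg.view_height_px is None:
        raise PipelineError("stage 'load_config' failed: config must set view_width_px/view_height_px")
    fs = _stage("read_detections")(read_detections)(
        detections_path, (cfg.view_width_px, cfg.view_height_px), cfg.fps
    )
    log.info("read %d detections over %d frames", fs.n_detections, len(fs.frames))

    trajs = _stage("track")(build_trajectories)(fs, p)
    log.info("built %d trajectories", len(trajs))

    trajs = [_stage("calibrate")(calibrate_trajectory)(t, cfg) for t in trajs]

    kept, removed = _stage("filter_edges")(filter_edge_starts)(trajs, cfg)
    log.info("kept %d complete trajectories, removed %d", len(kept), len(removed))
    removed_df = pd.DataFrame(
        [{"ant_id": t.ant_id, "reason": reason} for t, reason in removed],
        columns=["ant_id", "reason"],
    )
    removed_path = os.path.join(out_dir, "removed.csv")
    removed_df.to_csv(removed_path, index=False)

    analysis: list[Trajectory] = []
    n_uturns = 0
    for t in kept:
        parts = _stage("split_uturns")(split_uturns)(t, cfg)
        n_uturns += len(parts) == 2
        analysis.extend(parts)
    analysis = [
        _stage("assign_direction")(assign_direction)(t, cfg).copy_with(ant_id=i)
        for i, t in enumerate(analysis)
    ]
    log.info("split %d U-turns; %d analysis trajectories", n_uturns, len(analysis))

    vm = _stage("visiting_map")(visiting_map)(analysis, cfg, "trajectories") if analysis else None
    records = [_stage("metrics")(compute_metrics)(t, vm) for t in analysis]
    samples_path, metrics_path = _stage("write")(write_trajectories)(
        analysis, records, out_dir
    )
    artifacts = {"samples": samples_path, "metrics": metrics_path, "removed": removed_path}
    if vm is not None:
        csv_p, png_p = _stage("heatmap")(export_heatmap)(vm, os.path.join(out_dir, "visiting_map"))
        artifacts["heatmap_csv"], artifacts["heatmap_png"] = csv_p, png_p
        vm_entries = visiting_map(analysis, cfg, "entries")
        csv_e, png_e = export_heatmap(vm_entries, os.path.join(out_dir, "visiting_map_entries"))
        artifacts["heatmap_entries_csv"], artifacts["heatmap_entries_png"] = csv_e, png_e

    cues = _stage("cues")(extract_cues)(fs, trajs, cfg, p)
    cues_path = os.path.join(out_dir, "cues.csv")
    pd.DataFrame(
        [
            {"cue_type": c.cue_type, "frame": c.frame, "x_px": c.x_px,
             "y_px": c.y_px, "magnitude": c.magnitude}
            for c in cues
        ],
        columns=["cue_type", "frame", "x_px", "y_px", "magnitude"],
    ).to_csv(cues_path, index=False)
    artifacts["cues"] = cues_path

    stats_report: dict = {}
    if with_stats and records:
        stats_report = _stage("stats")(_run_stats)(records, seed, k_max)
        stats_path = os.path.join(out_dir, "stats.json")
        with open(stats_path, "w") as fh:
            json.dump(stats_report, fh, indent=2, default=_jsonify)
        artifacts["stats"] = stats_path

    manifest = {
        "trailtrack_version": __version__,
        "seed": seed,
        "config_path": os.path.abspath(config_path),
        "config_sha256": _sha256(config_path),
        "detections_path": os.path.abspath(detections_path),
        "detections_sha256": _sha256(detections_path),
        "track_params": asdict(p),
        "counts": {
            "detections": fs.n_detections,
            "frames": len(fs.frames),
            "trajectories_built": len(trajs),
            "trajectories_kept": len(kept),
            "trajectories_removed": len(removed),
            "uturns_split": n_uturns,
            "analysis_trajectories": len(analysis),
            "cues": len(cues),
        },
        "artifacts": artifacts,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _run_stats(records, seed: int, k_max: int) -> dict:
    """Mixture + LMM stages on the per-trajectory metric records."""
    df = pd.DataFrame(
        [
            {
                "ant_id": r.ant_id, "ST": r.ST, "AEI": r.AEI,
                "speed": r.mean_speed_cm_s, "start_clock": r.start_clock,
            }
            for r in records
        ]
    )
    out: dict = {"n_trajectories": len(df)}
    st = df["ST"].to_numpy()
    if len(st) >= 10 * k_max:
        k_best, fits = select_k_bic(st, k_max=k_max, seed=seed, n_restarts=3, tol=1e-7)
        fit = fits[k_best]
        labels, summary = classify_groups(fit)
        out["mixture"] = {
            "k_best": k_best,
            "bic": {k: f.bic for k, f in fits.items()},
            "groups": group_value_summary(st, labels, summary),
        }
    else:
        out["mixture"] = None

    # hours since the start of the night as the time covariate
    df = df.dropna(subset=["start_clock"])
    if len(df) >= 10:
        df = df.assign(time_h=(df["start_clock"] - df["start_clock"].min()) / 3600.0)
        speed_fit = fit_lmm(df, "speed", "time_h", random_groups=[])
        out["speed_vs_time"] = {
            "slope": speed_fit.coef("time_h"),
            "se": speed_fit.se("time_h"),
            "p": float(speed_fit.fixed_effects.loc["time_h", "p"]),
        }
        aei_df = df.dropna(subset=["AEI"])
        if len(aei_df) >= 10 and aei_df["AEI"].nunique() > 1:
            aei_fit = fit_lmm(aei_df, "AEI", "ST", random_groups=[])
            out["aei_vs_st"] = {
                "slope": aei_fit.coef("ST"),
                "se": aei_fit.se("ST"),
                "p": float(aei_fit.fixed_effects.loc["ST", "p"]),
            }
            try:
                ic = interval_comparison(aei_df, response="AEI", clock_col="start_clock",
                                         random_groups=[])
                out["interval_comparison"] = {
                    "means": ic.group_means,
                    "pairwise": ic.pairwise,
                }
            except ValueError:
                out["interval_comparison"] = None
    return out
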