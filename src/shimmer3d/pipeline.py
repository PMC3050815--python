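"""End-to-end pipeline driver: segment -> match -> track/triangulate ->
wave detection -> episodes -> pooled time courses."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import StereoRig, load_calibration
from .config import PipelineConfig
from .episodes import (
    EpisodeRecord,
    classify_rs,
    episodes_to_frame,
    extract_episode,
    offset_correct,
    pool_courses,
    pooled_to_frame,
)
from .io import read_pair
from .matching import solve_matching
from .segmentation import build_template_bank, detections_to_frame, make_bee_template, segment_agents
from .tracking import Track, _make_problem, track_sequence
from .waves import LuminanceSeries, WaveEvent, detect_events, normalize_rrs

log = logging.getLogger("shimmer3d")

STAGES = ("segment", "match", "track", "detect", "episodes")


@dataclass
class PipelineResult:
    config: PipelineConfig
    detections_left: list = field(default_factory=list)
    detections_right: list = field(default_factory=list)
    correspondences: object = None
    tracks: list = field(default_factory=list)
    series: dict = field(default_factory=dict)  # agent_id -> LuminanceSeries
    events: list = field(default_factory=list)
    activity: np.ndarray | None = None
    episodes: list = field(default_factory=list)
    pooled: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def luminance_series(frames_l, tracks, cfg: PipelineConfig):
    """Per-agent sROI frame-difference series plus global activity.

    Series index j holds the mean absolute sROI difference between frames j
    and j+1, evaluated at the agent's fused left-view position in frame j+1
    (the sensor follows the track).
    """
    F = len(frames_l)
    n = len(tracks)
    mat = np.zeros((n, max(F - 1, 0)))
    valid = np.zeros((n, max(F - 1, 0)), dtype=bool)
    half = cfg.sroi_px // 2
    for j in range(F - 1):
        diff = np.abs(
            np.asarray(frames_l[j + 1], dtype=np.float32)
            - np.asarray(frames_l[j], dtype=np.float32)
        )
        h, w = diff.shape
        for t_idx, tr in enumerate(tracks):
            uv = tr.position(j + 1, "left")
            if uv is None:
                continue
            u, v = int(round(uv[0])), int(round(uv[1]))
            v0, v1 = max(v - half, 0), min(v + half, h)
            u0, u1 = max(u - half, 0), min(u + half, w)
            if v0 >= v1 or u0 >= u1:
                continue
            mat[t_idx, j] = float(diff[v0:v1, u0:u1].mean())
            valid[t_idx, j] = True
    series = {
        tr.agent_id: LuminanceSeries(tr.agent_id, mat[i], cfg.sroi_px)
        for i, tr in enumerate(tracks)
    }
    with np.errstate(invalid="ignore"):
        frac = (mat > cfg.delta_l_th).sum(axis=0) / np.maximum(valid.sum(axis=0), 1)
    return series, frac


def run_pipeline_arrays(
    frames_l,
    frames_r,
    rig: StereoRig,
    cfg: PipelineConfig | None = None,
    until: str = "episodes",
) -> PipelineResult:
    """Run the pipeline on in-memory rectified frame sequences."""
    if cfg is None:
        cfg = PipelineConfig()
    cfg.validate()
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; expected one of {STAGES}")
    res = PipelineResult(config=cfg)
    frames_l = list(frames_l)
    frames_r = list(frames_r)
    if len(frames_l) != len(frames_r):
        raise ValueError("left and right sequences differ in length")
    if not frames_l:
        res.summary = {"n_frames": 0}
        return res
    stage_idx = STAGES.index(until)

    bank = build_template_bank(
        make_bee_template(cfg.body_length_px),
        cfg.angle_range,
        cfg.angle_step,
        cfg.scale_px,
        cfg.body_length_px,
    )
    log.info("segmenting frame 0 (%d templates)", len(bank))
    res.detections_left = segment_agents(frames_l[0], bank, cfg.min_score, cfg.suppress_radius)
    res.detections_right = segment_agents(frames_r[0], bank, cfg.min_score, cfg.suppress_radius)
    res.summary["n_detections_left"] = len(res.detections_left)
    res.summary["n_detections_right"] = len(res.detections_right)
    if stage_idx < 1:
        return res

    problem = _make_problem(res.detections_left, res.detections_right, rig, cfg)
    res.correspondences = solve_matching(problem, frames_l[0], frames_r[0])
    res.summary["n_correspondences"] = len(res.correspondences.pairs)
    if stage_idx < 2:
        return res

    log.info("tracking %d frame pairs", len(frames_l))
    res.tracks = track_sequence(frames_l, frames_r, rig, cfg, bank=bank)
    res.summary["n_tracks"] = len(res.tracks)
    if stage_idx < 3:
        return res

    res.series, res.activity = luminance_series(frames_l, res.tracks, cfg)
    events: list[WaveEvent] = []
    for tr in res.tracks:
        events.extend(
            detect_events(
                res.series[tr.agent_id],
                cfg.delta_l_th,
                cfg.n_consecutive,
                cfg.lead,
                cfg.rs_window,
                cfg.rearm_frames,
            )
        )
    if events:
        normalize_rrs(events)
    res.events = events
    res.summary["n_events"] = len(events)
    if stage_idx < 4:
        return res

    by_id = {tr.agent_id: tr for tr in res.tracks}
    eps: list[EpisodeRecord] = []
    for ev in events:
        tr = by_id[ev.agent_id]
        arrival_frame = ev.arrival + 1  # series index -> absolute frame
        try:
            ep = extract_episode(tr, ev, arrival_frame, cfg.pre_frames, cfg.post_frames)
            offset_correct(ep, cfg.offset_frames)
        except ValueError:
            continue
        eps.append(ep)
    if eps:
        classify_rs(eps, cfg.n_levels, cfg.group_split, cfg.rs_range)
        res.pooled = pool_courses(eps)
    res.episodes = eps
    res.summary["n_episodes"] = len(eps)
    res.summary["n_full_episodes"] = sum(not e.partial for e in eps)
    return res


def _tracks_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for i, status in enumerate(tr.status):
            f = tr.start_frame + i
            pl = tr.pos_l[i] or (np.nan, np.nan)
            pr = tr.pos_r[i] or (np.nan, np.nan)
            xyz = tr.xyz[i] or (np.nan, np.nan, np.nan)
            rows.append(
                (f, tr.agent_id, pl[0], pl[1], pr[0], pr[1], *xyz, status, tr.score[i])
            )
    return pd.DataFrame(
        rows,
        columns=[
            "frame", "agent_id", "u_l", "v_l", "u_r", "v_r",
            "x_mm", "y_mm", "z_mm", "status", "score",
        ],
    ).sort_values(["frame", "agent_id"], kind="stable", ignore_index=True)


def _correspondences_frame(corr, frame: int = 0) -> pd.DataFrame:
    rows = [
        (frame, p, i, corr.disparities[(p, i)], corr.costs[(p, i)])
        for p, i in corr.pairs
    ]
    rows += [(frame, p, -1, np.nan, np.nan) for p in corr.unmatched_left]
    return pd.DataFrame(
        rows, columns=["frame", "left_id", "right_id", "disparity_px", "cost"]
    )


def _events_frame(events: list[WaveEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "agent_id": [e.agent_id for e in events],
            "wave_index": [e.wave_index for e in events],
            "arrival_frame": [e.arrival + 1 for e in events],
            "RS": [e.rs for e in events],
            "rRS": [e.rrs for e in events],
        }
    )


def write_outputs(res: PipelineResult, out_dir) -> Path:
    """Write every stage's table plus a summary log to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    det = pd.concat(
        [
            detections_to_frame(res.detections_left, 0, "left"),
            detections_to_frame(res.detections_right, 0, "right"),
        ],
        ignore_index=True,
    )
    det.to_csv(out / "detections.csv", index=False)
    if res.correspondences is not None:
        _correspondences_frame(res.correspondences).to_csv(
            out / "correspondences.csv", index=False
        )
    if res.tracks:
        _tracks_frame(res.tracks).to_csv(out / "tracks.csv", index=False)
    if res.events:
        _events_frame(res.events).to_csv(out / "events.csv", index=False)
    if res.activity is not None:
        pd.DataFrame(
            {"frame": np.arange(1, len(res.activity) + 1), "fraction_active": res.activity}
        ).to_csv(out / "activity.csv", index=False)
    if res.episodes:
        episodes_to_frame(res.episodes).to_csv(out / "episodes.csv", index=False)
    for name, course in res.pooled.items():
        pooled_to_frame(course).to_csv(out / f"pooled_{name}.csv", index=False)
    summary = dict(res.summary)
    summary["config"] = res.config.to_dict()
    summary["config_hash"] = res.config.config_hash()
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    # persist the effective configuration verbatim alongside the outputs
    (out / "config.json").write_text(json.dumps(res.config.to_dict(), indent=1))
    return out


def run_pipeline(
    left_dir,
    right_dir,
    calib_path,
    out_dir,
    cfg: PipelineConfig | None = None,
    until: str = "episodes",
) -> PipelineResult:
    """Run the full pipeline from directories of numbered frames."""
    frames_l, frames_r = read_pair(left_dir, right_dir)
    rig = load_calibration(calib_path)
    res = run_pipeline_arrays(frames_l, frames_r, rig, cfg, until=until)
    write_outputs(res, out_dir)
    return res
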