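"""Frame-to-frame stereo tracking of matched agents.

Each agent carries a 20x20 px template around its thorax in each view.  In
the next frame the template is correlated over a 40x40 px search region
centred on the previous position and the global NCC maximum becomes the new
position.  Abdominal flipping deforms the appearance fast enough that a
single rolling template drifts, so the tracker keeps the templates of the
preceding 15 frames and scores the search region against all of them: the
appearance produced on the way up through a flip recurs on the way down
(time symmetry), and matching against the stored set anchors the track to
the pre-flip appearance.  Left and right tracks are then fused onto their
mean image row, which restores exact row consistency for triangulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .calibration import StereoRig, triangulate
from .config import PipelineConfig, disparity_range_from_rig
from .matching import CorrespondenceProblem, solve_matching
from .segmentation import build_template_bank, make_bee_template, segment_agents


class LostTrackError(RuntimeError):
    """Signals that no placement reached the minimum tracking score."""


@dataclass
class Track:
    """One agent's time series of image and world positions.

    Per-frame lists are indexed by absolute frame number minus
    ``start_frame``; entries are None once the track is lost.
    """

    agent_id: int
    start_frame: int
    pos_l: list = field(default_factory=list)  # (u, v) float px or None
    pos_r: list = field(default_factory=list)
    fused_row: list = field(default_factory=list)
    xyz: list = field(default_factory=list)  # (x, y, z) mm or None
    status: list = field(default_factory=list)  # tracked | lost | reseeded
    score: list = field(default_factory=list)
    mem_l: list = field(default_factory=list)  # (frame, 20x20 patch)
    mem_r: list = field(default_factory=list)

    @property
    def alive(self) -> bool:
        return bool(self.status) and self.status[-1] == "tracked"

    @property
    def last_frame(self) -> int:
        return self.start_frame + len(self.pos_l) - 1

    def position(self, frame: int, view: str):
        i = frame - self.start_frame
        if i < 0 or i >= len(self.pos_l):
            return None
        return (self.pos_l if view == "left" else self.pos_r)[i]

    def memory(self, view: str) -> list:
        return self.mem_l if view == "left" else self.mem_r

    def push_memory(self, view: str, frame: int, patch: np.ndarray, capacity: int) -> None:
        mem = self.memory(view)
        mem.append((frame, patch))
        while len(mem) > capacity:
            mem.pop(0)


def extract_patch(img: np.ndarray, uv, size: int):
    """Integer-aligned square patch centred on uv, or None at the border."""
    u, v = int(round(uv[0])), int(round(uv[1]))
    half = size // 2
    v0, u0 = v - half, u - half
    if v0 < 0 or u0 < 0 or v0 + size > img.shape[0] or u0 + size > img.shape[1]:
        return None
    return np.array(img[v0 : v0 + size, u0 : u0 + size], dtype=np.float32)


def ncc_scan(region: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """NCC of each template at every placement inside a search region.

    region: (S, S); templates: (k, t, t).  Returns (S-t+1, S-t+1, k).
    Zero-variance windows or templates score 0.
    """
    region = np.ascontiguousarray(region, dtype=np.float32)
    templates = np.asarray(templates, dtype=np.float32)
    k, t, _ = templates.shape
    win = sliding_window_view(region, (t, t))
    side0, side1 = win.shape[:2]
    W = win.reshape(side0 * side1, t * t).astype(np.float32)
    W = W - W.mean(axis=1, keepdims=True)
    wn = np.linalg.norm(W, axis=1)
    T = templates.reshape(k, t * t).astype(np.float32)
    T = T - T.mean(axis=1, keepdims=True)
    tn = np.linalg.norm(T, axis=1)
    denom = wn[:, None] * tn[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (W @ T.T) / np.where(denom > 1e-6, denom, np.inf)
    return np.clip(corr.reshape(side0, side1, k), -1.0, 1.0)


def _best_placement(
    img: np.ndarray,
    prev_uv,
    templates: list[np.ndarray],
    cfg: PipelineConfig,
):
    """Global NCC maximum over templates within the search region.

    Ties are broken by smaller displacement from the previous position, then
    by row, column and most recent template.  Returns (uv, score, tpl_index)
    or raises LostTrackError.
    """
    t = cfg.template_px
    s = cfg.search_px
    half_s = s // 2
    half_t = t // 2
    u0 = int(round(prev_uv[0])) - half_s
    v0 = int(round(prev_uv[1])) - half_s
    u0 = max(0, min(u0, img.shape[1] - s))
    v0 = max(0, min(v0, img.shape[0] - s))
    if img.shape[0] < s or img.shape[1] < s:
        raise LostTrackError("image smaller than search region")
    region = img[v0 : v0 + s, u0 : u0 + s]
    corr = ncc_scan(region, np.stack(templates))
    best = float(corr.max())
    if best < cfg.track_min_score:
        raise LostTrackError(f"max NCC {best:.3f} below {cfg.track_min_score}")
    cand = np.argwhere(corr >= best - 1e-7)
    # candidate centre positions in image coordinates
    uu = cand[:, 1] + u0 + half_t
    vv = cand[:, 0] + v0 + half_t
    disp2 = (uu - prev_uv[0]) ** 2 + (vv - prev_uv[1]) ** 2
    age = len(templates) - 1 - cand[:, 2]  # 0 = most recent
    order = np.lexsort((age, uu, vv, disp2))
    pick = order[0]
    return (float(uu[pick]), float(vv[pick])), best, int(cand[pick, 2])


def track_step(track: Track, frame_next: np.ndarray, view: str, cfg: PipelineConfig):
    """One tracking step using only the current (most recent) template."""
    mem = track.memory(view)
    if not mem:
        raise LostTrackError("no template memory")
    prev = track.position(track.last_frame, view)
    if prev is None:
        raise LostTrackError("track has no current position")
    uv, score, _ = _best_placement(frame_next, prev, [mem[-1][1]], cfg)
    return uv, score


def symmetric_track_step(track: Track, frame_next: np.ndarray, view: str, cfg: PipelineConfig):
    """One tracking step scored against all stored templates (time symmetry).

    Returns (uv, score, template_age) where age counts frames back from the
    newest stored template.
    """
    mem = track.memory(view)
    if not mem:
        raise LostTrackError("no template memory")
    prev = track.position(track.last_frame, view)
    if prev is None:
        raise LostTrackError("track has no current position")
    uv, score, idx = _best_placement(frame_next, prev, [p for _, p in mem], cfg)
    return uv, score, len(mem) - 1 - idx


def fuse_views(pos_l, pos_r):
    """Project left/right positions onto their mean image row."""
    row = 0.5 * (pos_l[1] + pos_r[1])
    return (pos_l[0], row), (pos_r[0], row)


def _triangulate_mm(rig: StereoRig, pos_l, pos_r):
    p, _ = triangulate(pos_l, pos_r, rig)
    return (p.x, p.y, p.z)


def _make_problem(left, right, rig, cfg: PipelineConfig) -> CorrespondenceProblem:
    disp = cfg.disparity_range
    if disp is None:
        disp = disparity_range_from_rig(rig, cfg.z_half_extent_mm)
    return CorrespondenceProblem(
        left=left,
        right=right,
        row_tol=cfg.row_tol,
        disparity_range=disp,
        n_slots=cfg.n_slots,
        lam=cfg.lam,
        occlusion_cost=cfg.occlusion_cost,
        patch_px=cfg.template_px,
    )


def _spawn_tracks(
    corr,
    left,
    right,
    img_l,
    img_r,
    frame: int,
    rig: StereoRig,
    cfg: PipelineConfig,
    next_id: int,
    existing: list[Track] | None = None,
) -> list[Track]:
    """Create tracks for matched detections, skipping live duplicates."""
    live_pts = []
    if existing:
        for tr in existing:
            if tr.alive:
                p = tr.position(tr.last_frame, "left")
                if p is not None:
                    live_pts.append(p)
    out = []
    for p_idx, i_idx in corr.pairs:
        uv_l = left[p_idx].thorax
        uv_r = right[i_idx].thorax
        if any((uv_l[0] - a) ** 2 + (uv_l[1] - b) ** 2 <= cfg.suppress_radius**2 for a, b in live_pts):
            continue
        patch_l = extract_patch(img_l, uv_l, cfg.template_px)
        patch_r = extract_patch(img_r, uv_r, cfg.template_px)
        if patch_l is None or patch_r is None:
            continue
        fl, fr = fuse_views(uv_l, uv_r)
        tr = Track(agent_id=next_id, start_frame=frame)
        next_id += 1
        tr.pos_l.append(fl)
        tr.pos_r.append(fr)
        tr.fused_row.append(fl[1])
        tr.xyz.append(_triangulate_mm(rig, fl, fr))
        tr.status.append("tracked")
        tr.score.append(1.0)
        tr.push_memory("left", frame, patch_l, cfg.memory_frames)
        tr.push_memory("right", frame, patch_r, cfg.memory_frames)
        out.append(tr)
    return out


def reseed(
    tracks: list[Track],
    img_l: np.ndarray,
    img_r: np.ndarray,
    frame: int,
    rig: StereoRig,
    cfg: PipelineConfig,
    bank=None,
) -> list[Track]:
    """Replace lost tracks by re-running segmentation + stereo matching.

    Surviving tracks keep their identities; detections at the position of a
    surviving track are skipped; fresh tracks get new, monotonically
    increasing ids (a reseeded agent at a previously tracked position makes
    no identity claim).
    """
    if bank is None:
        bank = build_template_bank(
            make_bee_template(cfg.body_length_px),
            cfg.angle_range,
            cfg.angle_step,
            cfg.scale_px,
            cfg.body_length_px,
        )
    for tr in tracks:
        if tr.status and tr.status[-1] == "lost":
            tr.status[-1] = "reseeded"  # superseded by a fresh agent
    left = segment_agents(img_l, bank, cfg.min_score, cfg.suppress_radius)
    right = segment_agents(img_r, bank, cfg.min_score, cfg.suppress_radius)
    corr = solve_matching(_make_problem(left, right, rig, cfg), img_l, img_r)
    next_id = max((t.agent_id for t in tracks), default=-1) + 1
    fresh = _spawn_tracks(
        corr, left, right, img_l, img_r, frame, rig, cfg, next_id, existing=tracks
    )
    return tracks + fresh


def _sroi_mean(diff: np.ndarray, uv, size: int) -> float:
    half = size // 2
    u, v = int(round(uv[0])), int(round(uv[1]))
    v0, v1 = max(v - half, 0), min(v + half, diff.shape[0])
    u0, u1 = max(u - half, 0), min(u + half, diff.shape[1])
    if v0 >= v1 or u0 >= u1:
        return 0.0
    return float(diff[v0:v1, u0:u1].mean())


def track_sequence(
    frames_l,
    frames_r,
    rig: StereoRig,
    cfg: PipelineConfig | None = None,
    bank=None,
) -> list[Track]:
    """Track all agents through a synchronized rectified stereo sequence.

    Segment + match the first frame pair, then per frame: symmetric tracking
    in both views, row fusion, triangulation.  After a wave has passed
    (global sROI activity below ``reseed_activity_frac`` for
    ``reseed_quiet_frames`` consecutive frames) lost agents are replaced by
    re-running segmentation and matching.
    """
    if cfg is None:
        cfg = PipelineConfig()
    cfg.validate()
    frames_l = list(frames_l)
    frames_r = list(frames_r)
    if len(frames_l) != len(frames_r):
        raise ValueError("left and right sequences differ in length")
    if not frames_l:
        return []
    if bank is None:
        bank = build_template_bank(
            make_bee_template(cfg.body_length_px),
            cfg.angle_range,
            cfg.angle_step,
            cfg.scale_px,
            cfg.body_length_px,
        )
    img_l0, img_r0 = frames_l[0], frames_r[0]
    left = segment_agents(img_l0, bank, cfg.min_score, cfg.suppress_radius)
    right = segment_agents(img_r0, bank, cfg.min_score, cfg.suppress_radius)
    corr = solve_matching(_make_problem(left, right, rig, cfg), img_l0, img_r0)
    tracks = _spawn_tracks(corr, left, right, img_l0, img_r0, 0, rig, cfg, 0)

    quiet_run = 0
    lost_since_reseed = 0
    for f in range(1, len(frames_l)):
        img_l, img_r = frames_l[f], frames_r[f]
        diff = np.abs(
            np.asarray(img_l, dtype=np.float32) - np.asarray(frames_l[f - 1], dtype=np.float32)
        )
        active = 0
        live = 0
        for tr in tracks:
            if not tr.alive:
                continue
            live += 1
            try:
                uv_l, sc_l, _ = symmetric_track_step(tr, img_l, "left", cfg)
                uv_r, sc_r, _ = symmetric_track_step(tr, img_r, "right", cfg)
            except LostTrackError:
                tr.pos_l.append(None)
                tr.pos_r.append(None)
                tr.fused_row.append(None)
                tr.xyz.append(None)
                tr.status.append("lost")
                tr.score.append(0.0)
                lost_since_reseed += 1
                continue
            fl, fr = fuse_views(uv_l, uv_r)
            tr.pos_l.append(fl)
            tr.pos_r.append(fr)
            tr.fused_row.append(fl[1])
            tr.xyz.append(_triangulate_mm(rig, fl, fr))
            tr.status.append("tracked")
            tr.score.append(min(sc_l, sc_r))
            patch_l = extract_patch(img_l, fl, cfg.template_px)
            patch_r = extract_patch(img_r, fr, cfg.template_px)
            if patch_l is not None:
                tr.push_memory("left", f, patch_l, cfg.memory_frames)
            if patch_r is not None:
                tr.push_memory("right", f, patch_r, cfg.memory_frames)
            if _sroi_mean(diff, fl, cfg.sroi_px) > cfg.delta_l_th:
                active += 1
        frac = active / live if live else 0.0
        quiet_run = quiet_run + 1 if frac < cfg.reseed_activity_frac else 0
        if quiet_run >= cfg.reseed_quiet_frames and lost_since_reseed > 0:
            tracks = reseed(tracks, img_l, img_r, f, rig, cfg, bank=bank)
            lost_since_reseed = 0
            quiet_run = 0
    return tracks
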