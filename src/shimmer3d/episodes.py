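"""Episode extraction, offset correction, RS classification and pooling.

A wave episode is the 90-frame window (30 frames = 500 ms before and 60
frames = 1000 ms after time zero at 60 Hz) of one agent's 3D trajectory
around one wave arrival.  Episodes are offset-corrected by subtracting the
arithmetic mean of the first six pre-frames from each coordinate, which
zeroes slow curtain drift without high-pass filtering the flip response.
Episodes are then sorted into 10 equal relative-response-strength levels
spanning rRS 0.3-0.8, grouped low/middle/high, and pooled per relative
frame into mean +- s.e.m. time courses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .waves import WaveEvent

GROUP_NAMES = ("low", "middle", "high")


@dataclass
class EpisodeRecord:
    """One agent's offset-corrected motion around one wave arrival."""

    agent_id: int
    wave_index: int
    arrival_frame: int
    rel_frames: np.ndarray  # -pre .. +post-1
    dx: np.ndarray  # mm
    dy: np.ndarray
    dz: np.ndarray
    rs: float = float("nan")
    rrs: float = float("nan")
    rs_level: int = 0
    rs_group: str = ""
    partial: bool = False
    offset_corrected: bool = False

    def __len__(self) -> int:
        return len(self.rel_frames)


@dataclass
class PooledCourse:
    """Per-relative-frame mean and s.e.m. of one RS group."""

    rs_group: str
    rel_frames: np.ndarray
    mean: dict  # component -> array
    sem: dict
    n: int


def extract_episode(
    track,
    event: WaveEvent,
    arrival_frame: int | None = None,
    pre_frames: int = 30,
    post_frames: int = 60,
) -> EpisodeRecord:
    """Slice a track's 3D series around one wave arrival.

    ``arrival_frame`` is the absolute frame of time zero (defaults to the
    event's arrival index interpreted as an absolute frame).  Windows that
    do not fit inside the tracked range are truncated and flagged partial.
    """
    t0 = event.arrival if arrival_frame is None else arrival_frame
    lo = t0 - pre_frames
    hi = t0 + post_frames
    frames = np.arange(lo, hi)
    xyz = []
    partial = False
    for f in frames:
        i = f - track.start_frame
        p = track.xyz[i] if 0 <= i < len(track.xyz) else None
        xyz.append(p)
    mask = np.array([p is not None for p in xyz])
    if not mask.all():
        partial = True
    if not mask.any():
        raise ValueError("episode window does not overlap the track")
    frames = frames[mask]
    arr = np.array([p for p in xyz if p is not None], dtype=float)
    return EpisodeRecord(
        agent_id=track.agent_id,
        wave_index=event.wave_index,
        arrival_frame=t0,
        rel_frames=frames - t0,
        dx=arr[:, 0],
        dy=arr[:, 1],
        dz=arr[:, 2],
        rs=event.rs,
        rrs=event.rrs,
        partial=partial,
    )


def offset_correct(episode: EpisodeRecord, offset_frames: int = 6) -> EpisodeRecord:
    """Subtract the mean of the first ``offset_frames`` pre-frames per axis.

    Idempotent: the reference frames have zero mean afterwards, so applying
    the correction again subtracts zero.
    """
    pre = episode.rel_frames < 0
    if pre.sum() < offset_frames:
        raise ValueError(
            f"offset correction needs {offset_frames} pre-frames, "
            f"episode has {int(pre.sum())}"
        )
    ref = np.nonzero(pre)[0][:offset_frames]
    for comp in ("dx", "dy", "dz"):
        series = getattr(episode, comp)
        setattr(episode, comp, series - series[ref].mean())
    episode.offset_corrected = True
    return episode


def classify_rs(
    episodes: list[EpisodeRecord],
    n_levels: int = 10,
    groups: tuple[int, int, int] = (3, 4, 3),
    rs_range: tuple[float, float] = (0.3, 0.8),
) -> list[EpisodeRecord]:
    """Sort episodes into rRS levels and low/middle/high groups.

    Levels are ``n_levels`` equal-width bins over ``rs_range``; rRS values
    outside the range are clipped into the end bins.  With the default
    (3, 4, 3) split, levels 1-3 are "low", 4-7 "middle" and 8-10 "high".
    """
    if sum(groups) != n_levels:
        raise ValueError("group sizes must sum to n_levels")
    lo, hi = rs_range
    width = (hi - lo) / n_levels
    bounds = np.cumsum(groups)
    for ep in episodes:
        if math.isnan(ep.rrs):
            raise ValueError(f"episode of agent {ep.agent_id} has no rRS")
        level = 1 + int((ep.rrs - lo) / width)
        level = min(max(level, 1), n_levels)
        ep.rs_level = level
        g = int(np.searchsorted(bounds, level, side="left"))
        ep.rs_group = GROUP_NAMES[min(g, 2)]
    return episodes


def pool_courses(
    episodes: list[EpisodeRecord],
    by: str = "rs_group",
    include_partial: bool = False,
) -> dict[str, PooledCourse]:
    """Arithmetic mean and s.e.m. time courses per group.

    Only full-length episodes enter the pool unless ``include_partial``;
    empty groups are skipped.  Pooling is independent of episode order.
    """
    groups: dict[str, list[EpisodeRecord]] = {}
    for ep in episodes:
        if ep.partial and not include_partial:
            continue
        groups.setdefault(getattr(ep, by), []).append(ep)
    out: dict[str, PooledCourse] = {}
    for key, eps in sorted(groups.items()):
        rel = eps[0].rel_frames
        stacks = {
            comp: np.stack([getattr(e, comp) for e in eps]) for comp in ("dx", "dy", "dz")
        }
        stacks["rrs"] = np.array([[e.rrs] * len(rel) for e in eps])
        n = len(eps)
        mean = {c: s.mean(axis=0) for c, s in stacks.items()}
        sem = {
            c: (s.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros(len(rel)))
            for c, s in stacks.items()
        }
        out[key] = PooledCourse(key, rel, mean, sem, n)
    return out


def component_correlation(
    episodes: list[EpisodeRecord], comp_a: str = "dx", comp_b: str = "dz"
) -> tuple[float, float]:
    """Pearson correlation of per-episode peak values of two components.

    The peak is the maximum of the component in the post-arrival half of the
    episode.  Returns (r, p).
    """
    peaks_a, peaks_b = [], []
    for ep in episodes:
        post = ep.rel_frames >= 0
        if not post.any():
            continue
        peaks_a.append(float(getattr(ep, comp_a)[post].max()))
        peaks_b.append(float(getattr(ep, comp_b)[post].max()))
    if len(peaks_a) < 3:
        raise ValueError("component correlation needs at least 3 episodes")
    if np.std(peaks_a) < 1e-12 or np.std(peaks_b) < 1e-12:
        raise ValueError("degenerate variance in component peaks")
    r, p = stats.pearsonr(peaks_a, peaks_b)
    return float(r), float(p)


def flip_angle(projected_len: float, full_len: float) -> float:
    """Momentary flip angle (degrees) from abdomen foreshortening.

    A flipping abdomen projects as an ellipse of decreasing length; assuming
    rotation in a plane containing the optical axis, the elevation is
    arccos(projected / full).
    """
    if full_len <= 0:
        raise ValueError("full length must be positive")
    if not 0 <= projected_len <= full_len:
        raise ValueError("projected length must lie in [0, full length]")
    return math.degrees(math.acos(projected_len / full_len))


def episodes_to_frame(episodes: list[EpisodeRecord]) -> pd.DataFrame:
    """Long-format table: one row per agent, wave and relative frame."""
    rows = []
    for ep in episodes:
        for j, rf in enumerate(ep.rel_frames):
            rows.append(
                (
                    ep.agent_id,
                    ep.wave_index,
                    int(rf),
                    ep.dx[j],
                    ep.dy[j],
                    ep.dz[j],
                    ep.rrs,
                    ep.rs_level,
                    ep.rs_group,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "agent_id",
            "wave_index",
            "rel_frame",
            "dx_mm",
            "dy_mm",
            "dz_mm",
            "rrs",
            "level",
            "group",
        ],
    )


def pooled_to_frame(course: PooledCourse) -> pd.DataFrame:
    data = {"rel_frame": course.rel_frames}
    for comp in ("dx", "dy", "dz", "rrs"):
        data[f"{comp}_mean"] = course.mean[comp]
        data[f"{comp}_sem"] = course.sem[comp]
    df = pd.DataFrame(data)
    df.insert(0, "group", course.rs_group)
    df["n"] = course.n
    return df
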