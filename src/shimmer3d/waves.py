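"""Wave-arrival detection from frame-difference luminance.

The arrival of a shimmering wave at an agent is read from the pixel-wise
absolute difference of consecutive frames, averaged over a sensor region of
interest (sROI, default 60x60 px = 18x18 mm at 0.3 mm/px) around the
agent's thorax.  Mean differences at or below ~5 are sensor noise
("motionless"); the wave front is declared when the series exceeds the
threshold (default 10) in three successive frames, and time zero is set two
frames before that run starts.  The maximum of the series in a short window
after arrival is the agent's response strength (RS); dividing by the
population maximum gives the relative response strength rRS in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LuminanceSeries:
    """Per-frame mean absolute sROI frame difference for one agent.

    ``values[i]`` is the mean |f_{i+1} - f_i| over the sROI, so the series
    is one shorter than the frame sequence.
    """

    agent_id: int
    values: np.ndarray
    sroi_px: int = 60

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class WaveEvent:
    agent_id: int
    arrival: int  # series index of time zero
    rs: float
    rrs: float = float("nan")
    wave_index: int = 0


def difference_image(f_prev: np.ndarray, f_curr: np.ndarray) -> np.ndarray:
    """Pixel-wise absolute luminance difference of two frames (0-255)."""
    a = np.asarray(f_prev, dtype=float)
    b = np.asarray(f_curr, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    return np.abs(b - a)


def rescale_to_8bit(img: np.ndarray) -> np.ndarray:
    """Linearly map higher-bit-depth frames onto the 0-255 scale."""
    img = np.asarray(img, dtype=float)
    if img.max() <= 255.0:
        return img
    if np.issubdtype(np.asarray(img).dtype, np.integer):
        return img * (255.0 / np.iinfo(np.asarray(img).dtype).max)
    return img * (255.0 / img.max())


def _window_mean(diff: np.ndarray, uv, size: int) -> float:
    half = size // 2
    u, v = int(round(uv[0])), int(round(uv[1]))
    v0, v1 = max(v - half, 0), min(v + half, diff.shape[0])
    u0, u1 = max(u - half, 0), min(u + half, diff.shape[1])
    if v0 >= v1 or u0 >= u1:
        return 0.0
    return float(diff[v0:v1, u0:u1].mean())


def sroi_series(diff_frames, center_track, sroi_px: int = 60, agent_id: int = 0) -> LuminanceSeries:
    """Mean sROI luminance difference per frame, following the track.

    ``diff_frames`` are the F-1 difference images of an F-frame sequence;
    ``center_track`` gives the agent's fused position per frame (length F-1
    or F; entry i is used for difference i).  None positions reuse the last
    known position; windows clipped at the image border average the valid
    area only.
    """
    values = []
    last = None
    for i, diff in enumerate(diff_frames):
        uv = center_track[i] if i < len(center_track) else None
        if uv is None:
            uv = last
        if uv is None:
            values.append(0.0)
            continue
        last = uv
        values.append(_window_mean(np.asarray(diff, dtype=float), uv, sroi_px))
    return LuminanceSeries(agent_id, np.array(values), sroi_px)


def detect_arrival(
    series,
    delta_l_th: float = 10.0,
    n_consecutive: int = 3,
    lead: int = 2,
    start: int = 0,
):
    """First wave arrival in a luminance series, or None.

    Finds the first index k >= ``start`` beginning a run of
    ``n_consecutive`` values strictly above ``delta_l_th`` and returns
    k - ``lead`` (clipped at 0).
    """
    vals = series.values if isinstance(series, LuminanceSeries) else np.asarray(series, dtype=float)
    above = vals > delta_l_th
    run = 0
    for k in range(start, len(vals)):
        run = run + 1 if above[k] else 0
        if run == n_consecutive:
            first = k - n_consecutive + 1
            return max(first - lead, 0)
    return None


def response_strength(series, arrival: int, window_frames: int = 12) -> float:
    """Max of the series in [arrival, arrival + window_frames]."""
    vals = series.values if isinstance(series, LuminanceSeries) else np.asarray(series, dtype=float)
    lo = max(arrival, 0)
    hi = min(arrival + window_frames + 1, len(vals))
    if lo >= hi:
        raise ValueError("response window lies outside the series")
    return float(vals[lo:hi].max())


def detect_events(
    series: LuminanceSeries,
    delta_l_th: float = 10.0,
    n_consecutive: int = 3,
    lead: int = 2,
    rs_window: int = 12,
    rearm_frames: int = 12,
) -> list[WaveEvent]:
    """All wave arrivals of one agent, with response strengths.

    After an arrival, detection re-arms once the series has stayed at or
    below the threshold for ``rearm_frames`` consecutive frames.
    """
    events: list[WaveEvent] = []
    vals = series.values
    pos = 0
    wave_index = 0
    while pos < len(vals):
        arrival = detect_arrival(vals, delta_l_th, n_consecutive, lead, start=pos)
        if arrival is None:
            break
        rs = response_strength(series, arrival, rs_window)
        events.append(WaveEvent(series.agent_id, arrival, rs, wave_index=wave_index))
        wave_index += 1
        # re-arm: find rearm_frames consecutive sub-threshold values
        k = max(arrival + lead, arrival) + 1
        quiet = 0
        while k < len(vals):
            quiet = quiet + 1 if vals[k] <= delta_l_th else 0
            if quiet >= rearm_frames:
                break
            k += 1
        pos = k + 1
    return events


def normalize_rrs(events: list[WaveEvent]) -> list[WaveEvent]:
    """Attach rRS = RS / max RS over all events; the max maps to 1.0."""
    if not events:
        raise ValueError("normalize_rrs needs at least one event")
    max_rs = max(e.rs for e in events)
    if max_rs <= 0:
        raise ValueError("all response strengths are zero")
    for e in events:
        e.rrs = e.rs / max_rs
    return events


def global_activity(diff_frames, positions_per_frame, delta_l_th: float = 10.0, sroi_px: int = 60) -> np.ndarray:
    """Per difference frame, the fraction of agents whose sROI mean exceeds
    the threshold.  ``positions_per_frame[i]`` is a list of (u, v) or None."""
    out = np.zeros(len(diff_frames))
    for i, diff in enumerate(diff_frames):
        diff = np.asarray(diff, dtype=float)
        positions = positions_per_frame[i] if i < len(positions_per_frame) else []
        live = [uv for uv in positions if uv is not None]
        if not live:
            continue
        n_active = sum(_window_mean(diff, uv, sroi_px) > delta_l_th for uv in live)
        out[i] = n_active / len(live)
    return out
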