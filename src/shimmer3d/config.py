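"""Pipeline configuration: every stage default in one validated place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np


@dataclass
class PipelineConfig:
    """Defaults for all pipeline stages.

    Units: px unless stated; luminance thresholds on the 0-255 scale;
    windows in frames at the acquisition frame rate.
    """

    # segmentation
    min_score: float = 0.6
    suppress_radius: float = 20.0
    angle_range: float = 23.0
    angle_step: float = 2.86
    scale_px: float = 9.0
    body_length_px: float = 65.63
    # stereo matching
    row_tol: float = 2.0
    n_slots: int = 3
    lam: float = 0.3
    occlusion_cost: float = 0.6
    disparity_range: tuple[float, float] | None = None  # None: from rig volume
    z_half_extent_mm: float = 75.0  # half-depth of the measurement volume
    # tracking
    template_px: int = 20
    search_px: int = 40
    memory_frames: int = 15
    track_min_score: float = 0.4
    subpixel: bool = False
    reseed_activity_frac: float = 0.05
    reseed_quiet_frames: int = 30
    # wave detection
    sroi_px: int = 60
    delta_l_th: float = 10.0
    n_consecutive: int = 3
    lead: int = 2
    rs_window: int = 12
    rearm_frames: int = 12
    # episodes
    pre_frames: int = 30
    post_frames: int = 60
    offset_frames: int = 6
    n_levels: int = 10
    group_split: tuple[int, int, int] = (3, 4, 3)
    rs_range: tuple[float, float] = (0.3, 0.8)
    # bookkeeping
    seed: int = 0

    def validate(self) -> None:
        checks = [
            (0 <= self.min_score <= 1, "min_score in [0, 1]"),
            (self.suppress_radius >= 0, "suppress_radius >= 0"),
            (self.angle_step > 0, "angle_step > 0"),
            (self.row_tol >= 0, "row_tol >= 0"),
            (self.n_slots >= 1, "n_slots >= 1"),
            (self.lam >= 0, "lambda >= 0"),
            (self.occlusion_cost > 0, "occlusion cost > 0"),
            (self.template_px >= 3, "template_px >= 3"),
            (self.search_px > self.template_px, "search_px > template_px"),
            (self.memory_frames >= 1, "memory_frames >= 1"),
            (0 <= self.track_min_score <= 1, "track_min_score in [0, 1]"),
            (self.sroi_px >= 1, "sroi_px >= 1"),
            (self.delta_l_th >= 0, "luminance threshold >= 0"),
            (self.n_consecutive >= 1, "n_consecutive >= 1"),
            (self.lead >= 0, "lead >= 0"),
            (self.pre_frames >= self.offset_frames, "pre_frames >= offset_frames"),
            (self.post_frames >= 1, "post_frames >= 1"),
            (self.n_levels >= 1, "n_levels >= 1"),
            (sum(self.group_split) == self.n_levels, "group split sums to n_levels"),
            (self.rs_range[0] < self.rs_range[1], "rs_range increasing"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid configuration: {msg}")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = {}
        for f in cls.__dataclass_fields__:
            if f in data:
                val = data[f]
                if isinstance(val, list):
                    val = tuple(val)
                kwargs[f] = val
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def disparity_range_from_rig(rig, z_half_extent_mm: float = 75.0) -> tuple[float, float]:
    """Admissible disparity interval covering the rig's measurement depth.

    Projects points on the optical axis at z = -/+ the half extent into both
    views and reads off the disparity span.
    """
    pts = np.array([[0.0, 0.0, -z_half_extent_mm], [0.0, 0.0, z_half_extent_mm]])
    rect = rig.rectified()
    ul = rect.project(pts, "left")[:, 0]
    ur = rect.project(pts, "right")[:, 0]
    disp = ul - ur
    return float(disp.min()), float(disp.max())
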