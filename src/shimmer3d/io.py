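"""Frame-sequence reading and CSV/JSON output helpers."""

from __future__ import annotations

import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np

FRAME_PATTERN = re.compile(r"(\d+)\.(png|tif|tiff)$", re.IGNORECASE)


class SequenceError(ValueError):
    """Raised for missing, unordered or inconsistent frame sequences."""


def list_frames(path) -> list[Path]:
    """Numbered frame files of a directory in numeric order."""
    path = Path(path)
    if not path.is_dir():
        raise SequenceError(f"not a directory: {path}")
    entries = []
    for p in sorted(path.iterdir()):
        m = FRAME_PATTERN.search(p.name)
        if m:
            entries.append((int(m.group(1)), p))
    if not entries:
        raise SequenceError(f"no numbered PNG/TIFF frames in {path}")
    entries.sort(key=lambda e: e[0])
    numbers = [n for n, _ in entries]
    if len(set(numbers)) != len(numbers):
        raise SequenceError(f"duplicate frame numbers in {path}")
    return [p for _, p in entries]


def read_sequence(path, view: str = "left"):
    """Yield the frames of one camera directory as 8-bit grayscale arrays.

    Frames are ordered by their numeric filename; mixed dimensions raise.
    """
    shape = None
    for p in list_frames(path):
        img = iio.imread(p)
        if img.ndim == 3:
            img = img.mean(axis=-1)
        img = np.asarray(img)
        if img.dtype != np.uint8:
            img = np.clip(img, 0, 255).astype(np.uint8)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise SequenceError(
                f"mixed frame dimensions in {path}: {shape} vs {img.shape} ({p.name})"
            )
        yield img


def read_pair(left_dir, right_dir):
    """Read both camera sequences; lengths must agree."""
    frames_l = list(read_sequence(left_dir, "left"))
    frames_r = list(read_sequence(right_dir, "right"))
    if len(frames_l) != len(frames_r):
        raise SequenceError(
            f"unequal sequence lengths: {len(frames_l)} left vs {len(frames_r)} right"
        )
    return frames_l, frames_r
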