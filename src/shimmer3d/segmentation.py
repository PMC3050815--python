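"""Agent detection by normalized cross-correlation against a template bank.

Hundreds of near-identical bees cover the curtain surface; individual agents
are found by correlating the image with a bank of bee templates at a grid of
orientations and scales, keeping local correlation maxima and suppressing
weaker maxima near dominant ones.  Normalized cross-correlation (NCC) is
used throughout because it is invariant to affine luminance changes, which
matters under field illumination.

For an image ``f`` and template ``t`` placed at (u, v), the NCC is

    gamma(u, v) = sum (f - mean_f)(t - mean_t)
                  / sqrt(sum (f - mean_f)^2 * sum (t - mean_t)^2)

with the image statistics taken over the window under the template.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter
from scipy.signal import fftconvolve
from skimage.transform import rescale, rotate

from . import _sprites

DEFAULT_BODY_LENGTH_PX = 65.63  # reference bee length at 0.3 mm/px
DEFAULT_ANGLE_RANGE = 23.0  # total orientation span, degrees
DEFAULT_ANGLE_STEP = 2.86
DEFAULT_SCALE_PX = 9.0  # +- scale tolerance expressed in px of body length


@dataclass
class Template:
    """One grayscale bee template with its thorax anchor."""

    pixels: np.ndarray
    angle: float = 0.0
    scale: float = 1.0
    body_length_px: float = DEFAULT_BODY_LENGTH_PX
    anchor_uv: tuple[float, float] = (0.0, 0.0)  # thorax (u, v) within the patch

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 3:
            raise ValueError("template must be a 2-D patch of at least 3x3 px")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("template pixels must be finite")


@dataclass
class TemplateBank:
    templates: list[Template]
    angle_range: float = DEFAULT_ANGLE_RANGE
    angle_step: float = DEFAULT_ANGLE_STEP
    scale_range: float = DEFAULT_SCALE_PX / DEFAULT_BODY_LENGTH_PX

    def __post_init__(self) -> None:
        if not self.templates:
            raise ValueError("template bank must not be empty")

    def __len__(self) -> int:
        return len(self.templates)


@dataclass
class Detection:
    """One segmented agent in one image."""

    thorax: tuple[float, float]  # (u, v) px
    angle: float
    scale: float
    score: float
    box: tuple[int, int, int, int] = (0, 0, 0, 0)  # (u0, v0, width, height)


def ncc_map(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """NCC correlation surface of ``template`` over every valid placement.

    Returns an array of shape (H - k + 1, W - l + 1) whose entry (i, j) is
    the NCC of the template with the image window whose top-left corner is
    (i, j).  Windows (or templates) with zero variance get value 0.
    """
    img = np.asarray(image, dtype=float)
    t = np.asarray(template, dtype=float)
    if t.ndim != 2 or img.ndim != 2:
        raise ValueError("image and template must be 2-D")
    k, l = t.shape
    if k > img.shape[0] or l > img.shape[1]:
        raise ValueError("template larger than image")
    n = k * l
    t0 = t - t.mean()
    t_norm = math.sqrt(float((t0**2).sum()))
    out_shape = (img.shape[0] - k + 1, img.shape[1] - l + 1)
    if t_norm < 1e-12:
        return np.zeros(out_shape)

    # windowed sums via an integral image (exact), numerator via FFT
    def window_sums(a: np.ndarray) -> np.ndarray:
        S = np.zeros((a.shape[0] + 1, a.shape[1] + 1))
        np.cumsum(np.cumsum(a, axis=0), axis=1, out=S[1:, 1:])
        return S[k:, l:] - S[:-k, l:] - S[k:, :-l] + S[:-k, :-l]

    win_sum = window_sums(img)
    win_ss = window_sums(img**2)
    num = fftconvolve(img, t0[::-1, ::-1], mode="valid")
    var = np.maximum(win_ss - win_sum**2 / n, 0.0)
    denom = np.sqrt(var) * t_norm
    tol = 1e-8 * max(float(win_ss.max()), 1.0) ** 0.5 * t_norm
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = np.where(denom > tol, num / np.maximum(denom, 1e-300), 0.0)
    return np.clip(gamma, -1.0, 1.0)


def make_bee_template(
    body_length_px: float = DEFAULT_BODY_LENGTH_PX,
    smooth_sigma: float = 1.0,
    background: float = 20.0,
) -> Template:
    """Synthesize the base template: thorax + abdomen ellipses, smoothed.

    The head is omitted, as it is usually concealed by neighbouring bees;
    the thorax anchor sits near the top of the patch.
    """
    from scipy.ndimage import gaussian_filter

    h, w = _sprites.sprite_extent(body_length_px)
    patch = np.full((h, w), background)
    anchor = (w / 2.0, _sprites.THORAX_SEMI_MAJOR * body_length_px + 2.0)
    _sprites.draw_bee(patch, anchor, 0.0, body_length_px)
    if smooth_sigma > 0:
        patch = gaussian_filter(patch, smooth_sigma)
    return Template(patch, 0.0, 1.0, body_length_px, anchor)


def build_template_bank(
    base: Template | None = None,
    angle_range: float = DEFAULT_ANGLE_RANGE,
    angle_step: float = DEFAULT_ANGLE_STEP,
    scale_px: float = DEFAULT_SCALE_PX,
    ref_length_px: float | None = None,
    n_scales: int = 3,
) -> TemplateBank:
    """Rotated/scaled variants of a base template.

    Orientations span [-angle_range/2, +angle_range/2] in steps of
    ``angle_step``; scales span +-``scale_px``/``ref_length_px`` around 1 in
    ``n_scales`` grid points.  ``angle_range == 0`` and ``scale_px == 0``
    yield a bank holding exactly the base template.
    """
    if angle_step <= 0:
        raise ValueError("angle_step must be positive")
    if base is None:
        base = make_bee_template()
    if ref_length_px is None:
        ref_length_px = base.body_length_px

    if angle_range <= 0:
        angles = np.array([0.0])
    else:
        n_angles = int(round(angle_range / angle_step)) + 1
        angles = np.linspace(-angle_range / 2.0, angle_range / 2.0, n_angles)
    scale_frac = scale_px / ref_length_px
    if scale_frac <= 0 or n_scales <= 1:
        scales = np.array([1.0])
    else:
        scales = np.linspace(1.0 - scale_frac, 1.0 + scale_frac, n_scales)

    templates = []
    for s in scales:
        if abs(s - 1.0) < 1e-12:
            scaled = base.pixels
            anchor = base.anchor_uv
        else:
            scaled = rescale(base.pixels, s, order=1, preserve_range=True, anti_aliasing=s < 1)
            anchor = (base.anchor_uv[0] * s, base.anchor_uv[1] * s)
        for a in angles:
            if abs(a) < 1e-12:
                px = scaled
            else:
                px = rotate(
                    scaled, a, center=anchor, order=1, preserve_range=True,
                    mode="constant", cval=float(np.median(scaled)),
                )
            templates.append(
                Template(px, float(a), float(s), base.body_length_px * s, anchor)
            )
    return TemplateBank(templates, angle_range, angle_step, scale_frac)


def segment_agents(
    image: np.ndarray,
    bank: TemplateBank,
    min_score: float = 0.6,
    suppress_radius: float = 20.0,
) -> list[Detection]:
    """Detect agents as NCC local maxima over all templates in the bank.

    Per pixel, the best-scoring template wins; local maxima of the combined
    score surface at or above ``min_score`` become candidate detections, and
    weaker candidates within ``suppress_radius`` px of a stronger one are
    eliminated (greedy, descending score, ties broken by row then column).
    """
    img = np.asarray(image, dtype=float)
    best = np.full(img.shape, -np.inf)
    best_idx = np.zeros(img.shape, dtype=np.int32)
    for idx, tpl in enumerate(bank.templates):
        g = ncc_map(img, tpl.pixels)
        du = int(round(tpl.anchor_uv[0]))
        dv = int(round(tpl.anchor_uv[1]))
        view = best[dv : dv + g.shape[0], du : du + g.shape[1]]
        sel = g > view
        view[sel] = g[sel]
        best_idx[dv : dv + g.shape[0], du : du + g.shape[1]][sel] = idx

    finite = np.isfinite(best)
    local_max = (best == maximum_filter(best, size=3)) & finite & (best >= min_score)
    rows, cols = np.nonzero(local_max)
    scores = best[rows, cols]
    order = np.lexsort((cols, rows, -scores))
    accepted: list[Detection] = []
    acc_pts: list[tuple[float, float]] = []
    r2 = suppress_radius**2
    for o in order:
        v, u, s = float(rows[o]), float(cols[o]), float(scores[o])
        if any((u - au) ** 2 + (v - av) ** 2 <= r2 for au, av in acc_pts):
            continue
        tpl = bank.templates[int(best_idx[int(v), int(u)])]
        h, w = tpl.pixels.shape
        box = (
            int(u - round(tpl.anchor_uv[0])),
            int(v - round(tpl.anchor_uv[1])),
            w,
            h,
        )
        accepted.append(Detection((u, v), tpl.angle, tpl.scale, s, box))
        acc_pts.append((u, v))
    return accepted


def detections_to_frame(
    detections: list[Detection], frame: int = 0, camera: str = "left"
) -> pd.DataFrame:
    """Tabulate detections: frame, camera, id, u, v, angle_deg, scale, score."""
    return pd.DataFrame(
        {
            "frame": frame,
            "camera": camera,
            "id": np.arange(len(detections)),
            "u": [d.thorax[0] for d in detections],
            "v": [d.thorax[1] for d in detections],
            "angle_deg": [d.angle for d in detections],
            "scale": [d.scale for d in detections],
            "score": [d.score for d in detections],
        }
    )
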