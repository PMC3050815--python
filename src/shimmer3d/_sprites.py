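"""Two-ellipse bee sprite used by the synthetic renderer and template builder.

A surface bee seen from the front of the curtain is drawn as a bright thorax
ellipse with the longer, dimmer abdomen hanging below it (head up, abdomen
down; the head is concealed in real nests and is not drawn).  Abdominal
flipping rotates the abdomen out of the image plane, which foreshortens its
projected length by cos(flip angle) — the image cue the motion detector and
the flip-angle estimate rely on.
"""

from __future__ import annotations

import math

import numpy as np

# fractions of the full body length (head ~0.2 L is concealed and not drawn,
# so the visible thorax + abdomen span ~0.78 L; a 6 mm abdomen width is
# ~0.3 L, i.e. ~20 px at the reference length of ~65 px)
THORAX_SEMI_MAJOR = 0.11
THORAX_SEMI_MINOR = 0.095
ABDOMEN_SEMI_MAJOR = 0.27
ABDOMEN_SEMI_MINOR = 0.15
ABDOMEN_GAP = 0.02  # between thorax and abdomen ellipse edges
MIN_FORESHORTEN = 0.10  # a fully flipped abdomen still shows a curved stub
VENTRAL_BRIGHTEN = 0.5  # raised abdomens expose the paler ventral surface

THORAX_INTENSITY = 220.0
ABDOMEN_INTENSITY = 200.0
ABDOMEN_BANDS = 3  # dark transverse bands along the abdomen
ABDOMEN_BAND_DEPTH = 0.7  # high-contrast banding, as in A. dorsata


def draw_ellipse(
    canvas: np.ndarray,
    center_uv: tuple[float, float],
    semi_axes: tuple[float, float],
    angle_deg: float,
    intensity: float,
    n_bands: int = 0,
    band_depth: float = 0.0,
) -> None:
    """Max-composite an anti-aliased filled ellipse onto ``canvas`` in place.

    ``center_uv`` is (column, row) in float pixels; ``semi_axes`` is
    (along-axis, across-axis) in px; ``angle_deg`` rotates the major axis
    from the +v (downward) direction, positive clockwise in image coords.
    """
    h, w = canvas.shape
    cu, cv = center_uv
    a, b = semi_axes
    if a <= 0 or b <= 0:
        return
    rad = math.radians(angle_deg)
    ext = max(a, b) + 1.5
    u0, u1 = int(math.floor(cu - ext)), int(math.ceil(cu + ext)) + 1
    v0, v1 = int(math.floor(cv - ext)), int(math.ceil(cv + ext)) + 1
    u0, u1 = max(u0, 0), min(u1, w)
    v0, v1 = max(v0, 0), min(v1, h)
    if u0 >= u1 or v0 >= v1:
        return
    uu, vv = np.meshgrid(np.arange(u0, u1, dtype=float), np.arange(v0, v1, dtype=float))
    du, dv = uu - cu, vv - cv
    # body-frame coordinates: p along the major axis (downward at angle 0)
    p = du * math.sin(rad) + dv * math.cos(rad)
    q = du * math.cos(rad) - dv * math.sin(rad)
    r = np.sqrt((p / a) ** 2 + (q / b) ** 2)
    cov = np.clip((1.0 - r) * min(a, b), 0.0, 1.0)  # ~1 px soft edge
    value = intensity * cov
    if n_bands > 0 and band_depth > 0:
        # transverse banding; the pattern compresses with the projected
        # length, so a flipping abdomen changes its interior luminance
        stripes = 1.0 - band_depth * (0.5 + 0.5 * np.cos(n_bands * np.pi * p / a))
        value = value * stripes
    region = canvas[v0:v1, u0:u1]
    np.maximum(region, value, out=region)


def draw_bee(
    canvas: np.ndarray,
    thorax_uv: tuple[float, float],
    angle_deg: float,
    body_length_px: float,
    flip_angle_deg: float = 0.0,
    thorax_intensity: float = THORAX_INTENSITY,
    abdomen_intensity: float = ABDOMEN_INTENSITY,
) -> None:
    """Draw one bee (thorax + abdomen) onto ``canvas`` in place.

    ``angle_deg`` is the body-axis orientation (0 = vertical, head up);
    ``flip_angle_deg`` is the abdominal elevation out of the image plane.
    """
    L = body_length_px
    phi = math.radians(flip_angle_deg)
    fore = max(math.cos(phi), MIN_FORESHORTEN)
    a_abd = ABDOMEN_SEMI_MAJOR * L * fore
    abdomen_intensity = abdomen_intensity * (1.0 + VENTRAL_BRIGHTEN * abs(math.sin(phi)))
    rad = math.radians(angle_deg)
    down = np.array([math.sin(rad), math.cos(rad)])  # (du, dv) unit, body-down
    offset = (THORAX_SEMI_MAJOR + ABDOMEN_GAP) * L + a_abd
    abd_center = np.asarray(thorax_uv, dtype=float) + down * offset
    draw_ellipse(
        canvas,
        tuple(abd_center),
        (a_abd, ABDOMEN_SEMI_MINOR * L),
        angle_deg,
        abdomen_intensity,
        n_bands=ABDOMEN_BANDS,
        band_depth=ABDOMEN_BAND_DEPTH,
    )
    draw_ellipse(
        canvas,
        tuple(thorax_uv),
        (THORAX_SEMI_MAJOR * L, THORAX_SEMI_MINOR * L),
        angle_deg,
        thorax_intensity,
    )


def sprite_extent(body_length_px: float) -> tuple[int, int]:
    """(height, width) of a patch that holds an unrotated, unflipped bee."""
    L = body_length_px
    height = int(math.ceil(L * (THORAX_SEMI_MAJOR * 2 + ABDOMEN_GAP + ABDOMEN_SEMI_MAJOR * 2))) + 4
    width = int(math.ceil(L * 2 * ABDOMEN_SEMI_MINOR)) + 6
    return height, width
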