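"""Stereo rig geometry: baselines, depth error, rectification and triangulation.

The rig model is a calibrated two-camera setup converging on a nest surface:
two cameras a baseline ``b`` apart at working distance ``d``, subtending a
stereo angle ``alpha``.  World coordinates are metric (mm) in the nest frame:
``x`` horizontal (right-positive), ``y`` vertical (up-positive), ``z`` away
from the comb (towards the cameras).  Image coordinates are 0-based with the
origin at the top-left corner; ``u`` is the column and ``v`` the row, so
world ``y`` increases opposite to ``v``.

Projection matrices map homogeneous world points in mm to homogeneous pixel
coordinates.  After rectification the epipolar lines are horizontal, so a
correspondence search reduces to a 1-D search along the row.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage.transform import ProjectiveTransform, warp


class DegenerateGeometryError(ValueError):
    """Raised when a stereo configuration admits no parallax."""


class MissingCalibrationError(ValueError):
    """Raised when an operation needs calibration data the rig lacks."""


def compute_baseline(d: float, alpha: float) -> float:
    """Baseline b = 2 d tan(alpha/2) of two cameras converging at distance d.

    Parameters
    ----------
    d : float
        Working distance in metres.
    alpha : float
        Stereo (vergence) angle in degrees, 0 < alpha < 180.

    Returns
    -------
    float
        Baseline in metres.
    """
    if d <= 0:
        raise ValueError(f"working distance must be positive, got {d}")
    if not 0 < alpha < 180:
        raise ValueError(f"stereo angle must be in (0, 180) degrees, got {alpha}")
    return 2.0 * d * math.tan(math.radians(alpha) / 2.0)


def expected_depth_error(alpha: float, m: float, e_img: float) -> float:
    """Expected depth error e_z = (1/sin alpha) * m * e_img * cos(alpha/2).

    This is the first-order error of triangulated depth for orthogonally
    arranged cameras given a stereo-matching error of ``e_img`` pixels.

    Parameters
    ----------
    alpha : float
        Stereo angle in degrees, 0 < alpha < 180.
    m : float
        Magnification in mm per pixel at the working distance.
    e_img : float
        Assumed pixel error of stereo matching (px).

    Returns
    -------
    float
        Expected depth error in mm.
    """
    if not 0 < alpha < 180:
        raise ValueError(f"stereo angle must be in (0, 180) degrees, got {alpha}")
    if m <= 0:
        raise ValueError(f"magnification must be positive, got {m}")
    if e_img < 0:
        raise ValueError(f"pixel error must be non-negative, got {e_img}")
    a = math.radians(alpha)
    return (1.0 / math.sin(a)) * m * e_img * math.cos(a / 2.0)


def cross_matrix(h) -> np.ndarray:
    """3x3 antisymmetric matrix [h]_x with [h]_x @ v == cross(h, v)."""
    h = np.asarray(h, dtype=float).reshape(3)
    if not np.all(np.isfinite(h)):
        raise ValueError("cross_matrix requires a finite 3-vector")
    return np.array(
        [
            [0.0, -h[2], h[1]],
            [h[2], 0.0, -h[0]],
            [-h[1], h[0], 0.0],
        ]
    )


@dataclass(frozen=True)
class Point3D:
    """A metric 3D point in the nest frame (mm)."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class StereoRig:
    """Calibrated stereo rig.

    Attributes
    ----------
    P_left, P_right : (3, 4) ndarray
        Camera projection matrices; pixels out, world mm in.
    H_left, H_right : (3, 3) ndarray
        Rectifying homographies mapping raw image coordinates to rectified
        ones.  Identity for a rig whose P matrices already describe
        rectified images.
    d : float
        Working distance in metres.
    alpha : float
        Stereo angle in degrees.
    b : float
        Baseline in metres.
    m : float
        Magnification, mm per px at the working distance.
    e_img : float
        Assumed stereo-matching pixel error (px), used for error budgets.
    image_size : (int, int)
        (height, width) of the images in px.
    """

    P_left: np.ndarray
    P_right: np.ndarray
    H_left: np.ndarray = field(default_factory=lambda: np.eye(3))
    H_right: np.ndarray = field(default_factory=lambda: np.eye(3))
    d: float = 2.0
    alpha: float = 30.0
    b: float = 1.0718
    m: float = 0.3
    e_img: float = 1.0
    image_size: tuple[int, int] = (1728, 2352)

    def __post_init__(self) -> None:
        self.P_left = np.asarray(self.P_left, dtype=float).reshape(3, 4)
        self.P_right = np.asarray(self.P_right, dtype=float).reshape(3, 4)
        self.H_left = np.asarray(self.H_left, dtype=float).reshape(3, 3)
        self.H_right = np.asarray(self.H_right, dtype=float).reshape(3, 3)
        if np.linalg.matrix_rank(self.P_left) != 3 or np.linalg.matrix_rank(self.P_right) != 3:
            raise ValueError("projection matrices must have rank 3")
        if self.m <= 0:
            raise ValueError("magnification must be positive")
        if not 0 < self.alpha < 180:
            raise ValueError("stereo angle must be in (0, 180) degrees")

    # -- derived quantities -------------------------------------------------
    @property
    def depth_error_mm(self) -> float:
        """Expected depth error e_z for this rig's alpha, m and e_img."""
        return expected_depth_error(self.alpha, self.m, self.e_img)

    def camera_center(self, view: str) -> np.ndarray:
        """World-frame camera centre (mm) = right null vector of P."""
        P = self.P_left if view == "left" else self.P_right
        _, _, vt = np.linalg.svd(P)
        c = vt[-1]
        if abs(c[3]) < 1e-12:
            raise DegenerateGeometryError("camera centre at infinity")
        return c[:3] / c[3]

    def project(self, points, view: str) -> np.ndarray:
        """Project (n, 3) world points (mm) to (n, 2) pixel (u, v)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        P = self.P_left if view == "left" else self.P_right
        homo = np.hstack([pts, np.ones((len(pts), 1))])
        uvw = homo @ P.T
        return uvw[:, :2] / uvw[:, 2:3]

    def rectified(self) -> "StereoRig":
        """Rig expressed in rectified image coordinates (H folded into P)."""
        return replace(
            self,
            P_left=self.H_left @ self.P_left,
            P_right=self.H_right @ self.P_right,
            H_left=np.eye(3),
            H_right=np.eye(3),
        )


def _look_at_rotation(center: np.ndarray, target: np.ndarray) -> np.ndarray:
    """World->camera rotation for a camera at ``center`` looking at ``target``.

    Camera axes: x to the right, y down (image rows), z forward.
    """
    fwd = target - center
    fwd = fwd / np.linalg.norm(fwd)
    up = np.array([0.0, 1.0, 0.0])
    right = np.cross(fwd, up)
    right = right / np.linalg.norm(right)
    down = np.cross(fwd, right)
    return np.stack([right, down, fwd])


def _intrinsics(f_px: float, cu: float, cv: float) -> np.ndarray:
    return np.array([[f_px, 0.0, cu], [0.0, f_px, cv], [0.0, 0.0, 1.0]])


def make_parallel_rig(
    alpha: float = 30.0,
    d: float = 2.0,
    m: float = 0.3,
    image_size: tuple[int, int] = (1728, 2352),
    e_img: float = 1.0,
) -> StereoRig:
    """Rig in rectified (parallel-camera) geometry.

    The cameras sit at x = -b/2 and +b/2 (mm), both looking along -z with
    identical orientation; the per-view principal points are offset so that
    the world origin (comb-plane centre at the working distance) projects to
    the image centre in both views, i.e. disparity is zero at z = 0.  The
    stereo angle fixes the baseline via b = 2 d tan(alpha/2).  Homographies
    are identity: images rendered or acquired through this rig are already
    rectified, and projections of any world point share their row exactly.
    """
    h_px, w_px = image_size
    d_mm = d * 1000.0
    b_mm = compute_baseline(d, alpha) * 1000.0
    f_px = d_mm / m
    R = np.array([[1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, -1.0]])
    cv = h_px / 2.0
    rig_P = {}
    for sign, view in ((-1.0, "left"), (1.0, "right")):
        C = np.array([sign * b_mm / 2.0, 0.0, d_mm])
        # principal point offset puts the origin at the image centre
        cu = w_px / 2.0 + sign * f_px * b_mm / (2.0 * d_mm)
        K = _intrinsics(f_px, cu, cv)
        rig_P[view] = K @ np.hstack([R, -R @ C[:, None]])
    return StereoRig(
        P_left=rig_P["left"],
        P_right=rig_P["right"],
        d=d,
        alpha=alpha,
        b=b_mm / 1000.0,
        m=m,
        e_img=e_img,
        image_size=image_size,
    )


def make_verged_rig(
    alpha: float = 30.0,
    d: float = 2.0,
    m: float = 0.3,
    image_size: tuple[int, int] = (1728, 2352),
    e_img: float = 1.0,
) -> StereoRig:
    """Rig with physically converging cameras and computed rectification.

    Both cameras point at the world origin, separated by the baseline of
    ``compute_baseline(d, alpha)``.  The rectifying homographies rotate both
    views onto a common image plane whose x-axis is the baseline direction,
    so that rectified correspondences share rows.
    """
    h_px, w_px = image_size
    d_mm = d * 1000.0
    b_mm = compute_baseline(d, alpha) * 1000.0
    f_px = d_mm / m
    target = np.zeros(3)
    centers = {
        "left": np.array([-b_mm / 2.0, 0.0, d_mm]),
        "right": np.array([b_mm / 2.0, 0.0, d_mm]),
    }
    K = _intrinsics(f_px, w_px / 2.0, h_px / 2.0)
    P = {}
    R = {}
    for view, C in centers.items():
        R[view] = _look_at_rotation(C, target)
        P[view] = K @ np.hstack([R[view], -R[view] @ C[:, None]])

    # common rectified orientation: x along the baseline, z the mean forward
    r1 = centers["right"] - centers["left"]
    r1 = r1 / np.linalg.norm(r1)
    fwd_mean = R["left"][2] + R["right"][2]
    r3 = fwd_mean - np.dot(fwd_mean, r1) * r1
    r3 = r3 / np.linalg.norm(r3)
    r2 = np.cross(r3, r1)
    R_rect = np.stack([r1, r2, r3])
    H = {view: K @ R_rect @ R[view].T @ np.linalg.inv(K) for view in centers}
    return StereoRig(
        P_left=P["left"],
        P_right=P["right"],
        H_left=H["left"],
        H_right=H["right"],
        d=d,
        alpha=alpha,
        b=b_mm / 1000.0,
        m=m,
        e_img=e_img,
        image_size=image_size,
    )


def triangulate(t_left, t_right, rig: StereoRig) -> tuple[Point3D, float]:
    """Triangulate one stereo correspondence to a metric 3D point.

    Stacks the two cross-product constraints [t]_x P T = 0 into a 6x4
    homogeneous system and takes its least-squares null vector (smallest
    right singular vector), dehomogenized to mm.

    Parameters
    ----------
    t_left, t_right : array-like
        Pixel coordinates, either (u, v) or homogeneous (u, v, w), in the
        image frame the rig's P matrices refer to.
    rig : StereoRig

    Returns
    -------
    (Point3D, float)
        The triangulated point and the residual (smallest singular value of
        the stacked system, after row normalization).
    """
    cl = rig.camera_center("left")
    cr = rig.camera_center("right")
    if np.linalg.norm(cl - cr) < 1e-9:
        raise DegenerateGeometryError("camera centres coincide: no parallax")

    def homog(t):
        t = np.asarray(t, dtype=float).reshape(-1)
        if t.size == 2:
            return np.array([t[0], t[1], 1.0])
        return t / t[2]

    A = np.vstack(
        [
            cross_matrix(homog(t_left)) @ rig.P_left,
            cross_matrix(homog(t_right)) @ rig.P_right,
        ]
    )
    # normalize rows for a meaningful residual scale; drop numerically null rows
    norms = np.linalg.norm(A, axis=1)
    keep = norms > 1e-12
    A = A[keep] / norms[keep, None]
    _, s, vt = np.linalg.svd(A)
    T = vt[-1]
    if abs(T[3]) < 1e-12:
        raise DegenerateGeometryError("triangulated point at infinity")
    xyz = T[:3] / T[3]
    return Point3D(*xyz), float(s[-1])


def triangulate_many(uv_left: np.ndarray, uv_right: np.ndarray, rig: StereoRig) -> np.ndarray:
    """Triangulate (n, 2) pixel correspondences to (n, 3) mm points."""
    uv_left = np.atleast_2d(uv_left)
    uv_right = np.atleast_2d(uv_right)
    out = np.empty((len(uv_left), 3))
    for i, (tl, tr) in enumerate(zip(uv_left, uv_right)):
        p, _ = triangulate(tl, tr, rig)
        out[i] = (p.x, p.y, p.z)
    return out


def rectify_points(points_uv, H: np.ndarray) -> np.ndarray:
    """Apply a rectifying homography to (n, 2) pixel points."""
    pts = np.atleast_2d(np.asarray(points_uv, dtype=float))
    homo = np.hstack([pts, np.ones((len(pts), 1))])
    mapped = homo @ H.T
    return mapped[:, :2] / mapped[:, 2:3]


def rectify_pair(img_l: np.ndarray, img_r: np.ndarray, rig: StereoRig):
    """Warp a raw stereo pair into rectified geometry.

    After warping, projections of the same world point lie in the same image
    row (up to interpolation effects).  Identity homographies return the
    inputs unchanged.
    """
    if rig.H_left is None or rig.H_right is None:
        raise MissingCalibrationError("rig has no rectifying homographies")
    out = []
    for img, H in ((img_l, rig.H_left), (img_r, rig.H_right)):
        if np.allclose(H, np.eye(3)):
            out.append(img)
            continue
        tf = ProjectiveTransform(matrix=np.linalg.inv(H))
        warped = warp(img.astype(float), tf, preserve_range=True, order=1, cval=0.0)
        out.append(warped.astype(img.dtype) if img.dtype == np.uint8 else warped)
    return out[0], out[1]


# -- calibration file I/O ---------------------------------------------------

def save_calibration(rig: StereoRig, path) -> None:
    """Write the rig to a JSON calibration file."""
    payload = {
        "p_left": rig.P_left.tolist(),
        "p_right": rig.P_right.tolist(),
        "h_left": rig.H_left.tolist(),
        "h_right": rig.H_right.tolist(),
        "alpha_deg": rig.alpha,
        "baseline_m": rig.b,
        "working_distance_m": rig.d,
        "mm_per_px": rig.m,
        "e_img_px": rig.e_img,
        "image_size": list(rig.image_size),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_calibration(path) -> StereoRig:
    """Read a rig from a JSON calibration file."""
    data = json.loads(Path(path).read_text())
    return StereoRig(
        P_left=np.array(data["p_left"]),
        P_right=np.array(data["p_right"]),
        H_left=np.array(data.get("h_left", np.eye(3).tolist())),
        H_right=np.array(data.get("h_right", np.eye(3).tolist())),
        d=data.get("working_distance_m", 2.0),
        alpha=data["alpha_deg"],
        b=data["baseline_m"],
        m=data["mm_per_px"],
        e_img=data.get("e_img_px", 1.0),
        image_size=tuple(data["image_size"]),
    )
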