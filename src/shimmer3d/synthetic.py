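"""Ground-truthed synthetic bee-curtain scenes with propagating waves.

The generator emulates the statistical structure the pipeline assumes: a
gently domed curtain of ellipse-shaped agents (head up, abdomen down, body
~65 px long at 0.3 mm/px, side-to-side spacing ~12.67 mm with jitter), a
wave front crossing the surface at constant speed, per-agent participation
strengths drawn approximately Gaussian with a non-participant fraction, and
biphasic torsion-pendulum flip kinematics: the thorax first moves ~1 mm
towards the comb over 100 ms while the abdomen rises, then is pushed away
from the comb at ~6x the phase-1 velocity, relaxing back with a ~2.5 s time
constant.  Non-participants move passively through an isotropic exponential
coupling kernel driven by their neighbours' active motion.

Every scene carries exact ground truth: per-agent 3D positions, projections
in both views (consistent with the rig to machine precision before
rendering noise), flip angles, front-crossing frames and participation
strengths.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import _sprites
from .calibration import StereoRig, make_parallel_rig, save_calibration


@dataclass
class CurtainConfig:
    field_width_mm: float = 700.0
    field_height_mm: float = 500.0
    spacing_mm: float = 12.67  # grid pitch, both axes (side-to-side distance)
    jitter_mm: float = 0.9  # positional jitter s.d. in x and y
    z_jitter_mm: float = 0.5
    orientation_sd_deg: float = 5.0
    orientation_max_deg: float = 11.5  # quiescent-curtain orientation limit
    body_length_mm: float = 19.69  # 65.63 px at 0.3 mm/px
    body_length_sd_mm: float = 0.5
    body_length_max_dev: float = 0.12  # clip, keeps scales inside the bank span
    dome_amp_mm: float = 10.0  # curtain surface bulge towards the cameras


@dataclass
class CurtainModel:
    positions: np.ndarray  # (n, 3) rest positions, mm
    orientation: np.ndarray  # (n,) degrees, 0 = head up
    body_length_mm: np.ndarray  # (n,)
    config: CurtainConfig
    seed: int

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class WaveSpec:
    """One wave front: a line sweeping the curtain at constant speed."""

    start_frame: int = 0
    speed_mm_s: float = 500.0
    direction: tuple[float, float] = (-1.0, 0.0)  # propagation, default right->left
    participant_fraction: float = 0.8
    strength_mean: float = 0.55
    strength_sd: float = 0.15
    strength_min: float = 0.05
    strength_corr_mm: float = 25.0  # spatial correlation length of participation

    def __post_init__(self) -> None:
        if self.speed_mm_s <= 0:
            raise ValueError("wave speed must be positive")
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("wave direction must be non-zero")
        self.direction = tuple(d / n)


@dataclass
class FlipKinematics:
    """Biphasic thorax kinematics of an abdomen flip, scaled by strength."""

    dz_toward_mm: float = 1.0  # phase-1 displacement towards the comb
    phase1_ms: float = 100.0
    velocity_ratio: float = 6.0  # phase-2 / phase-1 mean thorax speed
    z_peak_mm: float = 1.0  # overshoot away from the comb
    y_lift_mm: float = 0.5  # upward thorax lift (free parameter)
    y_tau_s: float = 0.5
    x_coupling: float = 0.3  # x follows z (shear towards the oncoming wave)
    flip_max_deg: float = 90.0
    flip_ms: float = 200.0  # full up-and-down flip: 12 frames at 60 Hz
    tau_s: float = 2.5  # residual curtain relaxation time constant
    passive_amp: float = 0.15  # curtain coupling gain
    passive_scale_mm: float = 15.0  # exponential kernel length


@dataclass
class GroundTruth:
    times: np.ndarray  # (F,) seconds
    positions: np.ndarray  # (F, n, 3) mm
    flip_deg: np.ndarray  # (F, n)
    strengths: np.ndarray  # (n_waves, n) participation strength in [0, 1]
    arrival_frame: np.ndarray  # (n_waves, n) front-crossing frame (float)
    proj_left: np.ndarray | None = None  # (F, n, 2) px
    proj_right: np.ndarray | None = None
    curtain: CurtainModel | None = None
    fps: float = 60.0

    @property
    def n_frames(self) -> int:
        return len(self.times)


def build_curtain(config: CurtainConfig | None = None, seed: int = 0) -> CurtainModel:
    """Jittered grid of agents on a gently curved surface; reproducible."""
    if config is None:
        config = CurtainConfig()
    rng = np.random.default_rng(seed)
    w, h, s = config.field_width_mm, config.field_height_mm, config.spacing_mm
    if s <= 0 or w <= 0 or h <= 0:
        raise ValueError("field dimensions and spacing must be positive")
    n_cols = max(int(w // s), 1)
    n_rows = max(int(h // s), 1)
    xs = (np.arange(n_cols) - (n_cols - 1) / 2.0) * s
    ys = (np.arange(n_rows) - (n_rows - 1) / 2.0) * s
    gx, gy = np.meshgrid(xs, ys)
    x = gx.ravel() + rng.normal(0.0, config.jitter_mm, gx.size)
    y = gy.ravel() + rng.normal(0.0, config.jitter_mm, gy.size)
    rx, ry = max(w / 2.0, 1e-9), max(h / 2.0, 1e-9)
    z = config.dome_amp_mm * np.clip(1.0 - (gx.ravel() / rx) ** 2 - (gy.ravel() / ry) ** 2, 0.0, None)
    z = z + rng.normal(0.0, config.z_jitter_mm, gx.size)
    ori = rng.normal(0.0, config.orientation_sd_deg, gx.size)
    ori = np.clip(ori, -config.orientation_max_deg, config.orientation_max_deg)
    L = rng.normal(config.body_length_mm, config.body_length_sd_mm, gx.size)
    dev = config.body_length_max_dev * config.body_length_mm
    L = np.clip(L, config.body_length_mm - dev, config.body_length_mm + dev)
    return CurtainModel(np.column_stack([x, y, z]), ori, L, config, seed)


def _correlated_field(xy: np.ndarray, corr_mm: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field with ~``corr_mm`` correlation length."""
    z = rng.standard_normal(len(xy))
    if corr_mm <= 0:
        return z
    d2 = ((xy[None, :, :] - xy[:, None, :]) ** 2).sum(-1)
    G = np.exp(-d2 / (2.0 * corr_mm**2))
    denom = np.sqrt((G**2).sum(axis=1))
    return (G @ z) / np.maximum(denom, 1e-12)


def _active_profiles(t_rel: np.ndarray, strengths: np.ndarray, kin: FlipKinematics):
    """Vectorized biphasic kinematics.

    t_rel: (F, n) time since front crossing (s); strengths: (n,).
    Returns dz, dy, dx, flip_deg arrays of shape (F, n); zero where the
    agent does not participate or the front has not yet arrived.
    """
    s = strengths[None, :]
    T1 = kin.phase1_ms / 1000.0
    v1 = kin.dz_toward_mm / T1  # mean phase-1 speed at full strength
    T2 = (kin.dz_toward_mm + kin.z_peak_mm) / (kin.velocity_ratio * v1)
    t = t_rel
    dz = np.zeros_like(t)
    phase1 = (t >= 0) & (t < T1)
    dz = np.where(
        phase1, -kin.dz_toward_mm * s * np.sin(np.pi * t / (2 * T1)) ** 2, dz
    )
    phase2 = (t >= T1) & (t < T1 + T2)
    ramp = np.sin(np.pi * (t - T1) / (2 * T2)) ** 2
    dz = np.where(
        phase2, s * (-kin.dz_toward_mm + (kin.dz_toward_mm + kin.z_peak_mm) * ramp), dz
    )
    phase3 = t >= T1 + T2
    dz = np.where(phase3, kin.z_peak_mm * s * np.exp(-(t - T1 - T2) / kin.tau_s), dz)

    dy = np.zeros_like(t)
    rise = (t >= 0) & (t < T1)
    dy = np.where(rise, kin.y_lift_mm * s * np.sin(np.pi * t / (2 * T1)) ** 2, dy)
    dy = np.where(t >= T1, kin.y_lift_mm * s * np.exp(-(t - T1) / kin.y_tau_s), dy)

    dx = kin.x_coupling * dz

    # abdomen elevation: up within the first half (100 ms), down within the
    # second; angular velocity is largest at onset, as in a whip-like thrust
    Tf = kin.flip_ms / 1000.0
    flip = np.where(
        (t >= 0) & (t <= Tf),
        kin.flip_max_deg * s * np.abs(np.sin(np.pi * t / Tf)),
        0.0,
    )
    inactive = s <= 0
    for a in (dz, dy, dx, flip):
        a[np.broadcast_to(inactive, a.shape)] = 0.0
    return dz, dy, dx, flip


def simulate_wave(
    curtain: CurtainModel,
    waves: WaveSpec | list[WaveSpec],
    kin: FlipKinematics | None = None,
    fps: float = 60.0,
    n_frames: int = 300,
    seed: int = 0,
    rig: StereoRig | None = None,
) -> GroundTruth:
    """Ground-truth trajectories for waves crossing the curtain.

    Each participating agent's flip starts when the front crosses it;
    non-participants and not-yet-reached neighbours receive attenuated
    passive motion through the spatial coupling kernel, so motion can lead
    the local front arrival.
    """
    if isinstance(waves, WaveSpec):
        waves = [waves]
    if kin is None:
        kin = FlipKinematics()
    rng = np.random.default_rng(seed)
    n = len(curtain)
    pos0 = curtain.positions
    times = np.arange(n_frames) / fps

    # coupling kernel (row-normalised, zero diagonal)
    dists = np.linalg.norm(pos0[None, :, :2] - pos0[:, None, :2], axis=-1)
    W = np.exp(-dists / kin.passive_scale_mm)
    np.fill_diagonal(W, 0.0)
    W = W / np.maximum(W.sum(axis=1, keepdims=True), 1e-12)

    disp = np.zeros((n_frames, n, 3))
    flip_deg = np.zeros((n_frames, n))
    strengths = np.zeros((len(waves), n))
    arrival_frame = np.zeros((len(waves), n))
    for w_idx, wave in enumerate(waves):
        u = np.asarray(wave.direction)
        c = pos0[:, :2] @ u
        t_arr = wave.start_frame / fps + (c - c.min()) / wave.speed_mm_s
        arrival_frame[w_idx] = t_arr * fps
        # participation strength as a spatially correlated Gaussian field:
        # neighbouring agents respond with similar strength (locally
        # synchronized participation), and non-participants form patches
        s_field = _correlated_field(pos0[:, :2], wave.strength_corr_mm, rng)
        s = np.clip(
            wave.strength_mean + wave.strength_sd * s_field, wave.strength_min, 1.0
        )
        if wave.participant_fraction <= 0:
            s[:] = 0.0
        elif wave.participant_fraction < 1:
            p_field = _correlated_field(pos0[:, :2], wave.strength_corr_mm, rng)
            cut = np.quantile(p_field, 1.0 - wave.participant_fraction)
            s[p_field < cut] = 0.0
        strengths[w_idx] = s
        t_rel = times[:, None] - t_arr[None, :]
        dz, dy, dx, flip = _active_profiles(t_rel, s, kin)
        # passive curtain motion: kernel-weighted neighbour activity
        dz_pass = kin.passive_amp * dz @ W.T
        dy_pass = kin.passive_amp * dy @ W.T
        disp[:, :, 0] += dx
        disp[:, :, 1] += dy + dy_pass
        disp[:, :, 2] += dz + dz_pass
        flip_deg = np.maximum(flip_deg, flip)

    positions = pos0[None, :, :] + disp
    proj_l = proj_r = None
    if rig is not None:
        rect = rig.rectified()
        flat = positions.reshape(-1, 3)
        proj_l = rect.project(flat, "left").reshape(n_frames, n, 2)
        proj_r = rect.project(flat, "right").reshape(n_frames, n, 2)
    return GroundTruth(
        times=times,
        positions=positions,
        flip_deg=flip_deg,
        strengths=strengths,
        arrival_frame=arrival_frame,
        proj_left=proj_l,
        proj_right=proj_r,
        curtain=curtain,
        fps=fps,
    )


def render_stereo_frame(
    truth: GroundTruth,
    frame: int,
    rig: StereoRig,
    noise_sd: float = 3.0,
    seed: int | np.random.Generator = 0,
    background: float = 20.0,
):
    """Render one 8-bit grayscale stereo pair from ground truth.

    Agents are drawn far-to-near as thorax + abdomen ellipses at their
    projected positions; the projected abdomen length is foreshortened by
    cos(flip angle).  Additive Gaussian noise is clipped to [0, 255].
    """
    if truth.proj_left is None or truth.proj_right is None:
        raise ValueError("ground truth has no projections; simulate with a rig")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = rig.image_size
    d_mm = rig.d * 1000.0
    f_px = d_mm / rig.m
    order = np.argsort(truth.positions[frame, :, 2])  # far first
    out = []
    for view, proj in (("left", truth.proj_left), ("right", truth.proj_right)):
        canvas = np.full((h, w), float(background))
        for i in order:
            uv = proj[frame, i]
            z = truth.positions[frame, i, 2]
            length_px = truth.curtain.body_length_mm[i] * f_px / max(d_mm - z, 1e-6)
            _sprites.draw_bee(
                canvas,
                (uv[0], uv[1]),
                truth.curtain.orientation[i],
                length_px,
                truth.flip_deg[frame, i],
            )
        canvas = canvas + rng.normal(0.0, noise_sd, canvas.shape)
        out.append(np.clip(canvas, 0, 255).astype(np.uint8))
    return out[0], out[1]


@dataclass
class SceneConfig:
    """Full recording emulation: 60 Hz, 900 frames, 0.3 mm/px by default."""

    n_frames: int = 900
    fps: float = 60.0
    mm_per_px: float = 0.3
    alpha_deg: float = 30.0
    working_distance_m: float = 2.0
    image_size: tuple[int, int] = (1728, 2352)
    curtain: CurtainConfig = field(default_factory=CurtainConfig)
    waves: list[WaveSpec] = field(
        default_factory=lambda: [WaveSpec(start_frame=120), WaveSpec(start_frame=520)]
    )
    kinematics: FlipKinematics = field(default_factory=FlipKinematics)
    noise_sd: float = 3.0
    background: float = 20.0
    seed: int = 0


def make_rig(cfg: SceneConfig) -> StereoRig:
    return make_parallel_rig(
        alpha=cfg.alpha_deg,
        d=cfg.working_distance_m,
        m=cfg.mm_per_px,
        image_size=cfg.image_size,
    )


def make_scene(cfg: SceneConfig):
    """In-memory scene: (frames_left, frames_right, rig, truth)."""
    rig = make_rig(cfg)
    curtain = build_curtain(cfg.curtain, seed=cfg.seed)
    truth = simulate_wave(
        curtain,
        cfg.waves,
        cfg.kinematics,
        fps=cfg.fps,
        n_frames=cfg.n_frames,
        seed=cfg.seed + 1,
        rig=rig,
    )
    rng = np.random.default_rng(cfg.seed + 2)
    frames_l, frames_r = [], []
    for f in range(cfg.n_frames):
        img_l, img_r = render_stereo_frame(
            truth, f, rig, cfg.noise_sd, rng, cfg.background
        )
        frames_l.append(img_l)
        frames_r.append(img_r)
    return frames_l, frames_r, rig, truth


def _truth_tables(truth: GroundTruth):
    import pandas as pd

    F, n = truth.positions.shape[:2]
    frames = np.repeat(np.arange(F), n)
    agents = np.tile(np.arange(n), F)
    pos = truth.positions.reshape(-1, 3)
    positions = pd.DataFrame(
        {
            "frame": frames,
            "agent": agents,
            "x_mm": pos[:, 0],
            "y_mm": pos[:, 1],
            "z_mm": pos[:, 2],
            "u_left": truth.proj_left.reshape(-1, 2)[:, 0],
            "v_left": truth.proj_left.reshape(-1, 2)[:, 1],
            "u_right": truth.proj_right.reshape(-1, 2)[:, 0],
            "v_right": truth.proj_right.reshape(-1, 2)[:, 1],
            "flip_deg": truth.flip_deg.reshape(-1),
        }
    )
    rows = []
    for w in range(truth.strengths.shape[0]):
        for a in range(n):
            rows.append((w, a, truth.arrival_frame[w, a], truth.strengths[w, a]))
    events = pd.DataFrame(rows, columns=["wave", "agent", "arrival_frame", "strength"])
    return positions, events


def generate_dataset(cfg: SceneConfig, out_dir, write_frames: bool = True) -> Path:
    """Write a scene to disk in the layout the pipeline reader expects.

    out/left/NNNNNN.png, out/right/NNNNNN.png, calib.json,
    truth_positions.csv, truth_events.csv, manifest.json.  With
    ``write_frames=False`` only the ground-truth tables are written.
    """
    out = Path(out_dir)
    (out / "left").mkdir(parents=True, exist_ok=True)
    (out / "right").mkdir(parents=True, exist_ok=True)
    rig = make_rig(cfg)
    save_calibration(rig, out / "calib.json")
    curtain = build_curtain(cfg.curtain, seed=cfg.seed)
    truth = simulate_wave(
        curtain,
        cfg.waves,
        cfg.kinematics,
        fps=cfg.fps,
        n_frames=cfg.n_frames,
        seed=cfg.seed + 1,
        rig=rig,
    )
    n_frames = cfg.n_frames if write_frames else 0
    rng = np.random.default_rng(cfg.seed + 2)
    hasher = hashlib.sha256()
    for f in range(n_frames):
        img_l, img_r = render_stereo_frame(truth, f, rig, cfg.noise_sd, rng, cfg.background)
        for view, img in (("left", img_l), ("right", img_r)):
            path = out / view / f"{f:06d}.png"
            iio.imwrite(path, img)
            hasher.update(img.tobytes())
    positions, events = _truth_tables(truth)
    positions.to_csv(out / "truth_positions.csv", index=False)
    events.to_csv(out / "truth_events.csv", index=False)
    manifest = {
        "seed": cfg.seed,
        "n_frames": cfg.n_frames,
        "frames_written": n_frames,
        "fps": cfg.fps,
        "mm_per_px": cfg.mm_per_px,
        "image_size": list(cfg.image_size),
        "n_agents": len(truth.curtain),
        "waves": [asdict(w) for w in cfg.waves],
        "kinematics": asdict(cfg.kinematics),
        "curtain": asdict(cfg.curtain),
        "noise_sd": cfg.noise_sd,
        "frame_checksum": hasher.hexdigest(),
        "free_parameters": {"y_lift_mm": cfg.kinematics.y_lift_mm},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def reduced_scene_config(seed: int = 0) -> SceneConfig:
    """Desk-scale default: ~200 agents, 300 frames, two waves.

    Same spacing, kinematics, magnification and frame rate as the full
    recording; only the field of view and duration are reduced.
    """
    curtain = CurtainConfig(field_width_mm=190.0, field_height_mm=170.0)
    h = int(round((curtain.field_height_mm + 30.0) / 0.3))
    w = int(round((curtain.field_width_mm + 30.0) / 0.3))
    return SceneConfig(
        n_frames=300,
        image_size=(h, w),
        curtain=curtain,
        waves=[WaveSpec(start_frame=45), WaveSpec(start_frame=170)],
        seed=seed,
    )
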