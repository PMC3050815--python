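"""Shared fixtures: small rigs, rendered scenes, and the full recovery run."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import cKDTree

import shimmer3d as sh
from shimmer3d.config import PipelineConfig
from shimmer3d.synthetic import CurtainConfig, SceneConfig, WaveSpec


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_rig():
    """Paper-configuration rig (alpha=30, m=0.3) with a small sensor."""
    return sh.make_parallel_rig(image_size=(600, 700))


def _map_tracks_to_truth(tracks, truth):
    """agent_id -> ground-truth agent index, via start-frame projections."""
    trees = {}
    mapping = {}
    for tr in tracks:
        f0 = tr.start_frame
        if f0 not in trees:
            trees[f0] = cKDTree(truth.proj_left[f0])
        d, gi = trees[f0].query(tr.pos_l[0])
        if d <= 4.0:
            mapping[tr.agent_id] = int(gi)
    return mapping


@pytest.fixture(scope="session")
def wave_scene():
    """Reduced default scene (two waves, ~180 agents, 300 frames) with the
    full pipeline run and track-to-truth correspondence.  Built once; this
    is the substrate of the parameter-recovery checks."""
    cfg = sh.reduced_scene_config(seed=0)
    frames_l, frames_r, rig, truth = sh.make_scene(cfg)
    res = sh.run_pipeline_arrays(frames_l, frames_r, rig)
    mapping = _map_tracks_to_truth(res.tracks, truth)
    by_id = {tr.agent_id: tr for tr in res.tracks}
    event_rows = []
    for ev in res.events:
        gi = mapping.get(ev.agent_id)
        if gi is None:
            continue
        arr_abs = ev.arrival + 1
        w = int(np.argmin(np.abs(truth.arrival_frame[:, gi] - arr_abs)))
        event_rows.append(
            {
                "agent_id": ev.agent_id,
                "truth_index": gi,
                "wave": w,
                "arrival": arr_abs,
                "true_arrival": float(truth.arrival_frame[w, gi]),
                "amp_deg": float(truth.strengths[w, gi] * 90.0),
                "rs": ev.rs,
                "rrs": ev.rrs,
            }
        )
    return {
        "config": cfg,
        "frames_l": frames_l,
        "frames_r": frames_r,
        "rig": rig,
        "truth": truth,
        "result": res,
        "mapping": mapping,
        "by_id": by_id,
        "events": event_rows,
        "pipeline_config": PipelineConfig(),
    }


@pytest.fixture(scope="session")
def flip_fixture():
    """Single full-strength flipping bee with fast-decaying residuals, so the
    motion is time-symmetric within the clip; used for drift checks."""
    curtain_cfg = CurtainConfig(
        field_width_mm=10, field_height_mm=10, jitter_mm=0, z_jitter_mm=0, dome_amp_mm=0
    )
    kin = sh.FlipKinematics(tau_s=0.12, y_tau_s=0.12)
    scene_cfg = SceneConfig(
        n_frames=46,
        image_size=(240, 240),
        curtain=curtain_cfg,
        waves=[
            WaveSpec(
                start_frame=10,
                participant_fraction=1.0,
                strength_mean=1.0,
                strength_sd=0.0,
                strength_min=1.0,
            )
        ],
        kinematics=kin,
        seed=0,
        noise_sd=2.0,
    )
    curtain = sh.build_curtain(curtain_cfg, 0)
    rig = sh.synthetic.make_rig(scene_cfg)
    truth = sh.simulate_wave(curtain, scene_cfg.waves, kin, n_frames=46, seed=1, rig=rig)
    rng = np.random.default_rng(5)
    frames = [
        sh.render_stereo_frame(truth, f, rig, scene_cfg.noise_sd, rng)[0]
        for f in range(46)
    ]
    return frames, truth, rig
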