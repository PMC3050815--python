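# shimmer3d

Stereoscopic 3D motion analysis of densely packed agent clusters, built for
the *shimmering* defence waves of Giant honeybees (*Apis dorsata*).  Surface
bees of the nest's "bee curtain" flip their abdomens upward in rapid
succession, producing Mexican-wave-like patterns; understanding who
participates, how strongly, and what moves passively requires millimetre-
scale 3D trajectories of hundreds of near-identical individuals at once.

The package implements the full measurement chain for frame-locked,
rectified stereo video of a nest surface:

1. **Segmentation** — each bee is found by normalized cross-correlation
   (NCC) against a bank of rotated (±11.5°) and scaled (±13.7%) bee
   templates, with non-maximum suppression in a 20 px radius.
2. **Stereo matching** — left/right detections are paired one-to-one by
   discrete energy minimization, E(d) = E_data(d) + λ·E_smooth(d), solved
   exactly as a minimum s-t cut on a layered graph of disparity slots.
3. **Tracking** — each thorax is followed with a 20×20 px NCC template over
   a 40×40 px search region; a memory of the 15 preceding templates
   exploits the time symmetry of the abdominal flip so tracks do not drift.
   Left and right tracks are fused onto their mean image row.
4. **Triangulation** — fused correspondences are lifted to metric 3D by the
   least-squares null-space solution of the stacked cross-product system
   [t_left]×P_left · T = 0, [t_right]×P_right · T = 0.  For the field
   configuration (stereo angle α = 30°, magnification m = 0.3 mm/px) the
   expected depth error is e_z = m·e_img·cos(α/2)/sin(α) ≈ 0.6 mm.
5. **Wave detection** — the arrival of a wave at an agent is read from the
   mean absolute frame difference over a 60×60 px sensor region (sROI)
   around the thorax: time zero is two frames before the series exceeds
   ΔL_th = 10 in three successive frames; the subsequent maximum is the
   response strength RS, normalized population-wide to rRS.
6. **Episodes** — 90-frame windows (30 pre + 60 post at 60 Hz) around each
   arrival are offset-corrected (mean of the first six pre-frames
   subtracted), classified into ten rRS levels on [0.3, 0.8] grouped
   low/middle/high, and pooled into mean ± s.e.m. time courses of
   Δx, Δy, Δz.

A ground-truthed **synthetic bee-curtain simulator** (`shimmer3d.synthetic`)
renders stereo sequences of a jittered curtain of banded, two-ellipse bee
sprites with propagating wave fronts, approximately Gaussian participation
strengths and biphasic torsion-pendulum flip kinematics (~1 mm towards the
comb in 100 ms, then away at ~6× the velocity).  Every stage of the pipeline
is validated against this simulator's exact ground truth.

## Worked example

```python
import shimmer3d as sh

# a reduced two-wave scene: ~180 agents, 300 frames at 60 Hz, 0.3 mm/px
cfg = sh.reduced_scene_config(seed=0)
frames_l, frames_r, rig, truth = sh.make_scene(cfg)

result = sh.run_pipeline_arrays(frames_l, frames_r, rig)
print(result.summary)
high = result.pooled["high"]
dz = high.mean["dz"]
post = high.rel_frames >= 0
print(f"high-RS pooled dz: dip {dz[post][:9].min():+.2f} mm, "
      f"peak {dz[post].max():+.2f} mm over {high.n} episodes")
```

prints

```
{'n_detections_left': 182, 'n_detections_right': 182, 'n_correspondences': 174,
 'n_tracks': 174, 'n_events': 214, 'n_episodes': 214, 'n_full_episodes': 214}
high-RS pooled dz: dip -0.44 mm, peak +1.19 mm over 49 episodes
```

i.e. 182 agents detected per view, 174 stereo-matched and tracked, 214 wave
episodes cut; the pooled strongly-responding group shows the biphasic
thorax motion — a ~0.4 mm transient towards the comb followed by a ~1.2 mm
push away from it — that distinguishes active abdominal flipping from
passive curtain motion.

The same pipeline runs from the command line over directories of numbered
PNG frames plus a JSON calibration file:

```bash
shimmer3d simulate --out scene --seed 0
shimmer3d run --left scene/left --right scene/right \
              --calib scene/calib.json --out results
```

Every stage writes a CSV (`detections.csv`, `correspondences.csv`,
`tracks.csv`, `events.csv`, `episodes.csv`, `pooled_<group>.csv`) plus a
`summary.json` with per-stage counts and the effective configuration hash.

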