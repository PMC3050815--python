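"""Frame-difference wave-arrival detection and response strength."""

import numpy as np
import pytest

import shimmer3d as sh
from shimmer3d.synthetic import CurtainConfig, SceneConfig, WaveSpec
from shimmer3d.waves import (
    LuminanceSeries,
    detect_arrival,
    detect_events,
    difference_image,
    global_activity,
    normalize_rrs,
    response_strength,
    sroi_series,
)


class TestDifferenceImage:
    def test_identical_frames_zero(self, rng):
        f = (rng.random((30, 30)) * 255).astype(np.uint8)
        assert not difference_image(f, f).any()

    def test_uniform_offset(self, rng):
        f = rng.integers(0, 200, (30, 30)).astype(np.uint8)
        assert np.all(difference_image(f, f + 10) == 10)

    def test_matches_per_pixel_loop(self, rng):
        a = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        b = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        expected = np.array(
            [[abs(int(a[i, j]) - int(b[i, j])) for j in range(16)] for i in range(16)]
        )
        assert np.array_equal(difference_image(a, b), expected)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            difference_image(np.zeros((4, 4)), np.zeros((4, 5)))


class TestSroiSeries:
    def test_zero_diffs_zero_series(self):
        diffs = [np.zeros((100, 100))] * 5
        s = sroi_series(diffs, [(50, 50)] * 5)
        assert not s.values.any()
        assert len(s.values) == 5

    def test_saturated_sroi(self):
        diff = np.zeros((200, 200))
        diff[70:130, 70:130] = 255.0
        s = sroi_series([diff], [(100, 100)])
        assert s.values[0] == pytest.approx(255.0)

    def test_window_is_3600_px(self):
        # one bright pixel inside a full 60 px window averages over 3600 px
        diff = np.zeros((200, 200))
        diff[100, 100] = 3600.0
        s = sroi_series([diff], [(100, 100)], sroi_px=60)
        assert s.values[0] == pytest.approx(1.0)

    def test_window_follows_moving_track(self):
        diffs = []
        track = []
        for k in range(4):
            d = np.zeros((200, 200))
            u = 40 + 30 * k
            d[95:105, u - 5 : u + 5] = 36.0
            diffs.append(d)
            track.append((u, 100))
        s = sroi_series(diffs, track)
        assert np.all(s.values == s.values[0])


class TestDetectArrival:
    def test_noise_level_series_has_no_arrival(self):
        # dL <= 5 is the "motionless" state; constant 4 never triggers
        assert detect_arrival(np.full(60, 4.0)) is None

    def test_hand_traced_rule(self):
        series = np.zeros(40)
        series[20:] = (12, 13, 15) + (20,) * 17
        assert detect_arrival(series) == 18

    def test_two_frame_run_is_too_short(self):
        series = np.zeros(30)
        series[10:12] = 50.0
        assert detect_arrival(series, n_consecutive=3) is None

    def test_lead_clipped_at_zero(self):
        series = np.full(10, 20.0)
        assert detect_arrival(series) == 0


class TestResponseStrength:
    def test_peak_inside_window(self):
        series = np.zeros(40)
        series[12] = 80.0
        assert response_strength(series, 10, 12) == 80.0

    def test_monotone_rise_truncated_at_window_end(self):
        series = np.arange(40, dtype=float)
        assert response_strength(series, 10, 12) == 22.0

    def test_rs_strictly_increasing_in_flip_amplitude(self):
        """Isolated agents flipping at 30/60/90 degrees produce strictly
        increasing sROI response strengths."""
        rs = []
        for amp in (30.0, 60.0, 90.0):
            s = amp / 90.0
            curtain_cfg = CurtainConfig(
                field_width_mm=10, field_height_mm=10, jitter_mm=0, z_jitter_mm=0, dome_amp_mm=0
            )
            cfg = SceneConfig(
                n_frames=30,
                image_size=(200, 200),
                curtain=curtain_cfg,
                waves=[
                    WaveSpec(
                        start_frame=8,
                        participant_fraction=1.0,
                        strength_mean=s,
                        strength_sd=0.0,
                        strength_min=s,
                    )
                ],
                seed=0,
                noise_sd=2.0,
            )
            frames_l, _, rig, truth = sh.make_scene(cfg)
            diffs = [
                difference_image(frames_l[i], frames_l[i + 1]) for i in range(29)
            ]
            track = [tuple(truth.proj_left[i + 1, 0]) for i in range(29)]
            series = sroi_series(diffs, track)
            rs.append(response_strength(series, 8, 12))
        assert rs[0] < rs[1] < rs[2]


class TestEventsAndNormalization:
    def test_single_event_rrs_one(self):
        s = LuminanceSeries(0, np.concatenate([np.zeros(10), np.full(6, 30.0), np.zeros(20)]))
        events = normalize_rrs(detect_events(s))
        assert len(events) == 1
        assert events[0].rrs == 1.0

    def test_rrs_is_ratio_to_population_max(self):
        s1 = LuminanceSeries(0, np.concatenate([np.zeros(5), np.full(5, 50.0), np.zeros(20)]))
        s2 = LuminanceSeries(1, np.concatenate([np.zeros(5), np.full(5, 100.0), np.zeros(20)]))
        events = normalize_rrs(detect_events(s1) + detect_events(s2))
        assert sorted(e.rrs for e in events) == [0.5, 1.0]

    def test_rrs_invariant_under_uniform_rescaling(self):
        vals = np.concatenate([np.zeros(5), np.full(5, 40.0), np.zeros(20)])
        e1 = normalize_rrs(detect_events(LuminanceSeries(0, vals)))
        e2 = normalize_rrs(detect_events(LuminanceSeries(0, 2 * vals)))
        assert e1[0].rrs == e2[0].rrs == 1.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            normalize_rrs([])

    def test_rearm_detects_second_wave(self):
        vals = np.zeros(100)
        vals[10:16] = 40.0
        vals[60:66] = 60.0
        events = detect_events(LuminanceSeries(7, vals))
        assert [e.wave_index for e in events] == [0, 1]
        assert events[0].arrival == 8
        assert events[1].arrival == 58


class TestGlobalActivity:
    def test_quiescent_scene_near_zero(self, rng):
        diffs = [np.abs(rng.normal(0, 3, (120, 120))) for _ in range(10)]
        positions = [[(60, 60), (30, 30)]] * 10
        act = global_activity(diffs, positions)
        assert np.all(act <= 0.5)
        assert np.all((0 <= act) & (act <= 1))

    def test_wave_crossing_is_a_unimodal_pulse(self, wave_scene):
        """Global sROI activity rises and falls once per simulated wave."""
        act = wave_scene["result"].activity
        from scipy.ndimage import uniform_filter1d

        smooth = uniform_filter1d(act, 9)
        # two separated activity pulses, quiet before, between and after;
        # the peak fraction stays well below 1 because the front transit
        # (~0.4 s) is much longer than one agent's active phase (~0.2 s)
        assert smooth[40:80].max() > 0.15
        assert smooth[170:210].max() > 0.15
        assert smooth[145:165].max() < 0.05
        assert smooth[:30].max() < 0.05


def test_close_neighbour_false_positive_and_sroi_shrink_fix():
    """An inactive agent < 10 mm from flipping neighbours is falsely detected
    with the default 60 px sROI; shrinking the sROI removes the false
    positive."""
    curtain_cfg = CurtainConfig(
        field_width_mm=21,
        field_height_mm=7,  # three agents in one row, 7 mm apart
        spacing_mm=7.0,
        jitter_mm=0,
        z_jitter_mm=0,
        dome_amp_mm=0,
    )
    cfg = SceneConfig(
        n_frames=30,
        image_size=(260, 300),
        curtain=curtain_cfg,
        waves=[
            WaveSpec(
                start_frame=8,
                participant_fraction=1.0,
                strength_mean=1.0,
                strength_sd=0.0,
                strength_min=1.0,
            )
        ],
        seed=0,
        noise_sd=2.0,
    )
    curtain = sh.build_curtain(curtain_cfg, 0)
    assert len(curtain) == 3
    rig = sh.synthetic.make_rig(cfg)
    truth = sh.simulate_wave(curtain, cfg.waves, cfg.kinematics, n_frames=30, seed=1, rig=rig)
    # make the middle agent fully passive and refresh the projections
    focal = 1
    truth.strengths[0, focal] = 0.0
    truth.positions[:, focal, :] = curtain.positions[focal]
    truth.flip_deg[:, focal] = 0.0
    rect = rig.rectified()
    n_frames, n = truth.positions.shape[:2]
    flat = truth.positions.reshape(-1, 3)
    truth.proj_left = rect.project(flat, "left").reshape(n_frames, n, 2)
    truth.proj_right = rect.project(flat, "right").reshape(n_frames, n, 2)
    rng = np.random.default_rng(2)
    frames = [sh.render_stereo_frame(truth, f, rig, 2.0, rng)[0] for f in range(30)]
    diffs = [difference_image(frames[i], frames[i + 1]) for i in range(29)]
    track = [tuple(truth.proj_left[i + 1, focal]) for i in range(29)]
    wide = sroi_series(diffs, track, sroi_px=60, agent_id=focal)
    narrow = sroi_series(diffs, track, sroi_px=20, agent_id=focal)
    assert detect_arrival(wide.values) is not None  # contaminated
    assert detect_arrival(narrow.values) is None  # fixed by shrinking
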