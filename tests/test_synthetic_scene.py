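import numpy as np
import pytest

from droneval.detection_io import Treatment, clip_to_frame_range
from droneval.errors import ValidationError
from droneval.matcher import MatchConfig, match_sequence
from droneval.metrics_report import compute_metrics, iou_histogram
from droneval.stream_sync import estimate_offsets
from droneval.synthetic_scene import (
    AnimalModel,
    SimulationConfig,
    TreatmentDetectability,
    default_config,
    depth_series,
    fit_detection_curve,
    load_config,
    save_config,
    simulate_detection_outcomes,
    simulate_detections,
    simulate_flight,
    simulate_tracks,
)


def animal(**kwargs):
    defaults = dict(animal_id="a1", start_x=500.0, start_y=400.0, speed=2.0,
                    surface_duration=50, dive_duration=100, max_depth=6.0)
    defaults.update(kwargs)
    return AnimalModel(**defaults)


def detectability(treatment=Treatment.RGB, **kwargs):
    defaults = dict(d50=4.0, slope=0.5, jitter_sd=3.5, fp_rate=0.0, light_fraction=1.0)
    defaults.update(kwargs)
    return TreatmentDetectability(treatment=treatment, **defaults)


def sim_config(**kwargs):
    defaults = dict(
        n_frames=300,
        animals=(animal(),),
        detectability={Treatment.RGB: detectability()},
        camera_offsets={Treatment.RGB: 0},
        seed=7,
        frame_width=1200,
        frame_height=900,
        max_extension=0,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


ALWAYS_SEEN = dict(d50=1000.0, jitter_sd=0.0)  # p(depth) == 1 everywhere relevant


class TestDepthSeries:
    def test_surface_then_dive(self):
        a = animal(surface_duration=50, dive_duration=100)
        depth = depth_series(a, 300)
        assert np.all(depth[:50] == 0.0)
        assert depth[50 + 50] == pytest.approx(6.0)  # bottom of first dive
        assert np.all(depth >= 0.0) and depth.max() <= 6.0

    def test_zero_crossing_oracle(self):
        # dive 100, surface 50 -> cycle 150; 300 frames = exactly 2 full cycles
        depth = depth_series(animal(surface_duration=50, dive_duration=100), 300)
        submerged = depth > 0
        dive_starts = int(np.sum(submerged[1:] & ~submerged[:-1]) + submerged[0])
        assert dive_starts == 2

    def test_continuous_and_zero_at_surfacing(self):
        depth = depth_series(animal(), 450)
        steps = np.abs(np.diff(depth))
        assert steps.max() < 0.5  # no jumps at cycle boundaries
        # first frame after each dive is back at 0
        assert depth[150] == 0.0


class TestSimulateTracks:
    def test_static_limit(self):
        config = sim_config(animals=(animal(speed=0.0, surface_duration=300,
                                            dive_duration=1, heading=0.0),),
                            heading_noise_sd=0.0)
        tracks, _ = simulate_tracks(config)
        boxes = list(tracks[0].boxes_by_frame().values())
        assert len(boxes) == 300
        assert all(b == boxes[0] for b in boxes)

    def test_determinism(self):
        config = sim_config()
        t1, d1 = simulate_tracks(config)
        t2, d2 = simulate_tracks(config)
        assert t1 == t2
        assert all(np.array_equal(d1[k], d2[k]) for k in d1)

    def test_boxes_stay_inside_frame(self):
        config = sim_config(animals=(animal(start_x=10.0, start_y=10.0, speed=15.0),),
                            n_frames=500, max_extension=10)
        tracks, _ = simulate_tracks(config)
        for box in tracks[0].boxes_by_frame().values():
            assert box.x_min >= 0 and box.y_min >= 0
            assert box.x_max <= config.frame_width and box.y_max <= config.frame_height

    def test_keyframes_match_cutoff_conservation(self):
        config = sim_config(animals=(animal(), animal(animal_id="a2", start_x=800.0,
                                                      cycle_phase=75)))
        tracks, depths = simulate_tracks(config)
        cutoff = config.annotation_cutoff
        by_id = {t.animal_id: dict(t.keyframes) for t in tracks}
        for frame in range(config.n_frames):
            shallow = sum(1 for a in depths if depths[a][frame] < cutoff)
            keyframed = sum(1 for a in by_id if frame in by_id[a])
            assert keyframed == shallow

    def test_zero_animals_rejected(self):
        with pytest.raises(ValidationError):
            sim_config(animals=())

    def test_never_sightable_rejected(self):
        config = sim_config(
            n_frames=250,
            animals=(animal(surface_duration=1, dive_duration=299, max_depth=500.0,
                            cycle_phase=30),),
            detectability={Treatment.RGB: detectability(d50=0.001, slope=0.001)},
            annotation_margin=0.0,
        )
        with pytest.raises(ValidationError, match="cutoff"):
            simulate_tracks(config)


class TestSimulateDetections:
    def test_noise_free_limit_perfect_metrics(self):
        config = sim_config(detectability={Treatment.RGB: detectability(**ALWAYS_SEEN)})
        tracks, depths = simulate_tracks(config)
        from droneval.detection_io import tracks_to_detection_set
        gt = tracks_to_detection_set(tracks, flight_id="f", treatment=Treatment.RGB,
                                     frame_width=1200, frame_height=900)
        model = simulate_detections(tracks, depths,
                                    config.detectability[Treatment.RGB], seed=1,
                                    frame_width=1200, frame_height=900)
        model = clip_to_frame_range(model, gt.frame_range)
        counts, _ = match_sequence(gt, model)
        row = compute_metrics(counts, "f", Treatment.RGB)
        assert row.precision == 100.0 and row.recall == 100.0 and row.f1 == 100.0

    def test_zero_probability_empty(self):
        config = sim_config()
        tracks, depths = simulate_tracks(config)
        det = detectability(light_fraction=1e-9, d50=0.001, slope=0.001)
        model = simulate_detections(tracks, depths, det, seed=1,
                                    frame_width=1200, frame_height=900)
        assert len(model) == 0

    def test_determinism(self):
        config = sim_config()
        tracks, depths = simulate_tracks(config)
        det = config.detectability[Treatment.RGB]
        a = simulate_detections(tracks, depths, det, seed=5,
                                frame_width=1200, frame_height=900)
        b = simulate_detections(tracks, depths, det, seed=5,
                                frame_width=1200, frame_height=900)
        assert a == b

    def test_recall_monotone_in_d50_common_random_numbers(self):
        config = sim_config(n_frames=600)
        tracks, depths = simulate_tracks(config)
        recalls = []
        for d50 in (1.0, 2.0, 4.0, 8.0):
            outcomes = simulate_detection_outcomes(
                tracks, depths, detectability(d50=d50), seed=3)
            detected = [o[3] for o in outcomes]
            recalls.append(np.mean(detected))
        assert recalls == sorted(recalls)

    def test_clutter_rate(self):
        config = sim_config(n_frames=2000,
                            animals=(animal(surface_duration=2000, dive_duration=1),))
        tracks, depths = simulate_tracks(config)
        det = detectability(fp_rate=0.5, light_fraction=1e-9)
        model = simulate_detections(tracks, depths, det, seed=9,
                                    frame_width=1200, frame_height=900)
        # ~Poisson(0.5/frame) over 2000 frames
        assert 850 <= len(model) <= 1150

    def test_matched_iou_peak_near_calibrated_value(self):
        """Monte-Carlo oracle: jitter sd 3.5 px on a 60x25 box yields mean
        IoU ~0.74; the matched-IoU histogram peak must land within 0.05."""
        rng = np.random.default_rng(1)
        w, h, sd, n = 60.0, 25.0, 3.5, 10_000
        jitters = rng.normal(0, sd, (n, 4))
        x0 = jitters[:, 0]; y0 = jitters[:, 1]
        x1 = w + jitters[:, 2]; y1 = h + jitters[:, 3]
        iw = np.clip(np.minimum(x1, w) - np.maximum(x0, 0), 0, None)
        ih = np.clip(np.minimum(y1, h) - np.maximum(y0, 0), 0, None)
        inter = iw * ih
        union = w * h + np.clip(x1 - x0, 0, None) * np.clip(y1 - y0, 0, None) - inter
        oracle_mean = float(np.mean(inter / union))
        assert abs(oracle_mean - 0.74) <= 0.02

        config = sim_config(
            n_frames=2000,
            animals=(animal(surface_duration=2000, dive_duration=1,
                            body_width=60.0, body_height=25.0),),
            detectability={Treatment.RGB: detectability(d50=1000.0, jitter_sd=sd)},
            seed=1,
        )
        tracks, depths = simulate_tracks(config)
        from droneval.detection_io import tracks_to_detection_set
        gt = tracks_to_detection_set(tracks, flight_id="f", treatment=Treatment.RGB,
                                     frame_width=1200, frame_height=900)
        model = clip_to_frame_range(
            simulate_detections(tracks, depths,
                                config.detectability[Treatment.RGB], seed=1,
                                frame_width=1200, frame_height=900),
            gt.frame_range)
        counts, _ = match_sequence(gt, model, MatchConfig(iou_threshold=0.2))
        hist = iou_histogram(counts.matched_ious, bin_width=0.02)
        primary = hist.peaks[int(np.argmax([hist.counts[
            int(round((p - 0.01) / 0.02))] for p in hist.peaks]))]
        assert abs(primary - oracle_mean) <= 0.05


class TestSimulateFlight:
    def test_planted_offsets_recovered(self):
        config = sim_config(
            detectability={
                Treatment.RGB: detectability(),
                Treatment.GREEN: detectability(Treatment.GREEN, d50=2.5),
                Treatment.GREEN_POL: detectability(Treatment.GREEN_POL, d50=1.5),
            },
            camera_offsets={Treatment.RGB: 0, Treatment.GREEN: 1, Treatment.GREEN_POL: 0},
        )
        sim = simulate_flight(config)
        report = estimate_offsets(list(sim.anchors), "RGB")
        assert report.offset_by_camera == {"RGB": 0, "GREEN": 1, "GREEN_POL": 0}
        assert report.passed

    def test_identical_treatments_identical_streams(self):
        det_kwargs = dict(d50=4.0, slope=0.5, jitter_sd=2.0, fp_rate=0.1,
                          light_fraction=1.0)
        config = sim_config(
            detectability={
                t: TreatmentDetectability(treatment=t, **det_kwargs) for t in Treatment
            },
            camera_offsets={t: 0 for t in Treatment},
        )
        sim = simulate_flight(config)
        # force the same derived seed to exercise the symmetry contract
        from droneval.synthetic_scene import simulate_detections as sd
        streams = {
            t: sd(sim.tracks, sim.depths, config.detectability[t], seed=123,
                  frame_width=config.frame_width, frame_height=config.frame_height,
                  n_frames=config.n_frames)
            for t in Treatment
        }
        boxes = {t: [d.box for d in s.detections] for t, s in streams.items()}
        assert boxes[Treatment.RGB] == boxes[Treatment.GREEN] == boxes[Treatment.GREEN_POL]

    def test_determinism_byte_identical(self, tmp_path):
        from droneval.detection_io import write_detections
        config = sim_config()
        for name in ("a", "b"):
            sim = simulate_flight(config)
            write_detections(sim.model_sets[Treatment.RGB], tmp_path / f"{name}.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_shared_ground_truth(self):
        config = sim_config(detectability={
            Treatment.RGB: detectability(),
            Treatment.GREEN: detectability(Treatment.GREEN, d50=2.5),
        })
        sim = simulate_flight(config)
        assert len(sim.model_sets) == 2
        assert len(sim.ground_truth) > 0


class TestParameterRecovery:
    def test_d50_recovered_within_10pct(self):
        true_d50, true_slope = 3.0, 0.5
        config = sim_config(
            n_frames=5000,
            animals=(animal(surface_duration=40, dive_duration=160, max_depth=6.0),),
            detectability={Treatment.RGB: detectability(d50=true_d50, slope=true_slope)},
            annotation_margin=10.0,  # annotate the full dive so deep frames are trials
            seed=11,
        )
        tracks, depths = simulate_tracks(config)
        outcomes = simulate_detection_outcomes(
            tracks, depths, config.detectability[Treatment.RGB], seed=11)
        d = np.array([o[2] for o in outcomes])
        detected = np.array([o[3] for o in outcomes])
        d50_hat, slope_hat = fit_detection_curve(d, detected)
        assert abs(d50_hat - true_d50) / true_d50 <= 0.10
        assert slope_hat > 0


class TestOverlapBimodality:
    def test_two_close_animals_secondary_mode(self):
        # a1 and a2 swim 29 px apart (< one body length); the static isolated
        # animals give the same-animal ~0.74 peak more mass than the
        # cross-animal ~0.35 one (5 own pairs vs 2 cross pairs per frame)
        pair = dict(speed=0.5, heading=0.5, surface_duration=400, dive_duration=1,
                    body_width=60.0, body_height=25.0)
        solo = dict(pair, speed=0.0)
        config = sim_config(
            n_frames=400,
            animals=(animal(animal_id="a1", start_x=500.0, start_y=400.0, **pair),
                     animal(animal_id="a2", start_x=529.0, start_y=400.0, **pair),
                     animal(animal_id="a3", start_x=1000.0, start_y=700.0, **solo),
                     animal(animal_id="a4", start_x=200.0, start_y=700.0, **solo),
                     animal(animal_id="a5", start_x=950.0, start_y=150.0, **solo)),
            detectability={Treatment.RGB: detectability(d50=1000.0, jitter_sd=3.5)},
            heading_noise_sd=0.0,
            seed=2,
        )
        sim = simulate_flight(config)
        model = clip_to_frame_range(sim.model_sets[Treatment.RGB],
                                    sim.ground_truth.frame_range)
        counts, _ = match_sequence(sim.ground_truth, model)
        hist = iou_histogram(counts.overlap_ious, bin_width=0.05)
        assert len(hist.peaks) >= 2
        peak_counts = {p: hist.counts[min(int(p / 0.05), 19)] for p in hist.peaks}
        ranked = sorted(peak_counts, key=peak_counts.get, reverse=True)
        primary, secondary = ranked[0], ranked[1]
        assert secondary < primary  # lesser mode sits at lower IoU
        assert abs(primary - 0.74) <= 0.1
        assert abs(secondary - 0.35) <= 0.1


class TestConfigSerialisation:
    def test_yaml_round_trip(self, tmp_path):
        config = default_config()
        path = tmp_path / "preset.yaml"
        save_config(config, path)
        assert load_config(path) == config

    def test_default_preset_ordering(self):
        config = default_config()
        d = config.detectability
        assert d[Treatment.RGB].d50 >= d[Treatment.GREEN].d50 >= d[Treatment.GREEN_POL].d50
        assert d[Treatment.GREEN_POL].light_fraction == pytest.approx(
            d[Treatment.GREEN].light_fraction / 2)

    def test_overrides(self):
        config = default_config(n_frames=100, seed=1)
        assert config.n_frames == 100 and config.seed == 1
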