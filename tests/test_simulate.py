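import numpy as np
import pandas as pd
import pytest

from chipinvasion import (
    Calibration,
    SimulationParams,
    default_dose_config,
    default_experiment_config,
    estimate_effective_drift,
    generate_experiment,
    ground_truth_detections,
    positivity_rate,
    render,
    score_detections,
    segment_cells,
    simulate,
)
from chipinvasion.simulate import HALF_MAX_FACTOR, _channel_bounds, _inside_post


@pytest.fixture(scope="module")
def cal2():
    return Calibration(um_per_px=2.0)


class TestSimulationParams:
    def test_effective_drift_at_ic50_is_half(self):
        p = SimulationParams(drift_um_per_step=4.0, dose_uM=1.0, ic50_uM=1.0)
        assert p.effective_drift == pytest.approx(2.0)

    def test_zero_dose_full_drift(self):
        p = SimulationParams(drift_um_per_step=4.0, dose_uM=0.0)
        assert p.effective_drift == 4.0

    def test_noninvasive_requires_zero_drift(self):
        with pytest.raises(ValueError, match="zero drift"):
            SimulationParams(phenotype="non_invasive", drift_um_per_step=1.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(drift_um_per_step=-1),
            dict(diffusion_um=-0.1),
            dict(steps_per_day=0),
            dict(n_cells=0),
            dict(ic50_uM=0),
            dict(dose_uM=-1),
            dict(phenotype="sessile"),
        ],
    )
    def test_invalid_params(self, kwargs):
        with pytest.raises(ValueError):
            SimulationParams(**kwargs)


class TestSimulate:
    def test_day_count(self, default_geom):
        states = simulate(SimulationParams(n_cells=20, seed=0), default_geom, 2)
        assert [s.day for s in states] == [0.0, 1.0, 2.0]

    def test_invalid_n_days(self, default_geom):
        with pytest.raises(ValueError, match="n_days"):
            simulate(SimulationParams(seed=0), default_geom, 0)

    def test_frozen_dynamics(self, default_geom):
        p = SimulationParams(drift_um_per_step=0.0, diffusion_um=0.0, n_cells=30,
                             seed=3)
        states = simulate(p, default_geom, 2)
        np.testing.assert_array_equal(states[0].positions, states[2].positions)

    def test_deterministic_for_fixed_seed(self, default_geom):
        p = SimulationParams(n_cells=40, seed=11)
        a = simulate(p, default_geom, 2)
        b = simulate(p, default_geom, 2)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.positions, sb.positions)

    def test_different_seeds_differ(self, default_geom):
        a = simulate(SimulationParams(n_cells=40, seed=1), default_geom, 1)
        b = simulate(SimulationParams(n_cells=40, seed=2), default_geom, 1)
        assert not np.array_equal(a[1].positions, b[1].positions)

    def test_mean_displacement_matches_analytic_drift(self, default_geom):
        # deep seeding keeps cells away from posts/walls for one day
        p = SimulationParams(drift_um_per_step=1.0, diffusion_um=2.0,
                             n_cells=1000, seed=7)
        states = simulate(p, default_geom, 1)
        # use only cells that started deep enough not to interact with posts
        start_y = states[0].positions[:, 1]
        deep = start_y < -300
        disp = states[1].positions[deep, 1] - start_y[deep]
        expected = p.steps_per_day * p.effective_drift
        se = p.diffusion_um * np.sqrt(p.steps_per_day) / np.sqrt(deep.sum())
        assert abs(disp.mean() - expected) < 3 * se

    def test_no_position_inside_posts_any_step(self, default_geom):
        # fine-grained check: every stored day state of many walkers
        p = SimulationParams(drift_um_per_step=3.0, diffusion_um=4.0,
                             n_cells=300, seed=5, steps_per_day=25)
        for state in simulate(p, default_geom, 2):
            assert not _inside_post(state.positions, default_geom).any()

    def test_positions_inside_walls(self, default_geom):
        xmin, xmax, ymin, ymax = _channel_bounds(default_geom)
        p = SimulationParams(diffusion_um=10.0, n_cells=200, seed=9)
        for state in simulate(p, default_geom, 2):
            x, y = state.positions[:, 0], state.positions[:, 1]
            assert np.all((x >= xmin) & (x <= xmax))
            assert np.all((y >= ymin) & (y <= ymax))

    def test_noninvasive_seeded_deep(self, default_geom):
        p = SimulationParams(phenotype="non_invasive", drift_um_per_step=0.0,
                             n_cells=100, seed=13)
        day0 = simulate(p, default_geom, 1)[0]
        assert day0.positions[:, 1].max() < default_geom.post_center_y_um


class TestRender:
    def test_determinism(self, default_geom, cal2):
        state = simulate(SimulationParams(n_cells=30, seed=1), default_geom, 1)[1]
        img_a, _ = render(state, cal2, rng=np.random.default_rng(5))
        img_b, _ = render(state, cal2, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(img_a.pixels, img_b.pixels)

    def test_truth_lists_all_cells(self, default_geom, cal2):
        state = simulate(SimulationParams(n_cells=25, seed=2), default_geom, 1)[1]
        _, truth = render(state, cal2, labeled_fraction=0.6,
                          rng=np.random.default_rng(0))
        assert len(truth) == 25
        assert set(truth.columns) == {"x_um", "y_um", "labeled"}

    def test_high_snr_recovers_cells(self, default_geom, cal2):
        # well-separated cells: recall and precision >= 0.95
        rng = np.random.default_rng(21)
        n = 40
        x0, x1 = default_geom.active_window_x_um
        xs = np.linspace(x0 + 100, x1 - 100, n)
        ys = rng.uniform(-800, -200, n)
        from chipinvasion.simulate import SimState

        state = SimState(np.column_stack([xs, ys]), 1.0, default_geom)
        img, truth = render(state, cal2, snr=20.0, rng=rng)
        dets = segment_cells(img, min_area_um2=50)
        assert len(dets) >= 0.95 * n  # recall
        assert len(dets) <= n / 0.95  # precision (no spurious blobs)
        det_xy = np.array([d.centroid_um for d in dets])
        truth_xy = truth[["x_um", "y_um"]].to_numpy()
        d = np.linalg.norm(det_xy[:, None] - truth_xy[None], axis=2).min(axis=1)
        assert np.all(d < 5.0)

    def test_near_zero_snr_no_detections(self, default_geom, cal2):
        state = simulate(SimulationParams(n_cells=20, seed=3), default_geom, 1)[1]
        img, _ = render(state, cal2, snr=0.05, rng=np.random.default_rng(1))
        dets = segment_cells(img, min_area_um2=50)
        assert len(dets) <= 2  # essentially nothing rises above the noise

    def test_half_labeled_positivity(self, default_geom, cal2):
        # same field rendered in both modalities; half the cells labeled
        rng = np.random.default_rng(8)
        n = 30
        x0, x1 = default_geom.active_window_x_um
        xs = np.linspace(x0 + 150, x1 - 150, n)
        ys = np.where(np.arange(n) % 2 == 0, -300.0, -600.0)
        from chipinvasion.simulate import SimState

        state = SimState(np.column_stack([xs, ys]), 1.0, default_geom)
        label_rng = np.random.default_rng(42)
        fl_img, truth = render(state, cal2, snr=30.0, labeled_fraction=0.5,
                               rng=label_rng)
        bf_img, _ = render(state, cal2, snr=30.0, labeled_fraction=1.0,
                           rng=np.random.default_rng(43), modality="brightfield")
        fl = segment_cells(fl_img, min_area_um2=50)
        bf = segment_cells(bf_img, min_area_um2=50)
        rate = positivity_rate(bf, fl, match_radius_um=15.0)
        assert rate == pytest.approx(truth["labeled"].mean(), abs=0.1)

    def test_invalid_args(self, default_geom, cal2):
        state = simulate(SimulationParams(n_cells=5, seed=0), default_geom, 1)[1]
        with pytest.raises(ValueError, match="snr"):
            render(state, cal2, snr=0)
        with pytest.raises(ValueError, match="labeled_fraction"):
            render(state, cal2, labeled_fraction=0)


class TestGroundTruthDetections:
    def test_footprint_radius_is_half_max_disc(self, default_geom, cal2):
        positions = np.array([[2900.0, -500.0]])
        (det,) = ground_truth_detections(positions, default_geom, cal2,
                                         psf_sigma_um=6.0)
        pts = det.footprint_um()
        r = np.linalg.norm(pts - positions[0], axis=1)
        assert r.max() <= HALF_MAX_FACTOR * 6.0 + cal2.um_per_px
        assert det.area_um2 == pytest.approx(
            np.pi * (HALF_MAX_FACTOR * 6.0) ** 2, rel=0.2
        )

    def test_scores_match_rendered_segmentation(self, default_geom, cal2):
        """Closed loop at high SNR: rendering adds nothing to the scores."""
        p = SimulationParams(n_cells=120, seed=17)
        state = simulate(p, default_geom, 2)[2]
        img, _ = render(state, cal2, snr=50.0, rng=np.random.default_rng(99))
        thr = 100.0 + 50.0 * 20.0 / 2  # background + amplitude/2
        seg = segment_cells(img, min_area_um2=50,
                            threshold_method=f"fixed:{thr}")
        gt = ground_truth_detections(state.positions, default_geom, cal2, 6.0)
        s_seg = score_detections(seg, default_geom, "c", 2)
        s_gt = score_detections(gt, default_geom, "c", 2)
        assert s_seg.n_ipts_crossed == s_gt.n_ipts_crossed
        assert s_seg.max_distance_um == pytest.approx(s_gt.max_distance_um, abs=5)


class TestGenerateExperiment:
    def test_default_design_shape(self):
        cfg = default_experiment_config()
        cfg["n_chips"] = 3
        table, truth = generate_experiment(cfg)
        # 3 lines x 2 days x 3 chips = 18 records per metric
        per_metric = table.groupby("metric_name").size()
        assert per_metric["n_ipts_crossed"] == 18
        assert per_metric["max_distance_um"] == 18
        assert truth["chip_id"].nunique() == 9

    def test_deterministic(self):
        cfg = default_experiment_config()
        t1, _ = generate_experiment(cfg)
        t2, _ = generate_experiment(cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_missing_config_key(self):
        with pytest.raises(ValueError, match="missing keys"):
            generate_experiment({"arms": []})

    def test_empty_arms_rejected(self):
        cfg = default_experiment_config()
        cfg["arms"] = []
        with pytest.raises(ValueError, match="no arms"):
            generate_experiment(cfg)

    def test_writes_files(self, tmp_path):
        cfg = default_experiment_config()
        cfg["n_chips"] = 1
        cfg["arms"] = cfg["arms"][:1]
        cfg["arms"][0]["n_cells"] = 30
        generate_experiment(cfg, out_dir=tmp_path)
        tifs = sorted(tmp_path.glob("*.tif"))
        assert len(tifs) == 3  # day 0, 1, 2
        assert (tmp_path / "experiment_table.csv").exists()
        assert (tmp_path / "ground_truth_positions.csv").exists()
        assert (tmp_path / "geometry.json").exists()
        import json

        meta = json.loads(tifs[0].with_suffix(".json").read_text())
        assert {"chip_id", "day", "um_per_px", "origin_px"} <= set(meta)

    def test_invasive_exceeds_noninvasive(self):
        cfg = default_experiment_config()
        table, _ = generate_experiment(cfg)
        d2 = table[(table["day"] == 2) & (table["metric_name"] == "max_distance_um")]
        means = d2.groupby("cell_line")["value"].mean()
        assert means["INV1"] > means["NONINV"]
        assert means["INV2"] > means["NONINV"]

    def test_dose_config_non_increasing(self):
        cfg = default_dose_config()
        table, _ = generate_experiment(cfg)
        d2 = table[(table["day"] == 2) & (table["metric_name"] == "n_ipts_crossed")]
        means = d2.groupby("dose_uM")["value"].mean().sort_index()
        assert np.all(np.diff(means.to_numpy()) <= 0)


class TestEstimateEffectiveDrift:
    def test_recovers_drift_from_truth_positions(self, default_geom):
        p = SimulationParams(drift_um_per_step=2.0, diffusion_um=2.0,
                             n_cells=800, seed=31)
        states = simulate(p, default_geom, 1)
        # build single-pixel detections from true positions
        from tests.conftest import make_detection

        rng = np.random.default_rng(0)
        dets = {
            int(s.day): [
                make_detection(rng, tuple(xy), n_px=1, spread_px=0)
                for xy in s.positions
            ]
            for s in states
        }
        est = estimate_effective_drift(dets, p.steps_per_day)
        assert est == pytest.approx(p.effective_drift, rel=0.15)

    def test_requires_two_days(self):
        with pytest.raises(ValueError, match="two days"):
            estimate_effective_drift({0: []}, 50)
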