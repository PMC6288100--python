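import dataclasses

import numpy as np
import pytest
from click.testing import CliRunner

from shearfret import (
    FretPolarityModel,
    GroundTruth,
    RunConfig,
    StageError,
    ValidationError,
    cohort_polarity_test,
    generate_cohort,
    generate_stack,
)
from shearfret.cli import main, parse_time_point

NOISEFREE_CFG = RunConfig(despeckle_radius_px=0)


class TestFitRecovery:
    def test_noise_free_pipeline_recovers_generator_truth(self, noisefree_truth):
        stack, truth = generate_stack(noisefree_truth, n_frames=15)
        res = FretPolarityModel(stack, NOISEFREE_CFG).fit()
        exp_series = truth.expected_normalized_series(15, stack.frame_shape)
        np.testing.assert_allclose(res.series.normalized_ratio, exp_series, atol=1e-9)
        exp_bins = truth.expected_bin_traces(15, stack.frame_shape, 50)
        np.testing.assert_allclose(res.st_map.values, exp_bins, atol=1e-9)

    def test_summary_mentions_key_quantities(self, noisefree_stack):
        stack, _ = noisefree_stack
        res = FretPolarityModel(stack, NOISEFREE_CFG).fit()
        text = res.summary()
        assert "baseline" in text and "plateau" in text

    def test_prestimulus_normalized_mean_is_one(self, noisefree_stack):
        stack, truth = noisefree_stack
        res = FretPolarityModel(stack, NOISEFREE_CFG).fit()
        onset = truth.stimulus_onset_frame
        assert res.series.normalized_ratio[:onset].mean() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(res.st_map.values[:, :onset].mean(axis=1), 1.0,
                                   atol=1e-9)

    def test_updown_signs_follow_gradient(self):
        for g in (0.4, -0.4):
            truth = GroundTruth(
                center=(64.0, 64.5), gradient_slope=g, shot_noise=False,
                read_noise_sd=0.0, stimulus_onset_frame=5,
            )
            stack, _ = generate_stack(truth, n_frames=15)
            res = FretPolarityModel(stack, NOISEFREE_CFG).fit()
            down, up = res.updown_at(9 * 60.0)
            assert (down - up > 0) == (g > 0)


class TestFitMechanics:
    def test_stage_error_names_stage_and_frame(self):
        truth = GroundTruth(shot_noise=False, read_noise_sd=0.0)
        stack, _ = generate_stack(truth, n_frames=4)
        stack.donor[2] = 0.0  # cell vanishes in frame 2
        stack.fret[2] = 0.0
        with pytest.raises(StageError, match="segment.*frame 2"):
            FretPolarityModel(stack, NOISEFREE_CFG).fit()

    def test_mask_propagation_rescues_dim_frame(self):
        truth = GroundTruth(shot_noise=False, read_noise_sd=0.0)
        stack, _ = generate_stack(truth, n_frames=4)
        # frame 2: only a 5x5 patch of signal survives -> below the minimum
        # cell area, but still measurable under the propagated mask
        dim = np.zeros_like(stack.donor[2])
        dim[62:67, 62:67] = 100.0
        stack.donor[2] = dim
        stack.fret[2] = stack.fret[1].copy()
        cfg = dataclasses.replace(NOISEFREE_CFG, mask_propagation=True, donor_floor=0.0)
        res = FretPolarityModel(stack, cfg).fit()
        assert res.diagnostics["mask_propagated"][2] is True

    def test_fixed_edges_mode_runs(self, noisefree_stack):
        stack, _ = noisefree_stack
        cfg = dataclasses.replace(NOISEFREE_CFG, edges_mode="fixed")
        res = FretPolarityModel(stack, cfg).fit()
        assert len(res.profiles) == stack.n_frames

    def test_intensity_weighting_mode_runs(self, noisefree_stack):
        stack, _ = noisefree_stack
        cfg = dataclasses.replace(NOISEFREE_CFG, weighting="intensity")
        res = FretPolarityModel(stack, cfg).fit()
        assert res.profiles[0].percentages.sum() == pytest.approx(100.0, abs=1e-6)

    def test_save_outputs_are_deterministic(self, tmp_path, noisefree_stack):
        stack, _ = noisefree_stack
        res = FretPolarityModel(stack, NOISEFREE_CFG).fit()
        a, b = tmp_path / "a", tmp_path / "b"
        res.save(a)
        res.save(b)
        for name in ("series.csv", "profiles.csv", "map.csv", "ratio.tif",
                     "diagnostics.json", "config.yaml", "meta.yaml"):
            assert (a / name).read_bytes() == (b / name).read_bytes()


class TestRunConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(corner_window_px=6, donor_floor=3.5, t_variant="student")
        cfg.to_yaml(tmp_path / "cfg.yaml")
        assert RunConfig.from_yaml(tmp_path / "cfg.yaml") == cfg

    def test_unknown_key_named(self, tmp_path):
        (tmp_path / "cfg.yaml").write_text("no_such_knob: 1\n")
        with pytest.raises(ValidationError, match="no_such_knob"):
            RunConfig.from_yaml(tmp_path / "cfg.yaml")

    @pytest.mark.parametrize("field,value", [
        ("t_variant", "anova"), ("weighting", "area"),
        ("edges_mode", "adaptive"), ("donor_floor", "twice"),
    ])
    def test_invalid_values_rejected(self, field, value):
        with pytest.raises(ValidationError):
            RunConfig(**{field: value})


class TestCohortPolarity:
    def test_gradient_cohort_called_polar(self):
        base = GroundTruth(gradient_slope=0.6, decay_amplitude=0.25,
                           stimulus_onset_frame=5)
        cells = generate_cohort(
            base, 8, between_cell_sd={"gradient_slope": 0.05},
            master_seed=11, n_frames=20,
        )
        results = [FretPolarityModel(s).fit() for s, _ in cells]
        res = cohort_polarity_test(results, time_after_onset_s=14 * 60.0)
        assert res.polar and res.down_mean > res.up_mean

    def test_requires_two_cells(self):
        with pytest.raises(ValidationError):
            cohort_polarity_test([], 60.0)


class TestCli:
    def test_parse_time_point(self):
        assert parse_time_point("30m") == 1800.0
        assert parse_time_point("90s") == 90.0
        assert parse_time_point("120") == 120.0

    def test_simulate_analyze_cohort_round_trip(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(main, [
            "simulate", "--out", str(tmp_path / "sim"), "--seed", "4",
            "--n-cells", "3", "--frames", "12",
        ])
        assert r.exit_code == 0, r.output
        run_dirs = []
        for i in range(3):
            cell = tmp_path / "sim" / f"cell_{i:02d}"
            out = tmp_path / f"run_{i}"
            r = runner.invoke(main, [
                "analyze", "--donor", str(cell / "donor.tif"),
                "--fret", str(cell / "fret.tif"),
                "--meta", str(cell / "meta.yaml"), "--out", str(out),
            ])
            assert r.exit_code == 0, r.output
            run_dirs.append(out)
        args = ["cohort-test", "--time-point", "2m",
                "--out", str(tmp_path / "polarity.json")]
        for d in run_dirs:
            args += ["--runs", str(d)]
        r = runner.invoke(main, args)
        assert r.exit_code == 0, r.output
        assert (tmp_path / "polarity.json").exists()

    def test_simulate_rejects_unknown_generator_key(self, tmp_path):
        (tmp_path / "gen.yaml").write_text("warp_speed: 9\n")
        r = CliRunner().invoke(main, [
            "simulate", "--out", str(tmp_path / "sim"), "--config",
            str(tmp_path / "gen.yaml"),
        ])
        assert r.exit_code != 0
        assert "warp_speed" in r.output

    def test_truth_json_round_trips_through_loader(self, tmp_path):
        runner = CliRunner()
        runner.invoke(main, ["simulate", "--out", str(tmp_path / "sim"),
                             "--seed", "2", "--frames", "5"])
        truth = GroundTruth.from_json(tmp_path / "sim" / "cell_00" / "truth.json")
        assert truth.seed == 2
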