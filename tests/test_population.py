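import dataclasses

import numpy as np
import pytest
import tifffile
import yaml

from flickerspec import population, simulate
from flickerspec.fitting import FitResult
from flickerspec.population import (

    FilterSpec,
    FrameStack,
    MissingPixelSizeError,
    PopulationRecord,
    apply_population_filters,
    export_aggregate,
    load_config,
    read_aggregate,
    read_frame_stack,
    run_experiment,
    summarize,
    write_aggregate,
    write_frame_stack,
)


def make_fit(sigma=1e-6, epsilon=0.1, delta_epsilon=0.5, kappa=5.0):
    return FitResult(
        sigma=sigma, kappa=kappa, sigma_bar=300.0, epsilon=epsilon,
        epsilon_sigma_only=epsilon + delta_epsilon, delta_epsilon=delta_epsilon,
        durbin_watson=2.0, sigma_err=0.1 * sigma, kappa_err=0.5,
        converged=True, radius_um=2.0, n_frames=500,
    )


def make_record(object_id=0, sigma=1e-6, continuity=0.9, epsilon=0.1, delta=0.5, n_frames=500):
    return PopulationRecord(
        fit=make_fit(sigma=sigma, epsilon=epsilon, delta_epsilon=delta),
        video="v0", object_id=object_id, n_frames=n_frames,
        continuity_fraction=continuity, mean_intensity=180.0,
        centroid=(30.0, 40.0), experiment="test",
    )


class TestFrameStackIO:
    def test_ome_pixel_size_round_trip(self, tmp_path):
        frames = np.random.default_rng(0).integers(0, 255, (5, 16, 16), dtype=np.uint8)
        path = tmp_path / "video.ome.tif"
        write_frame_stack(path, frames, pixel_size=0.137)
        stack = read_frame_stack(path)
        assert stack.pixel_size == pytest.approx(0.137)
        assert np.array_equal(stack.frames, frames)

    def test_plain_tiff_requires_override(self, tmp_path):
        path = tmp_path / "plain.tif"
        tifffile.imwrite(path, np.zeros((3, 8, 8), dtype=np.uint8), photometric="minisblack")
        with pytest.raises(MissingPixelSizeError, match="pixel_size"):
            read_frame_stack(path)
        stack = read_frame_stack(path, pixel_size_override=0.2)
        assert stack.pixel_size == 0.2

    def test_frame_count_preserved(self, tmp_path):
        frames = np.zeros((133, 8, 8), dtype=np.uint8)
        path = tmp_path / "long.ome.tif"
        write_frame_stack(path, frames, pixel_size=0.1)
        assert read_frame_stack(path).n_frames == 133

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_frame_stack(tmp_path / "nope.tif")

    def test_single_frame_promoted(self, tmp_path):
        path = tmp_path / "one.tif"
        tifffile.imwrite(path, np.zeros((8, 8), dtype=np.uint8))
        assert read_frame_stack(path, pixel_size_override=0.1).frames.shape == (1, 8, 8)

    def test_invalid_pixel_size(self):
        with pytest.raises(ValueError):
            FrameStack(np.zeros((1, 4, 4)), pixel_size=0.0)


class TestPopulationFilters:
    def test_crafted_fixture(self):
        # six records each violating exactly one filter, plus one clean
        records = [
            make_record(0, sigma=1e-11),          # tension filter
            make_record(1, continuity=0.5),       # continuity filter
            make_record(2, epsilon=0.6),          # fit-error filter
            make_record(3, delta=0.01),           # delta-epsilon filter
            make_record(4, n_frames=100),         # minimum-frames filter
            make_record(5, sigma=0.0),            # tension filter again
            make_record(6),                       # clean
        ]
        passing, tallies = apply_population_filters(records, FilterSpec())
        assert [r.object_id for r in passing] == [6]
        assert tallies == {
            "sigma": 2, "continuity": 1, "epsilon": 1, "delta_epsilon": 1, "n_frames": 1,
        }

    def test_epsilon_filter(self):
        _, tallies = apply_population_filters([make_record(epsilon=0.6)], FilterSpec())
        assert tallies["epsilon"] == 1

    def test_sigma_filter(self):
        _, tallies = apply_population_filters([make_record(sigma=1e-11)], FilterSpec())
        assert tallies["sigma"] == 1

    def test_pass_fail_order_independent(self):
        # a record failing several filters is rejected regardless of tally order
        bad = make_record(sigma=1e-11, epsilon=0.9, n_frames=10)
        passing, _ = apply_population_filters([bad], FilterSpec())
        assert passing == []

    def test_min_frames_configurable(self):
        record = make_record(n_frames=150)
        passing, _ = apply_population_filters([record], FilterSpec(min_frames=133))
        assert len(passing) == 1


class TestSummarize:
    def test_single_record_gsd_one(self):
        center, spread = summarize(np.array([3.7]), "lognormal")
        assert center == pytest.approx(3.7)
        assert spread == pytest.approx(1.0)

    def test_geometric_mean_symmetry(self):
        center, _ = summarize(np.array([1.0, 100.0]), "lognormal")
        assert center == pytest.approx(10.0)

    def test_lognormal_monte_carlo(self):
        rng = np.random.default_rng(3)
        values = np.exp(rng.standard_normal(10_000))
        center, spread = summarize(values, "lognormal")
        assert spread == pytest.approx(np.e, rel=0.02)
        assert center == pytest.approx(1.0, rel=0.05)

    def test_linear(self):
        center, spread = summarize(np.array([1.0, 2.0, 3.0]), "linear")
        assert center == pytest.approx(2.0)
        assert spread == pytest.approx(1.0)

    def test_nonpositive_lognormal_rejected(self):
        with pytest.raises(ValueError):
            summarize(np.array([1.0, -1.0]), "lognormal")


class TestAggregateIO:
    def test_round_trip(self, tmp_path):
        records = [make_record(i) for i in range(4)]
        path = tmp_path / "agg.h5"
        write_aggregate(records, path)
        df = read_aggregate(path)
        assert len(df) == 4
        assert df.sigma.tolist() == pytest.approx([1e-6] * 4)
        assert df.video.tolist() == ["v0"] * 4
        assert df.continuity_fraction.tolist() == pytest.approx([0.9] * 4)

    def test_empty_set(self, tmp_path):
        path = tmp_path / "empty.h5"
        write_aggregate([], path)
        assert len(read_aggregate(path)) == 0

    def test_many_records_dtypes(self, tmp_path):
        records = [make_record(i) for i in range(1000)]
        path = tmp_path / "big.h5"
        write_aggregate(records, path)
        df = read_aggregate(path)
        assert len(df) == 1000
        assert df.object_id.dtype == np.int64
        assert df.sigma.dtype == np.float64

    def test_csv_export(self, tmp_path):
        import pandas as pd

        path = tmp_path / "agg.h5"
        write_aggregate([make_record(0)], path)
        out = tmp_path / "agg.csv"
        export_aggregate(path, out, "csv")
        assert len(pd.read_csv(out)) == 1


class TestConfig:
    def _write(self, tmp_path, payload):
        path = tmp_path / "config.yaml"
        path.write_text(yaml.safe_dump(payload))
        return path

    def test_valid_config(self, tmp_path):
        path = self._write(
            tmp_path,
            {
                "experiment_name": "exp1",
                "videos": ["a.ome.tif"],
                "pixel_size": 0.1,
                "detection": {"minimum_intensity": 0.25, "min_size": 20, "max_size": 50},
                "filters": {"min_frames": 50},
            },
        )
        config = load_config(path)
        assert config.experiment_name == "exp1"
        assert config.imaging.min_intensity == 0.25
        assert config.filters.min_frames == 50
        assert config.videos[0].endswith("a.ome.tif")

    def test_unknown_top_key_rejected(self, tmp_path):
        path = self._write(tmp_path, {"videos": ["a.tif"], "bogus": 1})
        with pytest.raises(ValueError, match="bogus"):
            load_config(path)

    def test_unknown_detection_key_rejected(self, tmp_path):
        path = self._write(tmp_path, {"videos": ["a.tif"], "detection": {"blur": 2}})
        with pytest.raises(ValueError, match="blur"):
            load_config(path)

    def test_missing_videos_rejected(self, tmp_path):
        path = self._write(tmp_path, {"experiment_name": "x"})
        with pytest.raises(ValueError, match="video"):
            load_config(path)


@pytest.fixture(scope="module")
def experiment_dir(tmp_path_factory):
    """Two 40-frame single-droplet videos plus a config file."""
    root = tmp_path_factory.mktemp("experiment")
    params = simulate.SimulationParams.from_sigma_bar(300.0, 5.0, 2.0, pixel_size=0.1)
    for i, seed in enumerate((101, 202)):
        frames, _ = simulate.generate_video(params, 40, 1, seed=seed)
        write_frame_stack(root / f"video{i}.ome.tif", frames, 0.1)
    config = {
        "experiment_name": "synthetic",
        "videos": ["video0.ome.tif", "video1.ome.tif"],
        "temperature": 298.0,
        "detection": {"minimum_intensity": 0.3, "min_size": 25, "max_size": 55},
        "filters": {"min_frames": 20, "max_epsilon": 2.0, "min_delta_epsilon": 0.0},
        "output": "aggregate.h5",
    }
    (root / "config.yaml").write_text(yaml.safe_dump(config))
    return root


class TestRunExperiment:
    def test_end_to_end(self, experiment_dir):
        out = run_experiment(experiment_dir / "config.yaml", experiment_dir)
        df = read_aggregate(out)
        assert len(df) == 2  # one droplet per video
        assert set(df.video) == {"video0", "video1"}
        # sigma_bar = 300 at kappa = 5 kBT, R = 2 um: order-of-magnitude check
        assert np.all(df.sigma > 1e-7) and np.all(df.sigma < 1e-5)
        assert (experiment_dir / "aggregate.log").exists()

    def test_rerun_identical(self, experiment_dir, tmp_path):
        out1 = run_experiment(experiment_dir / "config.yaml", tmp_path)
        df1 = read_aggregate(out1)
        out2 = run_experiment(experiment_dir / "config.yaml", experiment_dir)
        df2 = read_aggregate(out2)
        assert df1.equals(df2)

    def test_unreadable_video_skipped(self, experiment_dir, tmp_path):
        config = load_config(experiment_dir / "config.yaml")
        broken = dataclasses.replace(
            config, videos=config.videos + [str(tmp_path / "missing.ome.tif")]
        )
        out = run_experiment(broken, tmp_path)
        assert len(read_aggregate(out)) == 2

    def test_plain_tiff_without_pixel_size_fails_early(self, tmp_path):
        frames = np.zeros((3, 32, 32), dtype=np.uint8)
        tifffile.imwrite(tmp_path / "plain.tif", frames, photometric="minisblack")
        (tmp_path / "config.yaml").write_text(
            yaml.safe_dump({"experiment_name": "x", "videos": ["plain.tif"]})
        )
        with pytest.raises(MissingPixelSizeError):
            run_experiment(tmp_path / "config.yaml", tmp_path)
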