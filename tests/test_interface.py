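"""Container I/O, configuration round-trips, experiment grids, and the CLI."""

import h5py
import numpy as np
import pytest
from click.testing import CliRunner

from smsradial import RunConfig, run_simulation
from smsradial.cli import main
from smsradial.config import ConfigError
from smsradial.container import (
    ContainerError,
    read_acquisition,
    read_recon,
    read_true_maps,
    read_truth,
    write_recon,
    write_simulation,
)
from smsradial.experiments import COARSE_LAMBDAS, FINE_LAMBDAS, SPOKES_SWEEP
from smsradial.recon import ReconResult

TINY_KW = dict(
    grid_size=32,
    n_coils=2,
    n_frames=2,
    spokes_per_frame=8,
    points_per_spoke=32,
    noise_level=0.02,
    seed=1,
)


@pytest.fixture(scope="module")
def tiny_container(tmp_path_factory):
    path = tmp_path_factory.mktemp("containers") / "tiny.h5"
    run = run_simulation(RunConfig(**TINY_KW))
    write_simulation(path, run.kspace, run.phantom, run.true_maps)
    return path, run


class TestContainer:
    def test_acquisition_round_trip(self, tiny_container):
        path, run = tiny_container
        ks = read_acquisition(path)
        np.testing.assert_array_equal(ks.data, run.kspace.data)
        np.testing.assert_array_equal(ks.trajectory.coords, run.kspace.trajectory.coords)
        np.testing.assert_array_equal(
            ks.schedule.phases_rad, run.kspace.schedule.phases_rad
        )
        assert ks.trajectory.scheme == run.kspace.trajectory.scheme
        assert ks.trajectory.tr_ms == run.kspace.trajectory.tr_ms

    def test_truth_round_trip(self, tiny_container):
        path, run = tiny_container
        phantom = read_truth(path)
        np.testing.assert_array_equal(phantom.slices, run.phantom.slices)
        np.testing.assert_array_equal(phantom.centroids, run.phantom.centroids)
        maps = read_true_maps(path)
        np.testing.assert_array_equal(maps.maps, run.true_maps.maps)

    def test_recon_round_trip(self, tiny_container, rng):
        path, run = tiny_container
        videos = rng.standard_normal((3, 2, 32, 32)) + 1j * rng.standard_normal((3, 2, 32, 32))
        write_recon(path, ReconResult(videos=videos, objective=np.arange(4.0)))
        np.testing.assert_array_equal(read_recon(path), videos)

    def test_unknown_major_version_rejected(self, tmp_path):
        path = tmp_path / "future.h5"
        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = "2.0"
        with pytest.raises(ContainerError, match="schema version"):
            read_acquisition(path)

    def test_non_container_rejected(self, tmp_path):
        path = tmp_path / "raw.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("stuff", data=[1, 2, 3])
        with pytest.raises(ContainerError):
            read_acquisition(path)


class TestRunConfig:
    def test_yaml_round_trip_lossless(self, tmp_path):
        cfg = RunConfig(**TINY_KW).replace(lam=0.02, n_virtual=2)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert RunConfig.from_yaml(path) == cfg

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigError, match="unknown"):
            RunConfig.from_dict({"grid_sise": 64})

    @pytest.mark.parametrize(
        "bad",
        [
            {"grid_size": 16},
            {"scheme": "SPIRAL"},
            {"n_virtual": 99},
            {"lam": -0.1},
        ],
    )
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ConfigError):
            RunConfig(**bad)


class TestLambdaSearch:
    def test_coarse_search_minimum_is_interior(self, small_run, small_cfg):
        """Regularization helps under noise: best RMSE is not at the grid edge."""
        import dataclasses

        from smsradial.experiments import SimulationRun, lambda_search

        run = SimulationRun(
            config=small_cfg.replace(max_iterations=15),
            phantom=small_run.phantom,
            true_maps=small_run.true_maps,
            kspace=small_run.kspace,
        )
        rows = lambda_search(run, mode="coarse")
        assert [r["lam"] for r in rows] == list(COARSE_LAMBDAS)
        assert all({"rmse", "mean_tsnr", "edge_sharpness"} <= set(r) for r in rows)
        errors = [r["rmse"] for r in rows]
        best = int(np.argmin(errors))
        assert 0 < best < len(errors) - 1


class TestExperimentGrids:
    def test_coarse_lambda_grid(self):
        assert len(COARSE_LAMBDAS) == 4
        assert COARSE_LAMBDAS[0] == 1e-4 and COARSE_LAMBDAS[-1] == 1e-1

    def test_fine_lambda_grid(self):
        assert len(FINE_LAMBDAS) == 10
        np.testing.assert_allclose(np.diff(FINE_LAMBDAS), 0.01)
        assert FINE_LAMBDAS[0] == pytest.approx(0.01)
        assert FINE_LAMBDAS[-1] == pytest.approx(0.1)

    def test_spokes_sweep_values(self):
        assert SPOKES_SWEEP == (95, 45, 20, 15, 10)


class TestCli:
    def _simulate(self, runner, tmp_path, **extra):
        args = [
            "simulate", str(tmp_path / "run.h5"),
            "--grid-size", "32", "--n-slices", "2", "--n-frames", "2",
            "--spokes-per-frame", "8", "--seed", "1",
        ]
        for key, val in extra.items():
            args += [key, str(val)]
        return runner.invoke(main, args)

    def test_simulate_writes_valid_container(self, tmp_path):
        runner = CliRunner()
        # the tiny CLI fixtures use a short readout via config file
        cfg = RunConfig(**TINY_KW)
        cfg.to_yaml(tmp_path / "base.yaml")
        res = runner.invoke(
            main, ["simulate", str(tmp_path / "run.h5"), "--config", str(tmp_path / "base.yaml")]
        )
        assert res.exit_code == 0, res.output
        ks = read_acquisition(tmp_path / "run.h5")
        assert ks.n_coils == 2 and ks.n_spokes == 16

    def test_simulation_is_deterministic(self, tmp_path):
        runner = CliRunner()
        cfg = RunConfig(**TINY_KW)
        cfg.to_yaml(tmp_path / "base.yaml")
        for name in ("a.h5", "b.h5"):
            res = runner.invoke(
                main, ["simulate", str(tmp_path / name), "--config", str(tmp_path / "base.yaml")]
            )
            assert res.exit_code == 0, res.output
        np.testing.assert_array_equal(
            read_acquisition(tmp_path / "a.h5").data, read_acquisition(tmp_path / "b.h5").data
        )

    def test_five_slice_multiband_accepted(self, tmp_path):
        runner = CliRunner()
        cfg = RunConfig(**{**TINY_KW, "n_slices": 5, "n_coils": 6})
        cfg.to_yaml(tmp_path / "five.yaml")
        res = runner.invoke(
            main, ["simulate", str(tmp_path / "five.h5"), "--config", str(tmp_path / "five.yaml")]
        )
        assert res.exit_code == 0, res.output
        ks = read_acquisition(tmp_path / "five.h5")
        assert ks.trajectory.n_slices == 5
        phantom = read_truth(tmp_path / "five.h5")
        assert phantom.slices.shape == (5, 2, 32, 32)

    def test_recon_command_cgsense(self, tmp_path):
        runner = CliRunner()
        cfg = RunConfig(**TINY_KW)
        cfg.to_yaml(tmp_path / "base.yaml")
        res = runner.invoke(
            main, ["simulate", str(tmp_path / "run.h5"), "--config", str(tmp_path / "base.yaml")]
        )
        assert res.exit_code == 0, res.output
        res = runner.invoke(
            main,
            ["recon", str(tmp_path / "run.h5"), "--method", "cgsense",
             "--config", str(tmp_path / "base.yaml")],
        )
        assert res.exit_code == 0, res.output
        videos = read_recon(tmp_path / "run.h5")
        assert videos.shape == (3, 2, 32, 32)
        assert np.abs(videos).max() > 0

    def test_config_error_exit_code(self, tmp_path):
        runner = CliRunner()
        bad = tmp_path / "bad.yaml"
        bad.write_text("grid_size: 16\n")
        res = runner.invoke(main, ["simulate", str(tmp_path / "x.h5"), "--config", str(bad)])
        assert res.exit_code == 2

    def test_data_error_exit_code(self, tmp_path):
        runner = CliRunner()
        empty = tmp_path / "empty.h5"
        with h5py.File(empty, "w") as f:
            f.attrs["schema_version"] = "1.0"
        res = runner.invoke(main, ["recon", str(empty)])
        assert res.exit_code == 3
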