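"""Tests for the functional training front end, config files, and CLI."""

import numpy as np
import pytest
from click.testing import CliRunner

from glsnn import GLSNN, TrainConfig, make_blobs, run_ablation, train
from glsnn.cli import main
from glsnn.config import load_config, save_config
from glsnn.trainer import depth_sweep


@pytest.fixture(scope="module")
def small_task():
    return make_blobs(n_per_class=30, dim=10, n_classes=3, seed=4)


class TestTrainWrapper:
    def test_matches_model_fit(self, small_task):
        tr, te = small_task
        cfg = TrainConfig(layer_sizes=(10, 8, 3), epochs=3, seed=0)
        r_fn = train(cfg, tr, te)
        r_obj = GLSNN(tr, te, layer_sizes=(10, 8, 3), epochs=3, seed=0).fit()
        for W1, W2 in zip(r_fn.network.weights, r_obj.network.weights):
            np.testing.assert_array_equal(W1, W2)


class TestAblation:
    def test_zero_feedback_freezes_all_but_top_two(self, small_task):
        tr, te = small_task
        cfg = TrainConfig(layer_sizes=(10, 8, 8, 8, 3), epochs=2, seed=0)
        (res,) = run_ablation(cfg, [0], tr, te)
        init = GLSNN(tr, te, layer_sizes=cfg.layer_sizes,
                     **{k: v for k, v in vars(cfg).items() if k != "layer_sizes"}
                     )._init_state()[0]
        np.testing.assert_array_equal(res.network.weights[0], init.weights[0])
        np.testing.assert_array_equal(res.network.weights[1], init.weights[1])
        assert not np.array_equal(res.network.weights[2], init.weights[2])
        assert not np.array_equal(res.network.weights[3], init.weights[3])

    def test_full_feedback_updates_every_matrix(self, small_task):
        tr, te = small_task
        cfg = TrainConfig(layer_sizes=(10, 8, 8, 8, 3), epochs=2, seed=0)
        (res,) = run_ablation(cfg, [2], tr, te)
        init = GLSNN(tr, te, layer_sizes=cfg.layer_sizes,
                     **{k: v for k, v in vars(cfg).items() if k != "layer_sizes"}
                     )._init_state()[0]
        for W0, W1 in zip(init.weights, res.network.weights):
            assert not np.array_equal(W0, W1)

    def test_invalid_count_rejected(self, small_task):
        tr, te = small_task
        cfg = TrainConfig(layer_sizes=(10, 8, 3), epochs=1)
        with pytest.raises(ValueError):
            run_ablation(cfg, [5], tr, te)

    def test_results_in_requested_order(self, small_task):
        tr, te = small_task
        cfg = TrainConfig(layer_sizes=(10, 8, 8, 3), epochs=1, seed=0)
        results = run_ablation(cfg, [1, 0], tr, te)
        assert [r.config.n_feedback_layers for r in results] == [1, 0]


class TestDepthSweep:
    def test_table_rows_and_reproducibility(self, small_task):
        tr, te = small_task
        cfg = TrainConfig(layer_sizes=(10, 8, 3), epochs=2, seed=0)
        t1 = depth_sweep(cfg, [1, 2, 3], hidden_width=8, train_set=tr, test_set=te)
        t2 = depth_sweep(cfg, [1, 2, 3], hidden_width=8, train_set=tr, test_set=te)
        assert len(t1) == 3
        assert list(t1["hidden_layers"]) == [1, 2, 3]
        assert t1["architecture"][1] == "10-8-8-3"
        np.testing.assert_array_equal(t1["test_acc"], t2["test_acc"])

    def test_depth_beyond_step_budget_rejected(self, small_task):
        tr, te = small_task
        cfg = TrainConfig(layer_sizes=(10, 8, 3), epochs=1)
        with pytest.raises(ValueError, match="steps"):
            depth_sweep(cfg, [10], hidden_width=4, train_set=tr, test_set=te)


class TestConfigFile:
    def test_round_trip_and_overrides(self, tmp_path):
        cfg = TrainConfig(layer_sizes=(10, 8, 3), epochs=17, eta_w=0.02, seed=9)
        path = tmp_path / "run.ini"
        save_config(path, cfg)
        loaded = load_config(path)
        assert loaded == cfg
        assert load_config(path, epochs=3).epochs == 3

    def test_neuron_section_parsed(self, tmp_path):
        path = tmp_path / "run.ini"
        path.write_text(
            "[neuron]\nV_th = 0.002\ndt = 0.01\nT = 0.2\n"
            "[network]\nlayer_sizes = 10, 8, 3\n"
            "[train]\nepochs = 5\neta_t = 0.25\n"
        )
        cfg = load_config(path)
        assert cfg.neuron.V_th == 0.002 and cfg.neuron.n_steps == 20
        assert cfg.epochs == 5 and cfg.eta_t == 0.25

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "bad.ini"
        path.write_text("[network]\nlayer_sizes = 4,2\n[train]\nmomentum = 0.9\n")
        with pytest.raises(ValueError, match="momentum"):
            load_config(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_config(tmp_path / "nope.ini")


class TestCli:
    def test_make_synthetic_then_train_then_eval(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        r = runner.invoke(main, [
            "make-synthetic", "--out-dir", str(data), "--n-per-class", "30",
            "--dim", "10", "--n-classes", "3", "--seed", "0",
        ])
        assert r.exit_code == 0, r.output
        assert (data / "train-images.idx").exists()

        model = tmp_path / "model.npz"
        r = runner.invoke(main, [
            "train",
            "--layer-sizes", "10,8,3", "--epochs", "3", "--seed", "0",
            "--train-images", str(data / "train-images.idx"),
            "--train-labels", str(data / "train-labels.idx"),
            "--test-images", str(data / "test-images.idx"),
            "--test-labels", str(data / "test-labels.idx"),
            "--out", str(model), "--history", str(tmp_path / "hist.tsv"),
        ])
        assert r.exit_code == 0, r.output
        assert "epoch=3" in r.output and "GLSNN Results" in r.output
        assert model.exists() and (tmp_path / "hist.tsv").exists()

        r = runner.invoke(main, [
            "eval", "--model", str(model),
            "--images", str(data / "test-images.idx"),
            "--labels", str(data / "test-labels.idx"),
        ])
        assert r.exit_code == 0, r.output
        assert r.output.startswith("accuracy=")

    def test_ablate_command(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        runner.invoke(main, ["make-synthetic", "--out-dir", str(data),
                             "--n-per-class", "20", "--dim", "10",
                             "--n-classes", "3", "--seed", "1"])
        r = runner.invoke(main, [
            "ablate",
            "--layer-sizes", "10,6,6,3", "--epochs", "1", "--seed", "0",
            "--feedback-counts", "0,1",
            "--train-images", str(data / "train-images.idx"),
            "--train-labels", str(data / "train-labels.idx"),
        ])
        assert r.exit_code == 0, r.output
        assert "n_feedback_layers" in r.output

    def test_sweep_command(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        runner.invoke(main, ["make-synthetic", "--out-dir", str(data),
                             "--n-per-class", "20", "--dim", "10",
                             "--n-classes", "3", "--seed", "1"])
        r = runner.invoke(main, [
            "sweep",
            "--layer-sizes", "10,6,3", "--epochs", "1", "--seed", "0",
            "--depths", "1,2", "--hidden-width", "6",
            "--train-images", str(data / "train-images.idx"),
            "--train-labels", str(data / "train-labels.idx"),
        ])
        assert r.exit_code == 0, r.output
        assert "architecture" in r.output
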