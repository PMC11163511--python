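"""Training recipe: LR schedule, determinism, checkpoints, prediction."""

import dataclasses

import numpy as np
import pytest

from polypseg.data import SyntheticConfig, generate_synthetic_dataset, save_dataset
from polypseg.model import build_model
from polypseg.nn.optim import SGD, split_decay_params
from polypseg.training import (TrainConfig, evaluate, load_checkpoint,
                               make_checkpoint, model_from_checkpoint, poly_lr,
                               predict, save_checkpoint, train, TrainState)

SHORT = dict(epochs=4, batch_size=4, val_fraction=0.0, seed=3)


@pytest.fixture(scope="module")
def small_pairs():
    return generate_synthetic_dataset(
        SyntheticConfig(n_images=6, image_size=(32, 32), seed=5))


class TestPolyLR:
    def test_starts_at_base_rate(self):
        assert poly_lr(0, 1000, 5e-3) == pytest.approx(5e-3)

    def test_ends_at_zero(self):
        assert poly_lr(1000, 1000, 5e-3) == 0.0

    def test_halfway_value(self):
        assert poly_lr(500, 1000, 5e-3, power=0.9) == \
            pytest.approx(5e-3 * 0.5 ** 0.9, rel=1e-6)

    def test_monotone_nonincreasing(self):
        lrs = [poly_lr(i, 200, 5e-3, 0.9) for i in range(201)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_iteration_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            poly_lr(11, 10, 5e-3)


class TestTrainLoop:
    def test_loss_decreases_on_small_fixture(self, small_pairs, tiny_cfg):
        cfg = dataclasses.replace(tiny_cfg, ref_input_size=(32, 32))
        ckpt, state = train(cfg, TrainConfig(**SHORT), small_pairs)
        losses = [h["train_loss"] for h in state.history]
        assert losses[-1] < losses[0]
        assert state.iteration == 4 * 2  # 4 epochs x ceil(6/4) batches

    def test_same_seed_reproduces_loss_curve(self, small_pairs, tiny_cfg):
        cfg = dataclasses.replace(tiny_cfg, ref_input_size=(32, 32))
        _, s1 = train(cfg, TrainConfig(**SHORT), small_pairs)
        _, s2 = train(cfg, TrainConfig(**SHORT), small_pairs)
        a = [h["train_loss"] for h in s1.history]
        b = [h["train_loss"] for h in s2.history]
        np.testing.assert_allclose(a, b, rtol=1e-6)

    def test_empty_dataset_rejected(self, tiny_cfg):
        with pytest.raises(ValueError, match="empty"):
            train(tiny_cfg, TrainConfig(**SHORT), [])

    def test_weight_decay_spares_norm_and_bias_parameters(self, tiny_cfg):
        """One SGD step with vs without decay from identical weights:
        only the decayed group (conv/linear weights) may differ."""
        model = build_model(dataclasses.replace(tiny_cfg,
                                                ref_input_size=(32, 32)), seed=0)
        decay, no_decay = split_decay_params(model)
        assert decay and no_decay
        x = np.random.default_rng(0).random((2, 3, 32, 32), dtype=np.float32)

        def one_step(wd):
            m = build_model(dataclasses.replace(
                tiny_cfg, ref_input_size=(32, 32)), seed=0)
            m.eval()  # freeze batch-norm stats so updates are comparable
            opt = SGD(m, lr=0.1, momentum=0.0, weight_decay=wd)
            out = m(x)
            (out.probabilities * out.probabilities).mean().backward()
            opt.step()
            return m.state_dict()

        with_wd, without_wd = one_step(1.0), one_step(0.0)
        model_names = {n for n, _ in model.named_parameters()}
        decay_ids = {id(p) for p in decay}
        named = dict(model.named_parameters())
        for name in model_names:
            a, b = with_wd[name], without_wd[name]
            if id(named[name]) in decay_ids:
                continue  # decayed weights are allowed (expected) to differ
            np.testing.assert_array_equal(a, b, err_msg=name)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_nonfinite_loss_aborts_with_diagnostics(self, small_pairs, tiny_cfg):
        cfg = dataclasses.replace(tiny_cfg, ref_input_size=(32, 32))
        bad = TrainConfig(**{**SHORT, "base_lr": 1e6})  # guaranteed blow-up
        with pytest.raises(RuntimeError, match="non-finite|overflow") as exc:
            for _ in range(3):
                train(cfg, bad, small_pairs)
        assert "lr" in str(exc.value)


class TestCheckpoints:
    def test_save_load_evaluate_round_trip_bit_stable(self, small_pairs,
                                                      tiny_cfg, tmp_path):
        cfg = dataclasses.replace(tiny_cfg, ref_input_size=(32, 32))
        tc = TrainConfig(**{**SHORT, "epochs": 2})
        ckpt, state = train(cfg, tc, small_pairs)
        before = evaluate(ckpt, small_pairs)
        save_checkpoint(ckpt, tmp_path / "model.npz")
        loaded = load_checkpoint(tmp_path / "model.npz")
        after = evaluate(loaded, small_pairs)
        assert before.per_image == after.per_image

    def test_config_hash_mismatch_detected(self, tiny_cfg, tmp_path):
        model = build_model(tiny_cfg, seed=0)
        ckpt = make_checkpoint(model, tiny_cfg, TrainConfig(**SHORT),
                               TrainState())
        ckpt["config_hash"] = "deadbeef00000000"
        save_checkpoint(ckpt, tmp_path / "bad.npz")
        with pytest.raises(ValueError, match="hash"):
            load_checkpoint(tmp_path / "bad.npz")

    def test_train_config_round_trips_losslessly(self):
        tc = TrainConfig()  # the 200-epoch reference recipe
        assert tc.epochs == 200 and tc.base_lr == 5e-3
        assert TrainConfig.from_dict(tc.to_dict()) == tc

    def test_run_artifacts_written(self, small_pairs, tiny_cfg, tmp_path):
        cfg = dataclasses.replace(tiny_cfg, ref_input_size=(32, 32))
        train(cfg, TrainConfig(**{**SHORT, "epochs": 2}), small_pairs,
              out_dir=tmp_path)
        assert (tmp_path / "best.npz").exists()
        assert (tmp_path / "last.npz").exists()
        log = (tmp_path / "train_log.csv").read_text().splitlines()
        assert log[0].startswith("epoch,train_loss,lr,val_mdice")
        assert len(log) == 3


class TestEvaluatePredict:
    def test_evaluation_is_deterministic(self, small_pairs, tiny_cfg):
        model = build_model(dataclasses.replace(
            tiny_cfg, ref_input_size=(32, 32)), seed=0)
        a = evaluate(model, small_pairs)
        b = evaluate(model, small_pairs)
        assert a.per_image == b.per_image

    def test_empty_dataset_rejected(self, tiny_cfg):
        model = build_model(tiny_cfg, seed=0)
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, [])

    def test_predict_writes_masks_and_overlays(self, small_pairs, tiny_cfg,
                                               tmp_path):
        save_dataset(small_pairs[:3], tmp_path / "data")
        model = build_model(dataclasses.replace(
            tiny_cfg, ref_input_size=(32, 32)), seed=0)
        images = sorted((tmp_path / "data" / "images").iterdir())
        records = predict(model, images, tmp_path / "out", input_size=(32, 32))
        assert len(records) == 3
        from PIL import Image
        for r in records:
            assert "error" not in r
            mask = np.asarray(Image.open(r["mask"]))
            assert set(np.unique(mask)) <= {0, 255}
            assert (tmp_path / "out" / r["overlay"].split("/")[-1]).exists()

    def test_predict_skips_unreadable_file(self, tiny_cfg, tmp_path):
        bad = tmp_path / "junk.png"
        bad.write_bytes(b"not an image")
        model = build_model(dataclasses.replace(
            tiny_cfg, ref_input_size=(32, 32)), seed=0)
        records = predict(model, [bad], tmp_path / "out", input_size=(32, 32))
        assert len(records) == 1 and "error" in records[0]

    def test_overlay_probabilities_match_forward(self, small_pairs, tiny_cfg):
        from polypseg.training import predict_probabilities
        model = build_model(dataclasses.replace(
            tiny_cfg, ref_input_size=(32, 32)), seed=0)
        maps = predict_probabilities(model, [small_pairs[0].image])
        again = predict_probabilities(model, [small_pairs[0].image])
        np.testing.assert_array_equal(maps[0], again[0])
        assert maps[0].shape == (32, 32)
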