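"""Schedule, training loop, checkpointing, evaluation, prediction, CLI."""

import numpy as np
import pytest

from mfel import MFEL, TrainConfig
from mfel.engine import (
    evaluate,
    evaluate_model,
    load_checkpoint,
    lr_at,
    model_from_checkpoint,
    predict,
    train,
)

from conftest import tiny_config


class TestSchedule:
    def test_warmup_starts_at_final_rate(self):
        cfg = TrainConfig()
        assert lr_at(0, cfg) == pytest.approx(1e-5)

    def test_warmup_reaches_initial_rate(self):
        cfg = TrainConfig()
        assert lr_at(cfg.warmup_epochs, cfg) == pytest.approx(1e-3)

    def test_last_epoch_decays_to_final_rate(self):
        cfg = TrainConfig()
        assert lr_at(cfg.epochs - 1, cfg) == pytest.approx(1e-5, abs=1e-12)

    def test_cosine_midpoint_value(self):
        cfg = TrainConfig()  # warmup 5, epochs 150: midpoint at epoch 77
        assert lr_at(77, cfg) == pytest.approx(5.05e-4, abs=1e-12)

    def test_monotone_decay_after_warmup(self):
        cfg = TrainConfig()
        rates = [lr_at(e, cfg) for e in range(cfg.warmup_epochs, cfg.epochs)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_out_of_range_epoch_rejected(self):
        cfg = TrainConfig()
        with pytest.raises(ValueError):
            lr_at(cfg.epochs, cfg)
        with pytest.raises(ValueError):
            lr_at(-1, cfg)


class TestTrainLoop:
    def test_smoke_run_logs_all_components(self, small_samples, tmp_path):
        cfg = tiny_config(epochs=2)
        res = train(cfg, small_samples, out_dir=tmp_path)
        assert len(res.history) == 2
        for h in res.history:
            for key in ("Lf", "Lb", "Ls", "Lrec", "Lbce", "Ldice", "Lmask", "Ltotal"):
                assert np.isfinite(h[key])
        assert (tmp_path / "losses.csv").exists()
        assert (tmp_path / "checkpoint.npz").exists()

    def test_empty_dataset_rejected(self, tiny_cfg):
        with pytest.raises(ValueError):
            train(tiny_cfg, [])

    def test_reconstruction_loss_components_are_positive(self, small_samples, tiny_cfg):
        res = train(tiny_cfg, small_samples)
        assert res.history[0]["Lrec"] > 0
        assert res.history[0]["Lmask"] > 0

    def test_summary_mentions_configuration(self, small_samples):
        res = train(tiny_config(epochs=2), small_samples)
        text = res.summary()
        assert "ablation" in text and "Ltotal" in text


class TestDeterminismAndResume:
    def test_same_seed_same_trajectory_and_weights(self, small_samples):
        a = train(tiny_config(epochs=2), small_samples)
        b = train(tiny_config(epochs=2), small_samples)
        assert a.loss_trajectory().tolist() == b.loss_trajectory().tolist()
        sa, sb = a.model.state_dict(), b.model.state_dict()
        assert all(np.array_equal(sa[k], sb[k]) for k in sa)

    def test_different_seed_changes_trajectory(self, small_samples):
        a = train(tiny_config(epochs=2, seed=5), small_samples)
        b = train(tiny_config(epochs=2, seed=6), small_samples)
        assert a.loss_trajectory().tolist() != b.loss_trajectory().tolist()

    def test_resume_preserves_trajectory_bitwise(self, small_samples, tmp_path):
        cfg = tiny_config(epochs=4)
        full = train(cfg, small_samples)
        part = train(tiny_config(epochs=4), small_samples,
                     out_dir=tmp_path / "part", stop_after_epoch=1)
        assert len(part.history) == 2
        resumed = train(tiny_config(epochs=4), small_samples,
                        resume_from=tmp_path / "part" / "checkpoint.npz")
        joint = part.history + resumed.history
        assert [h["Ltotal"] for h in joint] == [h["Ltotal"] for h in full.history]
        sa, sb = full.model.state_dict(), resumed.model.state_dict()
        assert all(np.array_equal(sa[k], sb[k]) for k in sa)

    def test_resume_with_wrong_config_rejected(self, small_samples, tmp_path):
        train(tiny_config(epochs=3), small_samples,
              out_dir=tmp_path, stop_after_epoch=0)
        with pytest.raises(ValueError, match="config"):
            train(tiny_config(epochs=3, lr_init=5e-4), small_samples,
                  resume_from=tmp_path / "checkpoint.npz")


class TestCheckpointIO:
    def test_round_trip_restores_identical_predictions(self, small_samples, tmp_path):
        res = train(tiny_config(epochs=2), small_samples, out_dir=tmp_path)
        restored = model_from_checkpoint(tmp_path / "checkpoint.npz")
        for s in small_samples[:2]:
            assert np.array_equal(res.model.predict_proba(s), restored.predict_proba(s))

    def test_sidecar_records_config_hash(self, small_samples, tmp_path):
        cfg = tiny_config(epochs=2)
        train(cfg, small_samples, out_dir=tmp_path)
        ckpt = load_checkpoint(tmp_path / "checkpoint.npz")
        assert ckpt["sidecar"]["config_hash"] == cfg.hash()


@pytest.fixture(scope="module")
def run(small_samples, tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    res = train(tiny_config(epochs=2), small_samples, out_dir=out)
    return res, out


class TestEvaluatePredict:
    def test_evaluation_is_deterministic(self, run, small_samples):
        res, _ = run
        a = evaluate_model(res.model, small_samples)
        b = evaluate_model(res.model, small_samples)
        assert a["mean"] == b["mean"]

    def test_evaluation_never_reads_masks_for_inference(self, run, small_samples):
        from mfel.data_io import ImageSample

        res, _ = run
        labeled = small_samples[0]
        unlabeled = ImageSample(id=labeled.id, image=labeled.image, mask=None)
        pa = res.model.predict_proba(labeled)
        pb = res.model.predict_proba(unlabeled)
        assert np.array_equal(pa, pb)

    def test_cross_dataset_evaluation_runs(self, run):
        from mfel import FixtureSpec, generate_fixtures

        res, _ = run
        other = generate_fixtures(FixtureSpec(n_samples=2, size=32, seed=99))
        out = evaluate_model(res.model, other)
        assert out["n_images"] == 2

    def test_evaluate_writes_csv_and_json(self, run, small_samples, tmp_path):
        _, out = run
        result = evaluate(out / "checkpoint.npz", small_samples, out_dir=tmp_path)
        assert (tmp_path / "metrics.csv").exists()
        assert (tmp_path / "summary.json").exists()
        assert set(result["mean"]) == {"precision", "recall", "f1", "iou"}

    def test_predict_writes_one_mask_per_image_plus_overlays(self, run, small_samples, tmp_path):
        from mfel.data_io import load_mask

        _, out = run
        written = predict(out / "checkpoint.npz", small_samples, tmp_path)
        assert len(written) == len(small_samples)
        for s in small_samples:
            m = load_mask(tmp_path / f"{s.id}_mask.png")
            assert set(np.unique(m)) <= {0.0, 1.0}
            assert (tmp_path / f"{s.id}_overlay.png").exists()

    def test_overlay_pixels_match_confusion_sets(self, run, small_samples):
        from mfel.objectives import confusion, error_overlay

        res, _ = run
        s = small_samples[0]
        pred = res.model.predict_mask(s)
        overlay = error_overlay(pred, s.mask, s.image)
        changed = np.any(overlay != s.image, axis=0)
        c = confusion(pred, s.mask)
        assert int(changed.sum()) == c.FP + c.FN


class TestModelObject:
    def test_from_samples_infers_working_size(self, small_samples):
        model = MFEL.from_samples(small_samples, epochs=2, warmup_epochs=1,
                                  stage_channels=(4, 8, 16), state_dim=4)
        assert model.config.working_size == 32

    def test_fit_returns_result_with_model(self, small_samples):
        model = MFEL(tiny_config(epochs=2))
        res = model.fit(small_samples)
        assert res.model is model
        assert res.n_steps == 2 * 2  # 4 samples / batch 2, 2 epochs


class TestCLI:
    def test_fixture_train_evaluate_predict_pipeline(self, tmp_path):
        from click.testing import CliRunner
        import yaml

        from mfel.cli import main

        runner = CliRunner()
        data = tmp_path / "data"
        r = runner.invoke(main, ["make-fixtures", "--out", str(data),
                                 "--n-samples", "2", "--size", "32", "--seed", "1"])
        assert r.exit_code == 0, r.output
        cfg = tiny_config(epochs=2).as_dict()
        (tmp_path / "cfg.yaml").write_text(yaml.safe_dump(cfg))
        r = runner.invoke(main, ["train", "--config", str(tmp_path / "cfg.yaml"),
                                 "--data", str(data), "--out", str(tmp_path / "run")])
        assert r.exit_code == 0, r.output
        ckpt = tmp_path / "run" / "checkpoint.npz"
        r = runner.invoke(main, ["evaluate", "--ckpt", str(ckpt), "--data", str(data),
                                 "--out", str(tmp_path / "eval")])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["predict", "--ckpt", str(ckpt),
                                 "--images", str(data / "images"),
                                 "--out", str(tmp_path / "preds"),
                                 "--gt", str(data / "masks")])
        assert r.exit_code == 0, r.output
        assert len(list((tmp_path / "preds").glob("*_mask.png"))) == 2
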