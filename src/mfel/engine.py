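"""Training/evaluation/prediction engine: schedules, checkpoints, runs.

The optimization regime: Adam (beta1=0.9, beta2=0.999), batch size 4, a
linear learning-rate warm-up from ``lr_final`` to ``lr_init`` over the first
``warmup_epochs`` epochs, then cosine annealing back down to ``lr_final`` by
the last epoch. Runs are bitwise-reproducible from one integer seed, and a
checkpoint stores everything needed for trajectory-preserving resume (model
weights, Adam moments, epoch counter, shuffling RNG state).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from . import objectives
from .config import TrainConfig, ABLATIONS
from .data_io import ImageSample, write_prediction
from .model import MFEL, FitResult
from .nn import Adam

__all__ = [
    "TrainConfig",
    "ABLATIONS",
    "lr_at",
    "train",
    "evaluate_model",
    "evaluate",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
    "model_from_checkpoint",
]


def lr_at(epoch: int, config: TrainConfig) -> float:
    """Learning rate at a 0-based epoch index.

    Linear ramp lr_final -> lr_init over the warm-up, then cosine decay
    lr_init -> lr_final over the remaining epochs:
    lr = lr_final + 0.5*(lr_init - lr_final)*(1 + cos(pi * t)).
    """
    if not 0 <= epoch < config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    if epoch < config.warmup_epochs:
        return config.lr_final + (config.lr_init - config.lr_final) * (
            epoch / config.warmup_epochs
        )
    span = config.epochs - 1 - config.warmup_epochs
    t = (epoch - config.warmup_epochs) / span if span > 0 else 1.0
    return config.lr_final + 0.5 * (config.lr_init - config.lr_final) * (
        1.0 + np.cos(np.pi * t)
    )


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(path, model: MFEL, optimizer: Adam, epoch: int,
                    shuffle_state: dict, n_steps: int) -> None:
    """Serialize model + optimizer + RNG into one .npz with a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"model::{k}": v for k, v in model.state_dict().items()}
    opt = optimizer.state_dict()
    for k, v in opt.items():
        if k == "t":
            continue
        arrays[f"opt::{k}"] = v
    np.savez(path, **arrays)
    sidecar = {
        "config": model.config.as_dict(),
        "config_hash": model.config.hash(),
        "epoch": epoch,
        "n_steps": n_steps,
        "adam_t": optimizer.state_dict()["t"],
        "shuffle_state": shuffle_state,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)


def load_checkpoint(path) -> dict:
    path = Path(path)
    with np.load(path) as npz:
        arrays = {k: npz[k].copy() for k in npz.files}
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    return {"arrays": arrays, "sidecar": sidecar}


def model_from_checkpoint(path) -> MFEL:
    ckpt = load_checkpoint(path)
    cfg = dict(ckpt["sidecar"]["config"])
    config = TrainConfig(**cfg)
    model = MFEL(config)
    model.load_state_dict(
        {k[len("model::"):]: v for k, v in ckpt["arrays"].items() if k.startswith("model::")}
    )
    return model


def _restore_shuffle_state(state: dict) -> np.random.Generator:
    gen = np.random.Generator(np.random.PCG64())
    st = {
        "bit_generator": "PCG64",
        "state": {"state": int(state["state"]), "inc": int(state["inc"])},
        "has_uint32": int(state["has_uint32"]),
        "uinteger": int(state["uinteger"]),
    }
    gen.bit_generator.state = st
    return gen


def _shuffle_state(gen: np.random.Generator) -> dict:
    st = gen.bit_generator.state
    return {
        "state": str(st["state"]["state"]),
        "inc": str(st["state"]["inc"]),
        "has_uint32": st["has_uint32"],
        "uinteger": st["uinteger"],
    }


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train(config: TrainConfig, dataset: list[ImageSample], model: MFEL | None = None,
          out_dir=None, resume_from=None, progress: bool = False,
          stop_after_epoch: int | None = None) -> FitResult:
    """Run the optimization loop; returns a :class:`FitResult`.

    ``stop_after_epoch`` interrupts the run after that 0-based epoch (the
    learning-rate schedule still spans the full ``config.epochs``), writing
    a checkpoint a later call can ``resume_from`` with an identical
    trajectory to an uninterrupted run.

    Each step averages the composite loss over one shuffled mini-batch and
    applies a single Adam update at the scheduled learning rate. All eight
    loss components are logged per epoch (epoch means). A non-finite loss
    aborts with a diagnostic naming the offending component.
    """
    if not dataset:
        raise ValueError("training requires a nonempty dataset")
    for s in dataset:
        if s.mask is None:
            raise ValueError(f"sample {s.id} has no mask; training requires labels")

    if model is None:
        model = MFEL(config)
    else:
        config = model.config

    named = list(model.named_parameters())
    optimizer = Adam(named, lr=config.lr_init)
    shuffle_rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([config.seed, 1]))
    )
    start_epoch = 0
    n_steps = 0
    history: list[dict] = []

    if resume_from is not None:
        ckpt = load_checkpoint(resume_from)
        side = ckpt["sidecar"]
        if side["config_hash"] != config.hash():
            raise ValueError("checkpoint config does not match the current config")
        model.load_state_dict(
            {k[len("model::"):]: v for k, v in ckpt["arrays"].items()
             if k.startswith("model::")}
        )
        opt_state = {"t": side["adam_t"]}
        opt_state.update(
            {k[len("opt::"):]: v for k, v in ckpt["arrays"].items() if k.startswith("opt::")}
        )
        optimizer.load_state_dict(opt_state)
        shuffle_rng = _restore_shuffle_state(side["shuffle_state"])
        start_epoch = side["epoch"] + 1
        n_steps = side["n_steps"]

    grad_flags = {name: False for name, _ in named}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    loss_keys = ("Lf", "Lb", "Ls", "Lrec", "Lbce", "Ldice", "Lmask", "Ltotal")
    stop = config.epochs if stop_after_epoch is None else min(config.epochs,
                                                              stop_after_epoch + 1)
    iterator = range(start_epoch, stop)
    if progress:
        iterator = _progress(iterator, total=stop - start_epoch)

    for epoch in iterator:
        lr = lr_at(epoch, config)
        optimizer.lr = lr
        order = shuffle_rng.permutation(len(dataset))
        epoch_logs: list[objectives.BatchLosses] = []
        for b0 in range(0, len(dataset), config.batch_size):
            batch = [dataset[i] for i in order[b0:b0 + config.batch_size]]
            model.zero_grad()
            total = None
            for sample in batch:
                ltotal, log, _ = model.forward_train(sample)
                _check_finite(log)
                total = ltotal if total is None else total + ltotal
                epoch_logs.append(log)
            (total * (1.0 / len(batch))).backward()
            if config.grad_clip is not None:
                _clip_gradients(named, config.grad_clip)
            if config.weight_decay:
                for _, p in named:
                    if p.grad is not None:
                        p.grad += config.weight_decay * p.data
            for name, p in named:
                if not grad_flags[name] and p.grad is not None and np.any(p.grad != 0):
                    grad_flags[name] = True
            optimizer.step()
            n_steps += 1
        means = {k: float(np.mean([getattr(l, k) for l in epoch_logs])) for k in loss_keys}
        means["epoch"] = epoch
        means["lr"] = lr
        history.append(means)

    ckpt_path = None
    if out_dir is not None:
        ckpt_path = out_dir / "checkpoint.npz"
        save_checkpoint(ckpt_path, model, optimizer, stop - 1,
                        _shuffle_state(shuffle_rng), n_steps)
        _write_history(history, out_dir / "losses.csv")
    result = FitResult(
        model=model, config=config, history=history, grad_flags=grad_flags,
        checkpoint_path=str(ckpt_path) if ckpt_path else None, n_steps=n_steps,
    )
    # stash optimizer/rng so callers (tests, resume helpers) can checkpoint mid-run
    result._optimizer = optimizer
    result._shuffle_rng = shuffle_rng
    return result


def _check_finite(log: objectives.BatchLosses) -> None:
    for key, val in log.as_dict().items():
        if not np.isfinite(val):
            raise RuntimeError(f"non-finite loss component {key}: {val}")


def _clip_gradients(named, max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(p.grad**2)) for _, p in named if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for _, p in named:
            if p.grad is not None:
                p.grad *= scale


def _write_history(history: list[dict], path) -> None:
    if not history:
        return
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(history[0].keys()))
        w.writeheader()
        w.writerows(history)


def _progress(it, total):
    try:
        from tqdm import tqdm

        return tqdm(it, total=total)
    except ImportError:  # tqdm is optional
        return it


# ---------------------------------------------------------------------------
# evaluation / prediction
# ---------------------------------------------------------------------------


def evaluate_model(model: MFEL, dataset: list[ImageSample],
                   threshold: float = 0.5) -> dict:
    """Inference-mode evaluation (masks used only as ground truth)."""
    if not dataset:
        raise ValueError("evaluation requires a nonempty dataset")
    pairs, ids, probs = [], [], {}
    for s in dataset:
        prob = model.predict_proba(s)
        probs[s.id] = prob
        if s.mask is not None:
            pairs.append(((prob >= threshold).astype(np.float64), s.mask))
            ids.append(s.id)
    if not pairs:
        import warnings

        warnings.warn("no ground-truth masks available; metrics skipped", stacklevel=2)
        return {"per_image": [], "mean": None, "global_pooled": None,
                "n_images": 0, "probabilities": probs}
    result = objectives.evaluate_dataset(pairs, ids)
    result["probabilities"] = probs
    return result


def evaluate(checkpoint_path, dataset: list[ImageSample], out_dir=None) -> dict:
    """Load a checkpoint, evaluate, optionally emit metrics CSV + JSON."""
    model = model_from_checkpoint(checkpoint_path)
    result = evaluate_model(model, dataset)
    if out_dir is not None and result["mean"] is not None:
        objectives.write_evaluation(result, out_dir)
    return result


def predict(checkpoint_path, samples: list[ImageSample], out_dir,
            with_overlays: bool = True) -> list[str]:
    """Write binary mask PNGs (and error overlays where GT exists)."""
    from PIL import Image

    model = model_from_checkpoint(checkpoint_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for s in samples:
        pred = model.predict_mask(s)
        mask_path = out_dir / f"{s.id}_mask.png"
        write_prediction(pred, mask_path)
        written.append(str(mask_path))
        if with_overlays and s.mask is not None:
            overlay = objectives.error_overlay(pred, s.mask, s.image)
            arr = (overlay * 255).round().astype(np.uint8).transpose(1, 2, 0)
            Image.fromarray(arr, mode="RGB").save(out_dir / f"{s.id}_overlay.png")
    return written
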