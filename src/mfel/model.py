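"""The dual-task segmentation model and its fit results.

:class:`MFEL` couples the self-supervised reconstruction branch with the
segmentation branch under the additive composite loss. The object follows
the model/results idiom: build the model from a config (optionally straight
from a dataset via :meth:`MFEL.from_samples`), call :meth:`fit`, and receive
a :class:`FitResult` holding the loss trajectories, gradient-flow diagnostics
and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn, objectives
from .autograd import Tensor, use_dtype
from .config import TrainConfig
from .data_io import ImageSample
from .fiir import EncoderConfig, ReconstructionBranch
from .fris import SegmentationBranch

__all__ = ["MFEL", "FitResult"]


class MFEL(nn.Module):
    """Multi-interactive feature embedding model for lesion segmentation.

    Training mode runs both branches: the image is decomposed by its mask,
    reconstructed three ways (foreground / background / whole), and the
    calibrated pixel-level pyramid feeds the segmentation branch through the
    bi-directional fusion modules. Inference mode needs no mask: the
    whole-image encoder's pyramid passes to the segmentation branch
    uncalibrated (the modulation layers are zero-initialized, so at step 0
    both regimes see identical features).
    """

    def __init__(self, config: TrainConfig):
        self.config = config
        ss = np.random.SeedSequence([config.seed, 0])
        rng = np.random.Generator(np.random.PCG64(ss))
        enc_cfg = EncoderConfig(in_channels=3, stage_channels=config.stage_channels)
        with use_dtype(config.precision):
            self.recon = ReconstructionBranch(enc_cfg, rng, fusion_mode=config.afm_mode)
            self.seg = SegmentationBranch(
                enc_cfg,
                rng,
                fusion_mode=config.bfm_mode,
                use_ssm=config.use_ssm,
                state_dim=config.state_dim,
                attention_scale=config.attention_scale,
            )

    @classmethod
    def from_samples(cls, samples: list[ImageSample], **config_kw) -> "MFEL":
        """Build a model sized to a dataset's working resolution."""
        if not samples:
            raise ValueError("need at least one sample")
        h = samples[0].image.shape[1]
        config_kw.setdefault("working_size", h)
        return cls(TrainConfig(**config_kw))

    # -- forward passes ----------------------------------------------------
    def forward_train(self, sample: ImageSample) -> tuple[Tensor, objectives.BatchLosses, Tensor]:
        """One training forward pass; returns (loss graph, logged floats, prob)."""
        with use_dtype(self.config.precision):
            return self._forward_train(sample)

    def _forward_train(self, sample: ImageSample):
        red = self.config.reduction
        if self.config.fiir_enabled:
            out = self.recon.forward_train(sample)
            lf = objectives.l1_loss(out["recon_fore"], out["targets"]["foreground"], red)
            lb = objectives.l1_loss(out["recon_back"], out["targets"]["background"], red)
            ls = objectives.l1_loss(out["recon_whole"], out["targets"]["whole"], red)
            pyramid = out["pyramid"]
        else:
            lf = lb = ls = None
            pyramid = None
        prob = self.seg(sample.image, pyramid)
        lbce = objectives.bce_loss(prob, sample.mask)
        ldice = objectives.dice_loss(prob, sample.mask)
        ltotal, log = objectives.total_loss(
            lf, lb, ls, lbce, ldice, reconstruction_enabled=self.config.fiir_enabled
        )
        return ltotal, log, prob

    def forward_infer(self, image: np.ndarray) -> Tensor:
        """Mask-free inference: per-pixel foreground probability [1,H,W]."""
        with use_dtype(self.config.precision):
            pyramid = self.recon.forward_infer(image) if self.config.fiir_enabled else None
            return self.seg(image, pyramid)

    def predict_proba(self, sample: ImageSample) -> np.ndarray:
        return self.forward_infer(sample.image).data

    def predict_mask(self, sample: ImageSample, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(sample) >= threshold).astype(np.float64)

    # -- estimation ---------------------------------------------------------
    def fit(self, samples: list[ImageSample], out_dir=None, resume_from=None,
            progress: bool = False) -> "FitResult":
        from .engine import train  # engine drives the optimization loop

        return train(self.config, samples, model=self, out_dir=out_dir,
                     resume_from=resume_from, progress=progress)

    def evaluate(self, samples: list[ImageSample]) -> dict:
        from .engine import evaluate_model

        return evaluate_model(self, samples)


@dataclass
class FitResult:
    """Outcome of one training run."""

    model: MFEL
    config: TrainConfig
    history: list[dict] = field(default_factory=list)  # per-epoch mean losses + lr
    grad_flags: dict[str, bool] = field(default_factory=dict)
    checkpoint_path: str | None = None
    n_steps: int = 0

    @property
    def final_losses(self) -> dict:
        return self.history[-1] if self.history else {}

    def loss_trajectory(self, key: str = "Ltotal") -> np.ndarray:
        return np.array([h[key] for h in self.history])

    def evaluate(self, samples: list[ImageSample]) -> dict:
        return self.model.evaluate(samples)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Dual-task lesion segmentation fit",
            "=" * 45,
            f"{'ablation variant':<28}{cfg.ablation}",
            f"{'epochs / batch size':<28}{cfg.epochs} / {cfg.batch_size}",
            f"{'optimizer steps taken':<28}{self.n_steps}",
            f"{'working resolution':<28}{cfg.working_size}",
            f"{'encoder stage channels':<28}{cfg.stage_channels}",
            f"{'trainable parameters':<28}{self.model.num_parameters()}",
            f"{'seed':<28}{cfg.seed}",
            "-" * 45,
        ]
        if self.history:
            first, last = self.history[0], self.history[-1]
            for key in ("Lf", "Lb", "Ls", "Lrec", "Lbce", "Ldice", "Lmask", "Ltotal"):
                lines.append(f"{key + ' (first -> last epoch)':<28}"
                             f"{first[key]:.4f} -> {last[key]:.4f}")
        lines.append("=" * 45)
        return "\n".join(lines)
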