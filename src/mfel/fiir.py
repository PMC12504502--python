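"""Self-supervised reconstruction branch with adaptive feature modulation.

During training the input image is split by its ground-truth mask into a
foreground image and a background image (see :func:`mfel.data_io.decompose`);
three encoders with shared architecture but independent weights extract
pyramids from the foreground, background and whole image. At each pyramid
level an adaptive feature modulation (AFM) block pools the concatenation of
the three features and emits per-channel calibration parameters (alpha,
beta) that rescale the whole-image feature:

    F_hat = (1 + alpha) * F + beta.

Three mirror decoders reconstruct the foreground, background and whole image
under L1 losses, forcing the calibrated pyramid to carry pixel-level detail
(texture, edges) that the segmentation branch then consumes.

The ground-truth mask exists only at training time, so foreground/background
reconstruction and AFM calibration are training-only: at inference the
whole-image encoder's pyramid passes through uncalibrated. The AFM output
layers are zero-initialized, making calibration exactly the identity at
step 0, so the segmentation branch sees the same feature distribution in
both regimes at the start of training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor, concat
from .data_io import ImageSample, decompose

__all__ = [
    "EncoderConfig",
    "Encoder",
    "ReconstructionDecoder",
    "AdaptiveModulation",
    "ReconstructionBranch",
]


@dataclass(frozen=True)
class EncoderConfig:
    in_channels: int = 3
    stage_channels: tuple[int, int, int] = (32, 64, 128)

    def __post_init__(self):
        if len(self.stage_channels) != 3:
            raise ValueError("exactly three encoder stages are required")


class Encoder(nn.Module):
    """Three-stage convolutional encoder; each stage halves H and W.

    Stage = two (3x3 conv, channel norm, ReLU) blocks followed by 2x2
    average-pool downsampling, so level i has shape [C_i, H/2^i, W/2^i].
    """

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        self.stages = []
        in_ch = config.in_channels
        for out_ch in config.stage_channels:
            stage = _ConvStage(in_ch, out_ch, rng)
            self.stages.append(stage)
            in_ch = out_ch

    def __call__(self, image: Tensor | np.ndarray) -> list[Tensor]:
        x = image if isinstance(image, Tensor) else Tensor(image)
        if x.shape[1] % 8 or x.shape[2] % 8:
            raise ValueError(f"spatial size {x.shape[1:]} must be divisible by 8")
        levels = []
        for stage in self.stages:
            x = stage(x)
            levels.append(x)
        return levels


class _ConvStage(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng)
        self.norm1 = nn.ChannelNorm(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng)
        self.norm2 = nn.ChannelNorm(out_ch)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(self.conv1(x)).relu()
        x = self.norm2(self.conv2(x)).relu()
        return x.avg_pool2x()


class ReconstructionDecoder(nn.Module):
    """Mirror decoder: 2x bilinear upsampling with skip concatenation.

    Takes a three-level pyramid and produces an image-shaped [out_ch, H, W]
    output squashed into [0,1] by a logistic nonlinearity.
    """

    def __init__(self, config: EncoderConfig, rng: np.random.Generator, out_ch: int = 3):
        c1, c2, c3 = config.stage_channels
        self.up2 = _UpBlock(c3 + c2, c2, rng)   # H/8 -> H/4, skip level 2
        self.up1 = _UpBlock(c2 + c1, c1, rng)   # H/4 -> H/2, skip level 1
        self.up0 = _UpBlock(c1, c1, rng)        # H/2 -> H, no skip
        self.head = nn.Conv2d(c1, out_ch, 1, rng)

    def __call__(self, pyramid: list[Tensor]) -> Tensor:
        f1, f2, f3 = pyramid
        x = self.up2(f3, skip=f2)
        x = self.up1(x, skip=f1)
        x = self.up0(x, skip=None)
        return self.head(x).sigmoid()


class _UpBlock(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.conv = nn.Conv2d(in_ch, out_ch, 3, rng)
        self.norm = nn.ChannelNorm(out_ch)

    def __call__(self, x: Tensor, skip: Tensor | None) -> Tensor:
        x = x.upsample_bilinear2x()
        if skip is not None:
            x = concat([x, skip], axis=0)
        return self.norm(self.conv(x)).relu()


class AdaptiveModulation(nn.Module):
    """Per-level AFM block emitting per-channel (alpha, beta).

    The three same-shaped features (foreground, background, whole-image) are
    concatenated on channels, globally average-pooled, and passed through two
    parallel 1x1-conv streams (hidden width C, ReLU between) whose final
    layers are zero-initialized — calibration starts as the identity.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        self.channels = channels
        self.alpha_in = nn.Conv2d(3 * channels, channels, 1, rng)
        self.alpha_out = nn.Conv2d(channels, channels, 1, rng, zero_init=True)
        self.beta_in = nn.Conv2d(3 * channels, channels, 1, rng)
        self.beta_out = nn.Conv2d(channels, channels, 1, rng, zero_init=True)

    def parameters_of(self, f_fore: Tensor, f_back: Tensor, f_rec: Tensor) -> tuple[Tensor, Tensor]:
        if not (f_fore.shape == f_back.shape == f_rec.shape):
            raise ValueError(
                f"AFM inputs must share shape: {f_fore.shape}, {f_back.shape}, {f_rec.shape}"
            )
        fused = concat([f_fore, f_back, f_rec], axis=0)
        pooled = fused.mean(axis=(1, 2), keepdims=True)  # [3C, 1, 1]
        alpha = self.alpha_out(self.alpha_in(pooled).relu())
        beta = self.beta_out(self.beta_in(pooled).relu())
        return alpha, beta

    @staticmethod
    def calibrate(f_rec: Tensor, alpha: Tensor, beta: Tensor) -> Tensor:
        if alpha.shape[0] != f_rec.shape[0]:
            raise ValueError(
                f"channel mismatch: feature {f_rec.shape[0]}, params {alpha.shape[0]}"
            )
        return (1.0 + alpha) * f_rec + beta

    def __call__(self, f_fore: Tensor, f_back: Tensor, f_rec: Tensor) -> Tensor:
        alpha, beta = self.parameters_of(f_fore, f_back, f_rec)
        return self.calibrate(f_rec, alpha, beta)


class _SummaryCombine(nn.Module):
    """Ablation variant: combine the three features by elementwise addition."""

    def __call__(self, f_fore: Tensor, f_back: Tensor, f_rec: Tensor) -> Tensor:
        return f_fore + f_back + f_rec


class _ConcatCombine(nn.Module):
    """Ablation variant: channel concatenation + 1x1 conv back to C channels."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.reduce = nn.Conv2d(3 * channels, channels, 1, rng)

    def __call__(self, f_fore: Tensor, f_back: Tensor, f_rec: Tensor) -> Tensor:
        return self.reduce(concat([f_fore, f_back, f_rec], axis=0))


class ReconstructionBranch(nn.Module):
    """Foreground/background/whole-image encoders, AFM, and three decoders.

    ``fusion_mode`` selects how foreground/background features refine the
    whole-image feature: "afm" (default), or the ablation variants
    "summary" / "concat".
    """

    def __init__(self, config: EncoderConfig, rng: np.random.Generator,
                 fusion_mode: str = "afm"):
        if fusion_mode not in ("afm", "summary", "concat"):
            raise ValueError(f"unknown fusion mode {fusion_mode!r}")
        self.config = config
        self.fusion_mode = fusion_mode
        self.enc_fore = Encoder(config, rng)
        self.enc_back = Encoder(config, rng)
        self.enc_whole = Encoder(config, rng)
        if fusion_mode == "afm":
            self.fusers = [AdaptiveModulation(c, rng) for c in config.stage_channels]
        elif fusion_mode == "summary":
            self.fusers = [_SummaryCombine() for _ in config.stage_channels]
        else:
            self.fusers = [_ConcatCombine(c, rng) for c in config.stage_channels]
        self.dec_fore = ReconstructionDecoder(config, rng)
        self.dec_back = ReconstructionDecoder(config, rng)
        self.dec_whole = ReconstructionDecoder(config, rng)

    def forward_train(self, sample: ImageSample) -> dict:
        """Full training pass: reconstructions + calibrated pyramid."""
        if sample.mask is None:
            raise ValueError("training-mode reconstruction requires a ground-truth mask")
        dec = decompose(sample)
        pyr_fore = self.enc_fore(dec.foreground)
        pyr_back = self.enc_back(dec.background)
        pyr_whole = self.enc_whole(sample.image)
        calibrated = [
            fuse(ff, fb, fr)
            for fuse, ff, fb, fr in zip(self.fusers, pyr_fore, pyr_back, pyr_whole)
        ]
        return {
            "recon_fore": self.dec_fore(pyr_fore),
            "recon_back": self.dec_back(pyr_back),
            "recon_whole": self.dec_whole(calibrated),
            "pyramid": calibrated,
            "targets": {"foreground": dec.foreground, "background": dec.background,
                        "whole": sample.image},
        }

    def forward_infer(self, image: Tensor | np.ndarray) -> list[Tensor]:
        """Inference pass: whole-image pyramid only, no mask, no calibration."""
        return self.enc_whole(image)

    def forward(self, sample: ImageSample, training: bool) -> dict:
        if training:
            return self.forward_train(sample)
        return {"pyramid": self.forward_infer(sample.image)}
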