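"""Training configuration and ablation switches."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

ABLATIONS = (
    "full",        # complete model
    "no_fiir",     # reconstruction branch disabled; segmentation alone
    "afm_summary",  # adaptive modulation replaced by elementwise addition
    "afm_concat",  # adaptive modulation replaced by concat + 1x1 conv
    "bfm_summary",  # cross-attention fusion replaced by elementwise addition
    "bfm_concat",  # cross-attention fusion replaced by concat + 1x1 conv
    "no_mamba",    # multi-branch state-space block bypassed with identity
)


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    Defaults follow the published regime: 150 epochs, batch 4, Adam with a
    warm-up then cosine-annealed learning rate from 1e-3 down to 1e-5.
    ``working_size`` is the square resolution images are resized to: 256 for
    dermoscopy, 128 for the gland-histology preset.
    """

    epochs: int = 150
    batch_size: int = 4
    lr_init: float = 1e-3
    lr_final: float = 1e-5
    warmup_epochs: int = 5
    seed: int = 0
    working_size: int = 256
    stage_channels: tuple[int, int, int] = (32, 64, 128)
    state_dim: int = 16
    ablation: str = "full"
    attention_scale: str = "sqrt_d"  # or "d" for the raw printed divisor
    reduction: str = "mean"          # L1 reduction; "sum" for fidelity runs
    weight_decay: float = 0.0
    grad_clip: float | None = None
    precision: str = "float32"  # network precision; "float64" for strict runs

    def __post_init__(self):
        if self.precision not in ("float32", "float64"):
            raise ValueError("precision must be 'float32' or 'float64'")
        self.stage_channels = tuple(self.stage_channels)
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}, got {self.ablation!r}")
        if self.attention_scale not in ("sqrt_d", "d"):
            raise ValueError("attention_scale must be 'sqrt_d' or 'd'")
        if self.reduction not in ("mean", "sum"):
            raise ValueError("reduction must be 'mean' or 'sum'")
        if not self.warmup_epochs < self.epochs:
            raise ValueError("warmup_epochs must be < epochs")
        if not self.lr_final < self.lr_init:
            raise ValueError("lr_final must be < lr_init")

    # convenience presets for the two imaging domains
    @classmethod
    def dermoscopy(cls, **kw) -> "TrainConfig":
        return cls(working_size=256, **kw)

    @classmethod
    def histology(cls, **kw) -> "TrainConfig":
        return cls(working_size=128, **kw)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["stage_channels"] = list(self.stage_channels)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(Path(path)) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(Path(path), "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)

    # -- ablation plumbing -------------------------------------------------
    @property
    def fiir_enabled(self) -> bool:
        return self.ablation != "no_fiir"

    @property
    def afm_mode(self) -> str:
        return {"afm_summary": "summary", "afm_concat": "concat"}.get(self.ablation, "afm")

    @property
    def bfm_mode(self) -> str:
        if self.ablation == "no_fiir":
            return "none"
        return {"bfm_summary": "summary", "bfm_concat": "concat"}.get(self.ablation, "bfm")

    @property
    def use_ssm(self) -> bool:
        return self.ablation != "no_mamba"
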