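"""Segmentation branch: cross-attention fusion + multi-branch state-space block.

The segmentation encoder extracts a semantic pyramid from the input image;
at each level a bi-directional fusion module (BFM) lets the segmentation
feature and the reconstruction branch's pixel-level feature query each other
with cross-attention:

    Attn_seg = softmax(Q_s K_r^T / sqrt(d)),  Attn_rec = softmax(Q_r K_s^T / sqrt(d)),

each stream retrieves the other's values, adds the result residually to its
own feature, and the two enhanced features are concatenated and reduced by a
1x1 conv into the refined segmentation feature.

The deepest refined feature is flattened to a raster token sequence, split
into four contiguous quarters, and each quarter runs through one
weight-shared selective state-space scan (input-dependent discretization
step, B and C; diagonal A) with a learnable gamma-scaled residual; the
quarters are re-concatenated, layer-normalized and projected back. A
U-Net-style decoder over the fused pyramid emits the per-pixel foreground
probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor, as_tensor, concat, stack

__all__ = [
    "AttentionMaps",
    "BidirectionalFusion",
    "SSMParams",
    "selective_scan",
    "ssm_scan",
    "MultiBranchSSM",
    "SegmentationDecoder",
    "SegmentationBranch",
    "split_sequence",
    "flatten_map",
    "unflatten_map",
]


@dataclass
class AttentionMaps:
    """Row-stochastic cross-attention maps between the two streams."""

    attn_seg: Tensor  # [L_s, L_r] — segmentation queries retrieve reconstruction
    attn_rec: Tensor  # [L_r, L_s] — reconstruction queries retrieve segmentation
    head_dim: int


def flatten_map(x: Tensor) -> tuple[Tensor, tuple[int, int, int]]:
    """[C,h,w] -> row-major raster tokens [h*w, C]."""
    c, h, w = x.shape
    return x.reshape(c, h * w).transpose(1, 0), (c, h, w)


def unflatten_map(tokens: Tensor, origin_shape: tuple[int, int, int]) -> Tensor:
    c, h, w = origin_shape
    return tokens.transpose(1, 0).reshape(c, h, w)


def split_sequence(tokens: Tensor, n_groups: int = 4) -> list[Tensor]:
    """Split [L,C] tokens into ``n_groups`` contiguous blocks in scan order."""
    L = tokens.shape[0]
    if L % n_groups:
        raise ValueError(f"sequence length {L} not divisible by {n_groups}")
    step = L // n_groups
    return [tokens[i * step:(i + 1) * step] for i in range(n_groups)]


class BidirectionalFusion(nn.Module):
    """Per-level BFM: paired cross-attentions with residuals and 1x1 fusion.

    ``scale`` selects the attention temperature: "sqrt_d" (default,
    numerically stable) or "d" (raw channel-dimension divisor).
    """

    def __init__(self, channels: int, rng: np.random.Generator, scale: str = "sqrt_d"):
        if scale not in ("sqrt_d", "d"):
            raise ValueError(f"unknown attention scale {scale!r}")
        self.channels = channels
        self.scale = scale
        d = channels
        self.q_seg = nn.Linear(channels, d, rng)
        self.k_rec = nn.Linear(channels, d, rng)
        self.v_rec = nn.Linear(channels, d, rng)
        self.q_rec = nn.Linear(channels, d, rng)
        self.k_seg = nn.Linear(channels, d, rng)
        self.v_seg = nn.Linear(channels, d, rng)
        self.proj_seg = nn.Conv2d(d, channels, 1, rng)
        self.proj_rec = nn.Conv2d(d, channels, 1, rng)
        self.reduce = nn.Conv2d(2 * channels, channels, 1, rng)

    def attention(self, f_seg: Tensor, f_rec: Tensor) -> AttentionMaps:
        if f_seg.shape != f_rec.shape:
            raise ValueError(f"BFM shape mismatch: {f_seg.shape} vs {f_rec.shape}")
        xs, _ = flatten_map(f_seg)
        xr, _ = flatten_map(f_rec)
        d = self.channels
        denom = float(np.sqrt(d)) if self.scale == "sqrt_d" else float(d)
        attn_seg = ((self.q_seg(xs) @ self.k_rec(xr).T) * (1.0 / denom)).softmax()
        attn_rec = ((self.q_rec(xr) @ self.k_seg(xs).T) * (1.0 / denom)).softmax()
        return AttentionMaps(attn_seg=attn_seg, attn_rec=attn_rec, head_dim=d)

    def fuse(self, f_seg: Tensor, f_rec: Tensor, maps: AttentionMaps) -> Tensor:
        shape = (self.channels,) + tuple(f_seg.shape[1:])
        xs, _ = flatten_map(f_seg)
        xr, _ = flatten_map(f_rec)
        retrieved_rec = maps.attn_seg @ self.v_rec(xr)   # seg queries pull rec values
        retrieved_seg = maps.attn_rec @ self.v_seg(xs)   # rec queries pull seg values
        enh_seg = self.proj_seg(unflatten_map(retrieved_rec, shape)) + f_seg
        enh_rec = self.proj_rec(unflatten_map(retrieved_seg, shape)) + f_rec
        return self.reduce(concat([enh_seg, enh_rec], axis=0))

    def __call__(self, f_seg: Tensor, f_rec: Tensor) -> Tensor:
        return self.fuse(f_seg, f_rec, self.attention(f_seg, f_rec))


class _SummaryFusion(nn.Module):
    """Ablation variant: elementwise addition of the two streams."""

    def __call__(self, f_seg: Tensor, f_rec: Tensor) -> Tensor:
        return f_seg + f_rec


class _ConcatFusion(nn.Module):
    """Ablation variant: channel concat + 1x1 conv reduction."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.reduce = nn.Conv2d(2 * channels, channels, 1, rng)

    def __call__(self, f_seg: Tensor, f_rec: Tensor) -> Tensor:
        return self.reduce(concat([f_seg, f_rec], axis=0))


class SSMParams(nn.Module):
    """Weights of one selective state-space scan, shared across branches.

    Input-dependent discretization: delta = softplus(x W_d + b_d) per
    channel; per-token B and C of size ``state_dim``; diagonal negative A
    (S4D-real initialization) and a skip coefficient D per channel. ``gamma``
    is the residual scaling of the multi-branch block, initialized to 1.
    """

    def __init__(self, channels: int, state_dim: int, rng: np.random.Generator):
        self.channels = channels
        self.state_dim = state_dim
        self.w_delta = nn.Linear(channels, channels, rng)
        # softplus(-3) ~ 0.049: short initial step keeps the scan stable
        self.w_delta.bias.data[:] = -3.0
        self.w_B = nn.Linear(channels, state_dim, rng, bias=False)
        self.w_C = nn.Linear(channels, state_dim, rng, bias=False)
        self.A_log = nn.parameter(
            np.log(np.broadcast_to(np.arange(1, state_dim + 1, dtype=np.float64),
                                   (channels, state_dim)).copy())
        )
        self.D = nn.parameter(np.ones(channels))
        self.gamma = nn.parameter(np.array(1.0))

    def project(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor, Tensor, Tensor]:
        """Input-dependent (delta, B, C) plus the static (A, D)."""
        delta = self.w_delta(x).softplus()          # [L, C] strictly positive
        B = self.w_B(x)                             # [L, N]
        C = self.w_C(x)                             # [L, N]
        A = -self.A_log.exp()                       # [C, N], strictly negative
        return delta, B, C, A, self.D


def selective_scan(x: Tensor, delta: Tensor, A: Tensor, B: Tensor, C: Tensor,
                   D: Tensor) -> Tensor:
    """Core selective state-space recurrence.

    x: [L, C] tokens; delta: [L, C]; A: [C, N]; B, C: [L, N]; D: [C].
    Discretization: Abar_t = exp(delta_t * A), Bbar_t = delta_t * B_t;
    h_t = Abar_t h_{t-1} + Bbar_t x_t (h_0 = 0), y_t = C_t h_t + D x_t.
    Sequential scan — sequence lengths here are small (deepest level only).

    Leading batch axes are allowed (x: [..., L, C] etc.); the recurrence
    runs independently over them, sharing (A, D) and any broadcast weights.
    """
    x, delta, A, B, C, D = map(as_tensor, (x, delta, A, B, C, D))
    if not np.all(np.isfinite(x.data)):
        raise ValueError("selective_scan requires finite inputs")
    *lead, L, Cdim = x.shape
    N = A.shape[1]
    lead = tuple(lead)
    h: Tensor | None = None
    ys = []
    for t in range(L):
        idx = (Ellipsis, t, slice(None))
        xt_flat = x[idx]                                   # [..., C]
        dt = delta[idx].reshape(lead + (Cdim, 1))          # [..., C, 1]
        xt = xt_flat.reshape(lead + (Cdim, 1))             # [..., C, 1]
        Bt = B[idx].reshape(lead + (1, N))                 # [..., 1, N]
        Ct = C[idx].reshape(lead + (1, N))
        inject = (dt * Bt) * xt                            # [..., C, N]
        if h is None:
            h = inject
        else:
            h = (dt * A).exp() * h + inject
        ys.append((h * Ct).sum(axis=-1) + D * xt_flat)
    return stack(ys, axis=-2)


def ssm_scan(tokens: Tensor, params: SSMParams) -> Tensor:
    """Apply one selective scan with input-dependent projections."""
    tokens = as_tensor(tokens)
    delta, B, C, A, D = params.project(tokens)
    return selective_scan(tokens, delta, A, B, C, D)


class MultiBranchSSM(nn.Module):
    """Four-branch state-space block on the deepest fused feature.

    Flatten + layer-norm, split the raster sequence into four contiguous
    quarters, run the shared scan on each with a gamma-scaled residual,
    concatenate, layer-norm, and project back to the channel dimension.
    """

    def __init__(self, channels: int, state_dim: int, rng: np.random.Generator,
                 n_branches: int = 4):
        self.norm_in = nn.LayerNorm(channels)
        self.params = SSMParams(channels, state_dim, rng)
        self.norm_out = nn.LayerNorm(channels)
        self.proj = nn.Linear(channels, channels, rng)
        self.n_branches = n_branches

    def __call__(self, f_deep: Tensor) -> Tensor:
        tokens, origin = flatten_map(f_deep)
        ns = self.norm_in(tokens)
        L, C = ns.shape
        G = self.n_branches
        if L % G:
            raise ValueError(f"sequence length {L} not divisible by {G}")
        # contiguous quarters stacked on a batch axis; one shared scan
        branched = ns.reshape(G, L // G, C)
        refined = ssm_scan(branched, self.params) + self.params.gamma * branched
        merged = refined.reshape(L, C)  # == concat of the four quarters
        out = self.proj(self.norm_out(merged))
        return unflatten_map(out, origin)


class SegmentationDecoder(nn.Module):
    """U-Net-style decoder over the fused pyramid -> foreground probability."""

    def __init__(self, stage_channels: tuple[int, int, int], rng: np.random.Generator):
        c1, c2, c3 = stage_channels
        self.up2 = _UpBlock(c3 + c2, c2, rng)
        self.up1 = _UpBlock(c2 + c1, c1, rng)
        self.up0 = _UpBlock(c1, c1, rng)
        self.head = nn.Conv2d(c1, 1, 1, rng)

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


class SegmentationBranch(nn.Module):
    """Segmentation encoder + per-level fusion + SSM block + decoder.

    ``fusion_mode``: "bfm" (default) or the ablation variants
    "summary"/"concat"/"none" ("none" ignores the reconstruction pyramid).
    ``use_ssm=False`` bypasses the multi-branch block with the identity.
    """

    def __init__(self, config, rng: np.random.Generator, fusion_mode: str = "bfm",
                 use_ssm: bool = True, state_dim: int = 16,
                 attention_scale: str = "sqrt_d"):
        from .fiir import Encoder  # shared encoder architecture

        if fusion_mode not in ("bfm", "summary", "concat", "none"):
            raise ValueError(f"unknown fusion mode {fusion_mode!r}")
        self.config = config
        self.fusion_mode = fusion_mode
        self.use_ssm = use_ssm
        self.encoder = Encoder(config, rng)
        chans = config.stage_channels
        if fusion_mode == "bfm":
            self.fusers = [BidirectionalFusion(c, rng, scale=attention_scale) for c in chans]
        elif fusion_mode == "summary":
            self.fusers = [_SummaryFusion() for _ in chans]
        elif fusion_mode == "concat":
            self.fusers = [_ConcatFusion(c, rng) for c in chans]
        else:
            self.fusers = []
        if use_ssm:
            self.ssm_block = MultiBranchSSM(chans[2], state_dim, rng)
        self.decoder = SegmentationDecoder(chans, rng)

    def __call__(self, image: Tensor | np.ndarray,
                 recon_pyramid: list[Tensor] | None) -> Tensor:
        seg_pyramid = self.encoder(image)
        if self.fusion_mode == "none" or recon_pyramid is None:
            fused = seg_pyramid
        else:
            fused = [
                fuse(fs, fr) for fuse, fs, fr in zip(self.fusers, seg_pyramid, recon_pyramid)
            ]
        deep = self.ssm_block(fused[2]) if self.use_ssm else fused[2]
        return self.decoder([fused[0], fused[1], deep])
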