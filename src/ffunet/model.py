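"""The feature-fusion U-Net for lesion segmentation.

An encoder-decoder with three departures from a plain U-Net:

* **No pooling.** Every downsampling step is a learned 3x3 stride-2
  convolution, which preserves spatial structure and mixes channels.
* **MSFF encoder blocks.** Each block opens with a 3x3 dilated convolution
  (+ RReLU), then applies three residual splitting steps: step k keeps
  floor(C_k/3) channels through a 3x3 convolution and passes the remaining
  C_k - floor(C_k/3) through a 5x5 convolution to the next step. The three
  retained branches and the final pass-on are concatenated (the widths
  telescope back to the post-dilation channel count), reduced by a 1x1
  convolution, and summed with an identity residual of the block input
  (1x1-projected on channel mismatch).
* **CCA decoder fusion.** Before each skip concatenation, the upsampled
  lower-resolution decoder features LD and the skip features SK each go
  through GAP -> 1x1 conv + BN (squeeze to c/r, r=2) -> RReLU -> 1x1 conv
  (back to c). The two c-vectors are added and rectified into a shared
  per-channel gate, which scales both LD and SK before they are
  concatenated. Both branches thus share one contextual channel attention.

All activations are randomized leaky ReLUs (RReLU); weights are
He-initialized. The output head is a 1x1 convolution with a sigmoid, one
channel per lesion class (one binary head per class by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ShapeError
from .nn import BatchNorm2d, Conv2d, Module, RReLU, Sequential, Sigmoid, Tensor, concat

__all__ = ["ModelConfig", "MSFF", "DownsampleConv", "CCA", "FFUNet",
           "build_model", "count_parameters", "msff_channel_plan",
           "architecture_summary"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    depth          : number of stride-2 downsampling stages (input H, W must
                     be divisible by 2**depth).
    base_channels  : channel width at full resolution, doubled per stage;
                     must be >= 9 so MSFF splitting keeps nonzero thirds.
    reduction_r    : CCA squeeze ratio (2 by default).
    dilation_rate  : dilation of the MSFF entry convolution.
    rrelu_lower/upper : uniform bounds of the RReLU negative slope.
    out_classes    : number of sigmoid output maps (1 = one binary head).
    cca_gate       : "rrelu" (the printed formulation) or "sigmoid"
                     (bounded-gate ablation).
    """

    depth: int = 4
    base_channels: int = 16
    reduction_r: int = 2
    dilation_rate: int = 2
    rrelu_lower: float = 1.0 / 8.0
    rrelu_upper: float = 1.0 / 3.0
    out_classes: int = 1
    cca_gate: str = "rrelu"

    def __post_init__(self):
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if self.base_channels < 9:
            raise ConfigurationError(
                "base_channels must be >= 9 so MSFF splitting thirds are nonzero")
        if self.reduction_r < 1:
            raise ConfigurationError("reduction_r must be >= 1")
        if self.dilation_rate < 1:
            raise ConfigurationError("dilation_rate must be >= 1")
        if not 0.0 <= self.rrelu_lower < self.rrelu_upper <= 1.0:
            raise ConfigurationError("need 0 <= rrelu_lower < rrelu_upper <= 1")
        if self.out_classes < 1:
            raise ConfigurationError("out_classes must be >= 1")
        if self.cca_gate not in ("rrelu", "sigmoid"):
            raise ConfigurationError("cca_gate must be 'rrelu' or 'sigmoid'")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def msff_channel_plan(channels: int, steps: int = 3):
    """Channel bookkeeping of the MSFF splitting cascade.

    Returns (retained widths per step, final pass-on width). Step k keeps
    floor(C_k/3) and passes on the rest; the retained widths plus the final
    pass-on always sum back to the input width (an exact identity).
    """
    if channels < 9:
        raise ConfigurationError(f"MSFF needs >= 9 channels, got {channels}")
    retained = []
    c = channels
    for _ in range(steps):
        keep = c // 3
        retained.append(keep)
        c -= keep
    return retained, c


class _ConvAct(Module):
    def __init__(self, in_c, out_c, k, cfg: ModelConfig, rng, *, stride=1,
                 dilation=1):
        super().__init__()
        self.conv = Conv2d(in_c, out_c, k, stride=stride, dilation=dilation,
                           rng=rng)
        self.act = RReLU(cfg.rrelu_lower, cfg.rrelu_upper, rng=rng)

    def forward(self, x):
        return self.act(self.conv(x))


class MSFF(Module):
    """Multiscale feature-fusion block (see module docstring)."""

    def __init__(self, in_channels: int, out_channels: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        super().__init__()
        if in_channels < 9:
            raise ConfigurationError(
                f"MSFF requires >= 9 input channels, got {in_channels}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.entry = _ConvAct(in_channels, in_channels, 3, cfg, rng,
                              dilation=cfg.dilation_rate)
        retained, final_pass = msff_channel_plan(in_channels)
        self.retained_widths = retained
        self.final_pass_width = final_pass
        self.keep_convs = []
        self.pass_convs = []
        c = in_channels
        for keep in retained:
            self.keep_convs.append(_ConvAct(c, keep, 3, cfg, rng))
            self.pass_convs.append(_ConvAct(c, c - keep, 5, cfg, rng))
            c -= keep
        self.reduce = Conv2d(in_channels, out_channels, 1, rng=rng)
        self.project = (None if in_channels == out_channels
                        else Conv2d(in_channels, out_channels, 1, rng=rng))
        self.out_act = RReLU(cfg.rrelu_lower, cfg.rrelu_upper, rng=rng)

    def forward(self, x):
        x = Tensor._coerce(x)
        h = self.entry(x)
        kept = []
        cur = h
        for keep_conv, pass_conv in zip(self.keep_convs, self.pass_convs):
            kept.append(keep_conv(cur))
            cur = pass_conv(cur)
        fused = self.reduce(concat(kept + [cur], axis=1))
        residual = x if self.project is None else self.project(x)
        return self.out_act(fused + residual)


class DownsampleConv(Module):
    """Learned downsampling: 3x3 stride-2 convolution + RReLU (no pooling)."""

    def __init__(self, in_c: int, out_c: int, cfg: ModelConfig, rng):
        super().__init__()
        self.block = _ConvAct(in_c, out_c, 3, cfg, rng, stride=2)

    def forward(self, x):
        x = Tensor._coerce(x)
        _, _, h, w = x.data.shape
        if h % 2 or w % 2:
            raise ShapeError(f"downsample needs even spatial size, got {h}x{w}")
        return self.block(x)


class CCA(Module):
    """Contextual channel attention fusing skip and lower-resolution decoder.

    The lower-resolution decoder features are bilinearly upsampled 2x and
    1x1-projected to the skip's channel count c (the two attention vectors
    must be addable, which forces equal width). Each branch is squeezed to
    c/r and re-expanded to c; the shared gate scales both branches before
    concatenation, giving 2c output channels.
    """

    def __init__(self, ld_channels: int, skip_channels: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        super().__init__()
        c = skip_channels
        squeeze = max(1, c // cfg.reduction_r)
        self.skip_channels = c
        self.squeeze_channels = squeeze
        self.proj = Conv2d(ld_channels, c, 1, rng=rng)
        # per-branch squeeze-excite paths: 1x1+BN -> RReLU -> 1x1
        self.ld_squeeze = Conv2d(c, squeeze, 1, rng=rng)
        self.ld_bn = BatchNorm2d(squeeze)
        self.ld_act = RReLU(cfg.rrelu_lower, cfg.rrelu_upper, rng=rng)
        self.ld_excite = Conv2d(squeeze, c, 1, rng=rng)
        self.sk_squeeze = Conv2d(c, squeeze, 1, rng=rng)
        self.sk_bn = BatchNorm2d(squeeze)
        self.sk_act = RReLU(cfg.rrelu_lower, cfg.rrelu_upper, rng=rng)
        self.sk_excite = Conv2d(squeeze, c, 1, rng=rng)
        self.gate_kind = cfg.cca_gate
        self.gate_act = RReLU(cfg.rrelu_lower, cfg.rrelu_upper, rng=rng)

    def forward(self, inputs):
        ld, sk = inputs
        ld = Tensor._coerce(ld)
        sk = Tensor._coerce(sk)
        ld_up = self.proj(ld.upsample_bilinear_2x())
        if ld_up.data.shape != sk.data.shape:
            raise ShapeError(
                f"after upsample+projection LD {ld_up.data.shape} must match "
                f"SK {sk.data.shape}")
        c_ld = self.ld_excite(self.ld_act(self.ld_bn(
            self.ld_squeeze(ld_up.mean_spatial()))))
        c_sk = self.sk_excite(self.sk_act(self.sk_bn(
            self.sk_squeeze(sk.mean_spatial()))))
        s = c_ld + c_sk
        gate = s.sigmoid() if self.gate_kind == "sigmoid" else self.gate_act(s)
        return concat([gate * ld_up, gate * sk], axis=1)


class _DecoderStage(Module):
    def __init__(self, ld_channels: int, skip_channels: int, cfg: ModelConfig,
                 rng):
        super().__init__()
        self.cca = CCA(ld_channels, skip_channels, cfg, rng)
        self.refine = Sequential(
            _ConvAct(2 * skip_channels, skip_channels, 3, cfg, rng),
            _ConvAct(skip_channels, skip_channels, 3, cfg, rng),
        )

    def forward(self, inputs):
        return self.refine(self.cca(inputs))


class FFUNet(Module):
    """Encoder-decoder segmentation network (see module docstring)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        init_rng = np.random.default_rng(seed)
        # separate stream for RReLU slope draws so architecture init and
        # training-time activation noise are independently reproducible
        act_rng = np.random.default_rng(seed + 101)
        cfg = config
        b = cfg.base_channels
        self.stem = _ConvAct(3, b, 3, cfg, init_rng)
        self.encoders = []
        self.downs = []
        c = b
        for _ in range(cfg.depth):
            self.encoders.append(MSFF(c, c, cfg, init_rng))
            self.downs.append(DownsampleConv(c, 2 * c, cfg, init_rng))
            c *= 2
        self.bottleneck = MSFF(c, c, cfg, init_rng)
        self.decoders = []
        for _ in range(cfg.depth):
            self.decoders.append(_DecoderStage(c, c // 2, cfg, init_rng))
            c //= 2
        self.head = Conv2d(c, cfg.out_classes, 1, rng=init_rng)
        self.out_act = Sigmoid()
        for m in self.modules():
            if isinstance(m, RReLU):
                m.rng = act_rng

    def forward(self, x) -> Tensor:
        x = Tensor._coerce(x)
        if x.ndim != 4 or x.data.shape[1] != 3:
            raise ShapeError(f"expected (N, 3, H, W) input, got {x.data.shape}")
        _, _, h, w = x.data.shape
        mult = 2 ** self.config.depth
        if h % mult or w % mult:
            raise ShapeError(
                f"input spatial size {h}x{w} must be divisible by {mult} "
                f"(2**depth with depth={self.config.depth})")
        cur = self.stem(x)
        skips = []
        for enc, down in zip(self.encoders, self.downs):
            cur = enc(cur)
            skips.append(cur)
            cur = down(cur)
        cur = self.bottleneck(cur)
        for dec, skip in zip(self.decoders, reversed(skips)):
            cur = dec((cur, skip))
        return self.out_act(self.head(cur))


def build_model(config: ModelConfig, seed: int = 0) -> FFUNet:
    """Construct a He-initialized network from its configuration."""
    return FFUNet(config, seed=seed)


def count_parameters(model: Module) -> int:
    """Total number of learnable scalars."""
    return int(sum(p.data.size for p in model.parameters()))


def architecture_summary(model: FFUNet) -> dict:
    """JSON-able per-layer summary: shapes and parameter counts."""
    layers = []
    for name, mod in model._named_modules():
        if isinstance(mod, Conv2d):
            n = mod.weight.data.size + (mod.bias.data.size if mod.bias else 0)
            layers.append({
                "name": name, "type": "Conv2d",
                "in_channels": mod.in_channels, "out_channels": mod.out_channels,
                "kernel_size": mod.kernel_size, "stride": mod.stride,
                "dilation": mod.dilation, "parameters": int(n),
            })
        elif isinstance(mod, BatchNorm2d):
            layers.append({"name": name, "type": "BatchNorm2d",
                           "channels": mod.num_channels,
                           "parameters": 2 * mod.num_channels})
    return {"config": model.config.to_dict(),
            "total_parameters": count_parameters(model),
            "layers": layers}
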