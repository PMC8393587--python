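"""Two-branch segmentation networks.

The first branch is a standard encoder–decoder (U-Net in 2D or 3D, or an
FCN-32-style fully convolutional net) producing per-class region logits.  The
second branch consumes the final decoder feature map ``F_H``, refines it with
residual blocks, projects it to one channel per class and passes it through
the transitional gate — edge extraction then band dilation — to produce the
contour map ``F_LC`` and the narrow-band map ``F_LN``.  Both branches share
the encoder and train end to end: the band loss on ``F_LC``/``F_LN``
back-propagates into the same features that produce the region logits.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .autodiff import Tensor, as_tensor, concatenate
from .band_operators import BandSpec, InvalidParameterError, transitional_gate

__all__ = [
    "BackboneConfig",
    "TwoBranchOutput",
    "TwoBranchNet",
    "build_backbone",
    "softmax",
    "save_checkpoint",
    "load_checkpoint",
]

_KINDS = ("unet2d", "fcn2d", "unet3d")

CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class BackboneConfig:
    """Configuration of a two-branch backbone.

    ``depth`` counts encoder levels; spatial input sizes must be divisible by
    ``2**(depth-1)`` (U-Net) or ``2**depth`` (FCN).  ``norm`` and
    ``activation`` default to batch+ReLU in 2D and instance+leaky-ReLU in 3D.
    """

    kind: str = "unet2d"
    in_channels: int = 1
    num_classes: int = 3
    depth: int = 2
    base_width: int = 8
    norm: str | None = None
    activation: str | None = None
    band_width: int | None = None
    residual_blocks: int = 1
    trainable_edge_kernel: bool = False

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise InvalidParameterError(f"unknown backbone kind {self.kind!r}")
        if self.depth < 2:
            raise InvalidParameterError("depth must be >= 2")
        if self.base_width < 4:
            raise InvalidParameterError("base_width must be >= 4")
        if self.num_classes < 2:
            raise InvalidParameterError("num_classes must be >= 2")

    @property
    def nd(self) -> int:
        return 3 if self.kind == "unet3d" else 2

    @property
    def norm_kind(self) -> str:
        return self.norm or ("instance" if self.nd == 3 else "batch")

    @property
    def activation_kind(self) -> str:
        return self.activation or ("leaky_relu" if self.nd == 3 else "relu")

    @property
    def band_spec(self) -> BandSpec:
        return BandSpec(B=self.band_width or (3 if self.nd == 3 else 5))

    @property
    def divisor(self) -> int:
        return 2 ** (self.depth - 1)


@dataclass
class TwoBranchOutput:
    """Outputs of a two-branch forward pass (all at input resolution)."""

    region_logits: Tensor
    F_H: Tensor
    F_LC: Tensor
    F_LN: Tensor

    @property
    def probs(self) -> Tensor:
        return softmax(self.region_logits, axis=1)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    """Numerically stabilized softmax along ``axis`` (differentiable)."""
    x = as_tensor(x)
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def _make_norm(kind: str, channels: int, nd: int) -> nn.Module:
    if kind == "batch":
        return nn.BatchNorm(channels, nd)
    if kind == "instance":
        return nn.InstanceNorm(channels, nd)
    raise InvalidParameterError(f"unknown norm {kind!r}")


def _make_act(kind: str) -> nn.Module:
    if kind == "relu":
        return nn.ReLU()
    if kind == "leaky_relu":
        return nn.LeakyReLU()
    raise InvalidParameterError(f"unknown activation {kind!r}")


class ConvBlock(nn.Module):
    """Two 3×3 (3×3×3) convolutions, each followed by norm and activation."""

    def __init__(self, in_ch, out_ch, cfg: BackboneConfig, rng):
        super().__init__()
        nd = cfg.nd
        self.body = nn.Sequential(
            nn.Conv(in_ch, out_ch, 3, nd, rng),
            _make_norm(cfg.norm_kind, out_ch, nd),
            _make_act(cfg.activation_kind),
            nn.Conv(out_ch, out_ch, 3, nd, rng),
            _make_norm(cfg.norm_kind, out_ch, nd),
            _make_act(cfg.activation_kind),
        )

    def forward(self, x):
        return self.body(x)


class ResidualBlock(nn.Module):
    """conv-norm-act-conv-norm plus identity skip, then activation."""

    def __init__(self, channels, cfg: BackboneConfig, rng):
        super().__init__()
        nd = cfg.nd
        self.f = nn.Sequential(
            nn.Conv(channels, channels, 3, nd, rng),
            _make_norm(cfg.norm_kind, channels, nd),
            _make_act(cfg.activation_kind),
            nn.Conv(channels, channels, 3, nd, rng),
            _make_norm(cfg.norm_kind, channels, nd),
        )
        self.act = _make_act(cfg.activation_kind)

    def forward(self, x):
        return self.act(self.f(x) + x)


class TrainableEdge(nn.Module):
    """Learnable variant of the gate's edge extractor.

    Two directional 3×3 convolutions initialized to the fixed smoothed
    central-difference kernels; the edge map is the root-sum-square of their
    responses.  Off by default (the fixed operator keeps oracles exact).
    """

    def __init__(self, channels: int, nd: int, rng):
        super().__init__()
        if nd != 2:
            raise InvalidParameterError("trainable edge kernel is 2D-only")
        smooth = np.array([0.25, 0.5, 0.25])
        diff = np.array([-0.5, 0.0, 0.5])
        ky = np.outer(diff, smooth)
        kx = np.outer(smooth, diff)
        self.convs = []
        for k in (ky, kx):
            conv = nn.Conv(channels, channels, 3, nd, rng)
            wdata = np.zeros_like(conv.weight.data)
            for c in range(channels):
                wdata[c, c] = k
            conv.weight.data = wdata
            conv.bias.data[:] = 0.0
            self.convs.append(conv)

    def forward(self, x):
        gy = self.convs[0](x)
        gx = self.convs[1](x)
        return (gy * gy + gx * gx).sqrt()


# ---------------------------------------------------------------------------
# backbones
# ---------------------------------------------------------------------------


class _SecondBranch(nn.Module):
    def __init__(self, cfg: BackboneConfig, rng):
        super().__init__()
        self.cfg = cfg
        self.blocks = [
            ResidualBlock(cfg.base_width, cfg, rng) for _ in range(cfg.residual_blocks)
        ]
        self.project = nn.Conv(cfg.base_width, cfg.num_classes, 1, cfg.nd, rng)
        self.edge = (
            TrainableEdge(cfg.num_classes, cfg.nd, rng)
            if cfg.trainable_edge_kernel
            else None
        )

    def forward(self, F_H):
        x = F_H
        for b in self.blocks:
            x = b(x)
        x = self.project(x)
        spec = self.cfg.band_spec
        if self.edge is not None:
            from .band_operators import dilate_band

            F_LC = self.edge(x)
            F_LN = dilate_band(F_LC, spec, self.cfg.nd)
        else:
            F_LC, F_LN = transitional_gate(x, spec, self.cfg.nd)
        return F_LC, F_LN


class TwoBranchNet(nn.Module):
    """Encoder–decoder first branch plus NB-AC attention second branch."""

    def __init__(self, cfg: BackboneConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        nd = cfg.nd
        if cfg.kind in ("unet2d", "unet3d"):
            widths = [cfg.base_width * 2**i for i in range(cfg.depth)]
            self.encoders = []
            in_ch = cfg.in_channels
            for w_ch in widths:
                self.encoders.append(ConvBlock(in_ch, w_ch, cfg, rng))
                in_ch = w_ch
            self.decoders = [
                ConvBlock(widths[i + 1] + widths[i], widths[i], cfg, rng)
                for i in reversed(range(cfg.depth - 1))
            ]
            self.pool = nn.MaxPool(nd)
            self.up = nn.UpsampleBilinear(nd)
        else:  # fcn2d
            widths = [cfg.base_width * 2 ** min(i, 3) for i in range(cfg.depth)]
            self.stages = []
            in_ch = cfg.in_channels
            for w_ch in widths:
                self.stages.append(ConvBlock(in_ch, w_ch, cfg, rng))
                in_ch = w_ch
            taps = sorted({1, min(3, cfg.depth), cfg.depth})
            self.tap_stages = taps
            self.tap_heads = [
                nn.Conv(widths[t - 1], cfg.base_width, 1, nd, rng) for t in taps
            ]
            self.pool = nn.MaxPool(nd)
            self.up = nn.UpsampleBilinear(nd)
            self.fuse = ConvBlock(cfg.base_width, cfg.base_width, cfg, rng)
        self.head = nn.Conv(cfg.base_width, cfg.num_classes, 1, nd, rng)
        self.second = _SecondBranch(cfg, rng)

    # -- forward ---------------------------------------------------------
    def _check_input(self, x: np.ndarray):
        cfg = self.cfg
        if x.ndim != cfg.nd + 2:
            raise InvalidParameterError(
                f"{cfg.kind} expects rank-{cfg.nd + 2} input (N, C, *spatial)"
            )
        if x.shape[1] != cfg.in_channels:
            raise InvalidParameterError(
                f"expected {cfg.in_channels} input channels, got {x.shape[1]}"
            )
        for s in x.shape[2:]:
            if s % cfg.divisor:
                raise InvalidParameterError(
                    f"spatial size {s} not divisible by {cfg.divisor}"
                )

    def forward(self, image) -> TwoBranchOutput:
        x = as_tensor(image)
        self._check_input(x.data)
        if self.cfg.kind in ("unet2d", "unet3d"):
            skips = []
            for i, enc in enumerate(self.encoders):
                x = enc(x)
                if i < len(self.encoders) - 1:
                    skips.append(x)
                    x = self.pool(x)
            for dec, skip in zip(self.decoders, reversed(skips)):
                x = self.up(x)
                x = dec(concatenate([x, skip], axis=1))
            F_H = x
        else:
            fused = None
            for s, stage in enumerate(self.stages, start=1):
                x = stage(x)
                if s in self.tap_stages:
                    head = self.tap_heads[self.tap_stages.index(s)]
                    tap = head(x)
                    for _ in range(s - 1):  # stage s sits after s-1 pools
                        tap = self.up(tap)
                    fused = tap if fused is None else fused + tap
                if s < len(self.stages):
                    x = self.pool(x)
            F_H = self.fuse(fused)
        logits = self.head(F_H)
        F_LC, F_LN = self.second(F_H)
        return TwoBranchOutput(logits, F_H, F_LC, F_LN)

    def predict(self, image) -> np.ndarray:
        """Argmax label mask for a batch (numpy in, numpy out)."""
        out = self.forward(as_tensor(np.asarray(image, dtype=np.float64)))
        return np.argmax(out.region_logits.data, axis=1)

    def parameter_checksum(self) -> float:
        return float(sum(np.abs(p.data).sum() for p in self.parameters()))


def build_backbone(cfg: BackboneConfig, seed: int = 0) -> TwoBranchNet:
    """Deterministically build a two-branch network from a config and seed."""
    return TwoBranchNet(cfg, seed=seed)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(net: TwoBranchNet, path, seed: int | None = None, meta: dict | None = None):
    """Single-file checkpoint: versioned header + all arrays (npz)."""
    path = Path(path)
    header = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": asdict(net.cfg),
        "seed": seed,
        "meta": meta or {},
    }
    state = net.named_state()
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[TwoBranchNet, dict]:
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        header = json.loads(bytes(data["__header__"].tobytes()).decode())
        if header.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version: {header.get('format_version')}")
        cfg = BackboneConfig(**header["config"])
        net = TwoBranchNet(cfg, seed=header.get("seed") or 0)
        state = {k: data[k] for k in data.files if k != "__header__"}
        net.load_state(state)
    return net, header
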