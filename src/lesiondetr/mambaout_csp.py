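"""Gated-CNN cross-stage-partial backbone and its residual-CNN baseline.

The token mixer is a gated convolutional residual (no state-space model):

    y = x + sigmoid(W_g . Norm(x)) * conv(W_f . Norm(x))

with ``Norm`` a channel layer norm, ``W_g``/``W_f`` pointwise linear maps,
``conv`` a 7x7 depthwise convolution on the feature branch, and ``*`` the
Hadamard product.  Stages wrap stacks of these blocks in a cross-stage
partial (CSP) layout: an entry convolution, a channel split into an
untouched shortcut half and a processed half, concatenation, and a 1x1
fuse — trading width for depth to keep the backbone light.

The baseline backbone is the classic two-conv residual ("basic block")
design with depths (2, 2, 2, 2), used for the backbone ablation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "GatedCNNBlock",
    "StageConfig",
    "CSPStage",
    "CSPMambaOutBackbone",
    "ResNetBackbone",
    "build_backbone",
]


class GatedCNNBlock(nn.Module):
    """One gated feature-selection residual block.

    With the default ``expansion=1`` the block is exactly
    ``x + sigmoid(gate) * conv(feature)`` with gate/feature branches mapping
    C -> C; an expansion ratio > 1 widens both branches and adds a 1x1
    output projection back to C.
    """

    def __init__(
        self, channels: int, kernel_size: int = 7, expansion: float = 1.0
    ) -> None:
        super().__init__()
        hidden = int(round(channels * expansion))
        self.channels = channels
        self.hidden = hidden
        self.norm = nn.LayerNorm2d(channels)
        self.w_g = nn.Conv2d(channels, hidden, 1)
        self.w_f = nn.Conv2d(channels, hidden, 1)
        self.conv = nn.Conv2d(
            hidden, hidden, kernel_size, padding=kernel_size // 2, groups=hidden
        )
        self.out_proj = (
            nn.Conv2d(hidden, channels, 1) if hidden != channels else nn.Identity()
        )

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(
                f"expected {self.channels} channels, got {x.shape[1]}"
            )
        xn = self.norm(x)
        gate = nn.sigmoid(self.w_g(xn))
        feat = self.conv(self.w_f(xn))
        return x + self.out_proj(gate * feat)


@dataclass(frozen=True)
class StageConfig:
    in_channels: int
    out_channels: int
    num_blocks: int
    split_ratio: float = 0.5
    stride: int = 1
    kernel_size: int = 7
    expansion: float = 1.0


class CSPStage(nn.Module):
    """Entry conv -> channel split -> (shortcut | gated blocks) -> concat -> fuse."""

    def __init__(self, cfg: StageConfig) -> None:
        super().__init__()
        width = cfg.out_channels
        main = int(round(width * cfg.split_ratio))
        if main <= 0 or main >= width or (cfg.split_ratio == 0.5 and width % 2):
            raise ValueError(
                f"cannot split {width} channels at ratio {cfg.split_ratio}"
            )
        self.cfg = cfg
        self.main_width = main
        self.entry = nn.Conv2d(
            cfg.in_channels, width, 3, stride=cfg.stride, padding=1
        )
        self.blocks = nn.ModuleList(
            GatedCNNBlock(main, cfg.kernel_size, cfg.expansion)
            for _ in range(cfg.num_blocks)
        )
        self.fuse = nn.Conv2d(width, cfg.out_channels, 1)
        self._capture_split = False
        self.last_residual: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} channels, got {x.shape[1]}"
            )
        y = self.entry(x)
        main = y[:, : self.main_width]
        shortcut = y[:, self.main_width :]
        if self._capture_split:
            self.last_residual = shortcut.data.copy()
        for block in self.blocks:
            main = block(main)
        return self.fuse(nn.concatenate([main, shortcut], axis=1))


class CSPMambaOutBackbone(nn.Module):
    """Stem (stride 4) + four CSP stages at strides (1, 2, 2, 2).

    The last three stages are tapped as the pyramid features S3/S4/S5 at
    strides 8/16/32.
    """

    def __init__(
        self,
        widths: tuple[int, int, int, int] = (48, 96, 192, 288),
        depths: tuple[int, int, int, int] = (2, 2, 6, 2),
        stem_width: int | None = None,
        kernel_size: int = 7,
    ) -> None:
        super().__init__()
        stem_width = stem_width or widths[0]
        self.widths = widths
        self.stem = nn.Sequential(
            nn.Conv2d(3, stem_width, 3, stride=2, padding=1),
            nn.LayerNorm2d(stem_width),
            nn.Conv2d(stem_width, stem_width, 3, stride=2, padding=1),
        )
        chans = [stem_width, *widths]
        strides = (1, 2, 2, 2)
        self.stages = nn.ModuleList(
            CSPStage(
                StageConfig(
                    in_channels=chans[i],
                    out_channels=chans[i + 1],
                    num_blocks=depths[i],
                    stride=strides[i],
                    kernel_size=kernel_size,
                )
            )
            for i in range(4)
        )

    @property
    def out_channels(self) -> tuple[int, int, int]:
        return self.widths[1], self.widths[2], self.widths[3]

    @property
    def out_strides(self) -> tuple[int, int, int]:
        return 8, 16, 32

    def forward(self, image: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        _check_input(image)
        x = self.stem(image)
        feats = []
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return feats[1], feats[2], feats[3]


class _BasicBlock(nn.Module):
    def __init__(self, cin: int, cout: int, stride: int = 1) -> None:
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=stride, padding=1, bias=False)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down = nn.Sequential(
                nn.Conv2d(cin, cout, 1, stride=stride, bias=False),
                nn.BatchNorm2d(cout),
            )
        else:
            self.down = nn.Identity()

    def forward(self, x: Tensor) -> Tensor:
        y = nn.relu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        return nn.relu(y + self.down(x))


class ResNetBackbone(nn.Module):
    """Baseline: 7x7 stem + max-pool, then four basic-block stages (2,2,2,2)."""

    def __init__(
        self, widths: tuple[int, int, int, int] = (64, 128, 256, 512)
    ) -> None:
        super().__init__()
        self.widths = widths
        self.stem_conv = nn.Conv2d(3, widths[0], 7, stride=2, padding=3, bias=False)
        self.stem_bn = nn.BatchNorm2d(widths[0])
        stages = []
        cin = widths[0]
        for i, w in enumerate(widths):
            stride = 1 if i == 0 else 2
            stages.append(
                nn.Sequential(_BasicBlock(cin, w, stride), _BasicBlock(w, w))
            )
            cin = w
        self.stages = nn.ModuleList(stages)

    @property
    def out_channels(self) -> tuple[int, int, int]:
        return self.widths[1], self.widths[2], self.widths[3]

    @property
    def out_strides(self) -> tuple[int, int, int]:
        return 8, 16, 32

    def forward(self, image: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        _check_input(image)
        x = nn.relu(self.stem_bn(self.stem_conv(image)))
        x = nn.max_pool2d(x, 3, 2, 1)
        feats = []
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return feats[1], feats[2], feats[3]


def _check_input(image: Tensor) -> None:
    if image.ndim != 4 or image.shape[1] != 3:
        raise ValueError(f"expected (B, 3, H, W) input, got {image.shape}")
    if image.shape[2] % 32 or image.shape[3] % 32:
        raise ValueError(
            f"input side must be divisible by 32, got {image.shape[2]}x{image.shape[3]}"
        )


def build_backbone(
    kind: str,
    widths: tuple[int, int, int, int] | None = None,
    depths: tuple[int, int, int, int] | None = None,
):
    if kind == "cspmambaout":
        kwargs = {}
        if widths is not None:
            kwargs["widths"] = widths
        if depths is not None:
            kwargs["depths"] = depths
        return CSPMambaOutBackbone(**kwargs)
    if kind == "resnet18":
        return ResNetBackbone(widths) if widths is not None else ResNetBackbone()
    raise ValueError(f"unknown backbone '{kind}' (choices: cspmambaout, resnet18)")
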