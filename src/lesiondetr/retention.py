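"""Manhattan-decay retention aggregation (MaSA) and the RepC3 baseline.

Manhattan self-attention masks the softmax score matrix elementwise with
the spatial decay ``D[n, m] = gamma ** d_manhattan(n, m)`` and — following
the retention convention — does *not* renormalize rows afterwards:

    out = [softmax(Q K^T / sqrt(d)) * D] V

Because ``D`` factorizes exactly over rows and columns, a decomposed
variant runs one 1D attention along each axis (horizontal then vertical)
with the 1D decay factors, at linear cost per axis.  The two operators
agree exactly on single-row/-column grids and differ in general — the
decomposition is an approximation by construction.

``RetBlock`` wraps the decomposed operator with rotary position encoding
on Q/K, a depthwise local-context enhancement of V, and a pre-norm FFN;
``RetBlockC3`` is the dual-path aggregation block (1x1 conv + RetBlocks,
added to a 1x1 shortcut).  ``RepC3`` is the convolutional baseline with a
batch-norm shortcut and SiLU.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor
from .rope_decay import (
    DecaySpec,
    build_axial_frequencies,
    default_gamma_schedule,
    manhattan_decay,
    rope2d_rotate,
)

__all__ = [
    "masa_full",
    "masa_decomposed",
    "lce",
    "RetBlock",
    "RetBlockC3",
    "RepC3",
]

_FULL_MASA_MAX_N = 4096


def _to_tokens(t: Tensor, num_heads: int):
    """(B, C, H, W) -> (B, heads, N, d) with row-major flattening."""
    B, C, H, W = t.shape
    return t.reshape(B, num_heads, C // num_heads, H * W).swapaxes(-1, -2)


def masa_full(q: Tensor, k: Tensor, v: Tensor, decay: DecaySpec, num_heads: int = 1) -> Tensor:
    """Full Manhattan self-attention (quadratic oracle path).

    ``A = softmax(QK^T / sqrt(d)) * D`` applied to V; rows are not
    renormalized after the decay mask.
    """
    B, C, H, W = q.shape
    N = H * W
    if N > _FULL_MASA_MAX_N:
        raise ValueError(
            f"grid {H}x{W} (N={N}) too large for the full-attention path; "
            "use masa_decomposed"
        )
    if (decay.H, decay.W) != (H, W):
        raise ValueError(f"decay grid {decay.H}x{decay.W} != feature grid {H}x{W}")
    d = C // num_heads
    qt = _to_tokens(q, num_heads)
    kt = _to_tokens(k, num_heads)
    vt = _to_tokens(v, num_heads)
    scores = nn.matmul(qt, kt.swapaxes(-1, -2)) * (1.0 / np.sqrt(d))
    attn = nn.softmax(scores, axis=-1) * decay.D
    out = nn.matmul(attn, vt)
    return out.swapaxes(-1, -2).reshape(B, C, H, W)


def masa_decomposed(
    q: Tensor, k: Tensor, v: Tensor, decay: DecaySpec, num_heads: int = 1
) -> Tensor:
    """Axis-decomposed MaSA: horizontal pass (per row, column decay), then
    vertical pass (per column, row decay) on the horizontal output.

    Peak intermediates are ``H x W x W`` and ``W x H x H`` per head — never
    the ``HW x HW`` matrix.
    """
    B, C, H, W = q.shape
    h = num_heads
    d = C // h
    scale = 1.0 / np.sqrt(d)
    # (B, heads, H, W, d): rows are attention groups for the horizontal pass
    qg = q.reshape(B, h, d, H, W).transpose(0, 1, 3, 4, 2)
    kg = k.reshape(B, h, d, H, W).transpose(0, 1, 3, 4, 2)
    vg = v.reshape(B, h, d, H, W).transpose(0, 1, 3, 4, 2)
    s_w = nn.matmul(qg, kg.swapaxes(-1, -2)) * scale  # (B, h, H, W, W)
    a_w = nn.softmax(s_w, axis=-1) * decay.d_col
    hz = nn.matmul(a_w, vg)  # (B, h, H, W, d)
    # vertical pass: swap row/col axes so columns become attention groups
    qv = qg.swapaxes(2, 3)  # (B, h, W, H, d)
    kv = kg.swapaxes(2, 3)
    hv = hz.swapaxes(2, 3)
    s_h = nn.matmul(qv, kv.swapaxes(-1, -2)) * scale  # (B, h, W, H, H)
    a_h = nn.softmax(s_h, axis=-1) * decay.d_row
    out = nn.matmul(a_h, hv)  # (B, h, W, H, d)
    return out.transpose(0, 1, 4, 3, 2).reshape(B, C, H, W)


def lce(v: Tensor, conv: nn.Conv2d) -> Tensor:
    """Local context enhancement: 5x5 depthwise convolution of V."""
    if conv.groups != conv.in_channels:
        raise ValueError("lce requires a depthwise convolution (groups == channels)")
    return conv(v)


class RetBlock(nn.Module):
    """Pre-norm retention block.

    ``X + [MaSA_decomposed(rope(Q), rope(K), V) + LCE(V)]`` followed by a
    norm + two-layer GELU FFN residual.  2D relative position enters twice:
    multiplicatively through the rotary encoding of Q/K and through the
    per-head Manhattan decay masks.
    """

    def __init__(
        self,
        channels: int,
        num_heads: int,
        gammas: np.ndarray | None = None,
        ffn_ratio: float = 2.0,
        rope_base: float = 10000.0,
    ) -> None:
        super().__init__()
        if channels % num_heads:
            raise ValueError(f"channels {channels} not divisible by heads {num_heads}")
        head_dim = channels // num_heads
        if head_dim % 4:
            raise ValueError(f"head_dim {head_dim} must be divisible by 4 for RoPE")
        self.channels = channels
        self.num_heads = num_heads
        self.gammas = (
            np.asarray(gammas, dtype=float)
            if gammas is not None
            else default_gamma_schedule(num_heads)
        )
        if np.any(self.gammas <= 0) or np.any(self.gammas > 1):
            raise ValueError("per-head gamma must lie in (0, 1]")
        self.rope = build_axial_frequencies(head_dim, base=rope_base)
        self.norm1 = nn.LayerNorm2d(channels)
        self.norm2 = nn.LayerNorm2d(channels)
        self.qkv = nn.Conv2d(channels, 3 * channels, 1)
        self.lce_conv = nn.Conv2d(channels, channels, 5, padding=2, groups=channels, bias=False)
        self.proj = nn.Conv2d(channels, channels, 1)
        hidden = int(channels * ffn_ratio)
        self.ffn1 = nn.Conv2d(channels, hidden, 1)
        self.ffn2 = nn.Conv2d(hidden, channels, 1)
        self._decay_cache: dict[tuple[int, int], list[DecaySpec]] = {}
        self.attention_impl = masa_decomposed  # swappable for oracle tests

    def _decays(self, H: int, W: int) -> list[DecaySpec]:
        key = (H, W)
        if key not in self._decay_cache:
            self._decay_cache[key] = [manhattan_decay(g, H, W) for g in self.gammas]
        return self._decay_cache[key]

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if C != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {C}")
        xn = self.norm1(x)
        qkv = self.qkv(xn)
        q, k, v = qkv[:, :C], qkv[:, C : 2 * C], qkv[:, 2 * C :]
        d = C // self.num_heads
        qh = rope2d_rotate(q.reshape(B, self.num_heads, d, H, W), self.rope)
        kh = rope2d_rotate(k.reshape(B, self.num_heads, d, H, W), self.rope)
        qh = qh.reshape(B, C, H, W)
        kh = kh.reshape(B, C, H, W)
        # per-head decay: run heads separately (gamma differs per head)
        outs = []
        for i, spec in enumerate(self._decays(H, W)):
            sl = slice(i * d, (i + 1) * d)
            outs.append(
                self.attention_impl(qh[:, sl], kh[:, sl], v[:, sl], spec, num_heads=1)
            )
        attn = nn.concatenate(outs, axis=1)
        y = x + self.proj(attn + lce(v, self.lce_conv))
        return y + self.ffn2(nn.gelu(self.ffn1(self.norm2(y))))


class RetBlockC3(nn.Module):
    """Dual-path aggregation: 1x1 conv -> n RetBlocks, plus a 1x1 shortcut,
    outputs summed elementwise."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        num_blocks: int = 1,
        num_heads: int = 4,
        gammas: np.ndarray | None = None,
    ) -> None:
        super().__init__()
        self.conv_a = nn.Conv2d(in_channels, out_channels, 1)
        self.conv_b = nn.Conv2d(in_channels, out_channels, 1)
        self.blocks = nn.ModuleList(
            RetBlock(out_channels, num_heads, gammas) for _ in range(num_blocks)
        )

    def forward(self, x: Tensor) -> Tensor:
        a = self.conv_a(x)
        for block in self.blocks:
            a = block(a)
        return a + self.conv_b(x)


class RepC3(nn.Module):
    """Baseline aggregation: conv branch + batch-normalized shortcut, SiLU.

    The branch is a stack of 3x3 convolutions; its output is summed with
    BN(x) and passed through SiLU.
    """

    def __init__(
        self, in_channels: int, out_channels: int, num_blocks: int = 3
    ) -> None:
        super().__init__()
        convs = []
        cin = in_channels
        for i in range(num_blocks):
            convs.append(nn.Conv2d(cin, out_channels, 3, padding=1))
            if i < num_blocks - 1:
                convs.append(_SiLUAct())
            cin = out_channels
        self.branch = nn.Sequential(*convs)
        self.shortcut_bn = nn.BatchNorm2d(in_channels)
        self.align = (
            nn.Conv2d(in_channels, out_channels, 1, bias=False)
            if in_channels != out_channels
            else nn.Identity()
        )

    def forward(self, x: Tensor) -> Tensor:
        return nn.silu(self.branch(x) + self.align(self.shortcut_bn(x)))


class _SiLUAct(nn.Module):
    def forward(self, x: Tensor) -> Tensor:
        return nn.silu(x)
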