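"""Magnitude-aware linear attention (MALA) intra-scale interaction block.

Standard linear attention replaces the softmax score with a positive
kernel map phi applied to queries and keys, so attention costs O(N d^2)
instead of O(N^2 d).  The price is that phi discards the *magnitude* of
the query vector, flattening the score distribution — a real problem for
MRI, where lesions are identified by signal-amplitude differences against
normal tissue.  MALA restores magnitude sensitivity with a correction
factor and a global-mean bias:

    z   = phi(Q_hat) . mean_i phi(K_hat)_i
    out = phi(Q_hat) [phi(K_hat)^T V] * (1 + (z + eps)^-1)  -  z * mean_i V_i

where Q_hat, K_hat are the rotary-encoded queries/keys.  The full block
adds a depthwise local positional perturbation on V, a pointwise
multiplicative output gate O, a 1x1 projection, and a post-norm GELU FFN.

The plain multi-head softmax block (:class:`AIFIMHSABlock`) is kept as the
ablation baseline for the same intra-scale slot.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor
from .rope_decay import AxialRoPE, build_axial_frequencies, rope2d_rotate

__all__ = [
    "kernel_map",
    "qkvo_project",
    "mala_core",
    "dw_lpe",
    "mala_fuse",
    "AIFIMALABlock",
    "AIFIMHSABlock",
]


def kernel_map(x):
    """Positive feature map ``phi(x) = ELU(x) + 1``; works on arrays and tensors."""
    if isinstance(x, Tensor):
        return nn.elu(x) + 1.0
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, x + 1.0, np.exp(x))


def qkvo_project(x: Tensor, conv: nn.Conv2d) -> tuple[Tensor, Tensor, Tensor, Tensor]:
    """Fused 1x1 projection producing Q, K, V and the gate O (C channels each)."""
    C = x.shape[1]
    if conv.in_channels != C or conv.out_channels != 4 * C:
        raise ValueError(
            f"projection expects {conv.in_channels}->{conv.out_channels} channels, "
            f"input has {C}"
        )
    y = conv(x)
    return (
        y[:, 0 * C : 1 * C],
        y[:, 1 * C : 2 * C],
        y[:, 2 * C : 3 * C],
        y[:, 3 * C : 4 * C],
    )


def _split_heads(t: Tensor, num_heads: int) -> Tensor:
    """(B, C, H, W) -> (B, heads, C/heads, H, W)."""
    B, C, H, W = t.shape
    return t.reshape(B, num_heads, C // num_heads, H, W)


def mala_core(
    q: Tensor,
    k: Tensor,
    v: Tensor,
    rope: AxialRoPE,
    num_heads: int,
    epsilon: float = 1e-6,
) -> Tensor:
    """Magnitude-corrected kernel attention, per head, linear in N = H*W.

    Only ``N x d`` and ``d x d`` intermediates are formed — the ``N x N``
    score matrix never exists.
    """
    for name, t in (("q", q), ("k", k), ("v", v)):
        if not np.all(np.isfinite(t.data)):
            bad = np.argwhere(~np.isfinite(t.data))[0]
            raise FloatingPointError(f"non-finite value in {name} at index {tuple(bad)}")
    if q.shape != k.shape or q.shape != v.shape:
        raise ValueError(f"Q/K/V shapes differ: {q.shape}, {k.shape}, {v.shape}")
    B, C, H, W = q.shape
    head_dim = C // num_heads
    qh = _split_heads(q, num_heads)
    kh = _split_heads(k, num_heads)
    vh = _split_heads(v, num_heads)
    qr = rope2d_rotate(qh, rope)
    kr = rope2d_rotate(kh, rope)
    N = H * W
    # tokens-last layout: (B, heads, N, d)
    phi_q = kernel_map(qr).reshape(B, num_heads, head_dim, N).swapaxes(-1, -2)
    phi_k = kernel_map(kr).reshape(B, num_heads, head_dim, N).swapaxes(-1, -2)
    vt = vh.reshape(B, num_heads, head_dim, N).swapaxes(-1, -2)
    k_mean = phi_k.mean(axis=-2, keepdims=True)  # (B, h, 1, d)
    v_mean = vt.mean(axis=-2, keepdims=True)
    z = (phi_q * k_mean).sum(axis=-1, keepdims=True)  # (B, h, N, 1)
    kv = nn.matmul(phi_k.swapaxes(-1, -2), vt)  # (B, h, d, d)
    linear_term = nn.matmul(phi_q, kv)  # (B, h, N, d)
    out = linear_term * (1.0 + (z + epsilon) ** -1.0) - z * v_mean
    return out.swapaxes(-1, -2).reshape(B, C, H, W)


def dw_lpe(v: Tensor, conv: nn.Conv2d) -> Tensor:
    """5x5 depthwise local positional perturbation of V (no channel mixing)."""
    if conv.groups != conv.in_channels:
        raise ValueError("dw_lpe requires a depthwise convolution (groups == channels)")
    return conv(v)


def mala_fuse(core_out: Tensor, lpe_out: Tensor, o: Tensor, proj: nn.Conv2d) -> Tensor:
    """Gate fusion: ``Proj1x1[(core + lpe) * O]``."""
    if core_out.shape != lpe_out.shape or core_out.shape != o.shape:
        raise ValueError(
            f"shape mismatch: core {core_out.shape}, lpe {lpe_out.shape}, gate {o.shape}"
        )
    return proj((core_out + lpe_out) * o)


class AIFIMALABlock(nn.Module):
    """Full intra-scale block: QKVO -> MALA-Core + DW-LPE -> gate -> post-norm FFN.

    The residual update is ``LN(X + LN(Y + FFN(Y)))`` with a two-layer
    pointwise GELU FFN, layer-normalizing over channels at each position.
    """

    def __init__(
        self,
        embed_dim: int,
        num_heads: int,
        epsilon: float = 1e-6,
        ffn_ratio: float = 2.0,
        rope_base: float = 10000.0,
    ) -> None:
        super().__init__()
        if embed_dim % num_heads:
            raise ValueError(f"embed_dim {embed_dim} not divisible by heads {num_heads}")
        head_dim = embed_dim // num_heads
        if head_dim % 4:
            raise ValueError(f"head_dim {head_dim} must be divisible by 4 for RoPE")
        self.embed_dim = embed_dim
        self.num_heads = num_heads
        self.epsilon = epsilon
        self.rope = build_axial_frequencies(head_dim, base=rope_base)
        self.qkvo = nn.Conv2d(embed_dim, 4 * embed_dim, 1)
        self.lpe = nn.Conv2d(embed_dim, embed_dim, 5, padding=2, groups=embed_dim, bias=False)
        self.proj = nn.Conv2d(embed_dim, embed_dim, 1)
        hidden = int(embed_dim * ffn_ratio)
        self.ffn1 = nn.Conv2d(embed_dim, hidden, 1)
        self.ffn2 = nn.Conv2d(hidden, embed_dim, 1)
        self.norm_inner = nn.LayerNorm2d(embed_dim)
        self.norm_outer = nn.LayerNorm2d(embed_dim)

    def attention(self, x: Tensor) -> Tensor:
        q, k, v, o = qkvo_project(x, self.qkvo)
        core = mala_core(q, k, v, self.rope, self.num_heads, self.epsilon)
        lpe = dw_lpe(v, self.lpe)
        return mala_fuse(core, lpe, o, self.proj)

    def forward(self, x: Tensor) -> Tensor:
        y = self.attention(x)
        inner = self.norm_inner(y + self.ffn2(nn.gelu(self.ffn1(y))))
        return self.norm_outer(x + inner)


class AIFIMHSABlock(nn.Module):
    """Baseline intra-scale block: plain multi-head softmax attention + FFN.

    Pre-norm transformer layout over flattened grid tokens; fills the same
    slot as the MALA block in the ablation grid.
    """

    def __init__(self, embed_dim: int, num_heads: int, ffn_ratio: float = 2.0) -> None:
        super().__init__()
        if embed_dim % num_heads:
            raise ValueError(f"embed_dim {embed_dim} not divisible by heads {num_heads}")
        self.embed_dim = embed_dim
        self.num_heads = num_heads
        self.qkv = nn.Conv2d(embed_dim, 3 * embed_dim, 1)
        self.proj = nn.Conv2d(embed_dim, embed_dim, 1)
        hidden = int(embed_dim * ffn_ratio)
        self.ffn1 = nn.Conv2d(embed_dim, hidden, 1)
        self.ffn2 = nn.Conv2d(hidden, embed_dim, 1)
        self.norm1 = nn.LayerNorm2d(embed_dim)
        self.norm2 = nn.LayerNorm2d(embed_dim)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        h = self.num_heads
        d = C // h
        xn = self.norm1(x)
        qkv = self.qkv(xn)
        q, k, v = qkv[:, :C], qkv[:, C : 2 * C], qkv[:, 2 * C :]
        qt = q.reshape(B, h, d, H * W).swapaxes(-1, -2)
        kt = k.reshape(B, h, d, H * W).swapaxes(-1, -2)
        vt = v.reshape(B, h, d, H * W).swapaxes(-1, -2)
        scores = nn.matmul(qt, kt.swapaxes(-1, -2)) * (1.0 / np.sqrt(d))
        attn = nn.softmax(scores, axis=-1)
        out = nn.matmul(attn, vt).swapaxes(-1, -2).reshape(B, C, H, W)
        x = x + self.proj(out)
        xn = self.norm2(x)
        return x + self.ffn2(nn.gelu(self.ffn1(xn)))
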