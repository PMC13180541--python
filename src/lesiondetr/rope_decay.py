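"""Positional geometry shared by the attention operators.

Two ingredients live here:

* **2D axial rotary positional encoding** — channel pairs of each
  attention head are rotated in the complex plane by angles proportional
  to the grid position; the first half of the head channels encodes the
  row axis, the second half the column axis.  Because rotations compose
  additively, inner products of rotated queries and keys depend only on
  the *relative* offset between positions.
* **Manhattan-distance decay** — a per-head spatial prior
  ``D[n, m] = gamma ** (|x_n - x_m| + |y_n - y_m|)`` attenuating attention
  with city-block distance on the feature grid.  The matrix factorizes
  exactly over the two axes, which is what makes the decomposed
  (axis-separable) retention pass possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor, concatenate, stack

__all__ = [
    "AxialRoPE",
    "DecaySpec",
    "build_axial_frequencies",
    "rope2d_rotate",
    "manhattan_decay",
    "default_gamma_schedule",
]


@dataclass(frozen=True)
class AxialRoPE:
    """Frequency vectors for the row (``freq_h``) and column (``freq_w``) axes.

    ``head_dim`` channels split as: channels ``[0, head_dim/2)`` rotate with
    row-position angles, channels ``[head_dim/2, head_dim)`` with
    column-position angles; within each half, consecutive channel pairs
    ``(2i, 2i+1)`` form one complex plane rotated by ``pos * freq[i]``.
    """

    head_dim: int
    freq_h: np.ndarray
    freq_w: np.ndarray
    base: float = 10000.0

    def angles(self, H: int, W: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-position angle grids, shapes ``(head_dim//4, H, W)`` each."""
        rows = np.arange(H, dtype=float)
        cols = np.arange(W, dtype=float)
        th = self.freq_h[:, None, None] * rows[None, :, None] * np.ones((1, 1, W))
        tw = self.freq_w[:, None, None] * np.ones((1, H, 1)) * cols[None, None, :]
        return th, tw


def build_axial_frequencies(head_dim: int, base: float = 10000.0) -> AxialRoPE:
    """Inverse-power frequency ladder, ``base ** (-2i / (head_dim/2))``.

    Each axis receives ``head_dim // 4`` frequencies (one per channel pair in
    its half), strictly decreasing from 1.
    """
    if head_dim % 4 != 0:
        raise ValueError(f"head_dim must be divisible by 4, got {head_dim}")
    n = head_dim // 4
    exponents = -2.0 * np.arange(n) / (head_dim / 2.0)
    freqs = np.power(float(base), exponents)
    return AxialRoPE(head_dim=head_dim, freq_h=freqs, freq_w=freqs.copy(), base=base)


def _rotate_half(t: Tensor | np.ndarray, cos: np.ndarray, sin: np.ndarray):
    """Rotate channel pairs: ``(a, b) -> (a cos - b sin, a sin + b cos)``.

    ``t`` has channels first ``(..., 2n, H, W)``; ``cos``/``sin`` have shape
    ``(n, H, W)`` and broadcast over leading axes.
    """
    a = t[..., 0::2, :, :]
    b = t[..., 1::2, :, :]
    ra = a * cos - b * sin
    rb = a * sin + b * cos
    # stacking on a new axis right after the pair axis interleaves channels
    # back as (a0, b0, a1, b1, ...) once reshaped
    if isinstance(t, Tensor):
        return stack([ra, rb], axis=-3).reshape(list(t.shape))
    return np.stack([ra, rb], axis=-3).reshape(t.shape)


def rope2d_rotate(t, rope: AxialRoPE):
    """Apply the dual-axis rotation to ``t`` of shape ``(..., head_dim, H, W)``.

    Works on plain arrays and on autodiff tensors (the rotation is linear,
    with constant coefficients, so gradients flow through untouched).
    Positions are the 0-based grid indices; position (0, 0) is the identity.
    """
    *_, C, H, W = t.shape
    if C != rope.head_dim:
        raise ValueError(
            f"channel count {C} does not match rope head_dim {rope.head_dim}"
        )
    th, tw = rope.angles(H, W)
    half = C // 2
    first = t[..., :half, :, :]
    second = t[..., half:, :, :]
    rh = _rotate_half(first, np.cos(th), np.sin(th))
    rw = _rotate_half(second, np.cos(tw), np.sin(tw))
    if isinstance(t, Tensor):
        return concatenate([rh, rw], axis=-3)
    return np.concatenate([rh, rw], axis=-3)


@dataclass(frozen=True)
class DecaySpec:
    """Manhattan decay for one head on an ``H x W`` grid.

    ``D`` is the full ``HW x HW`` matrix in row-major flattening
    (``n = r * W + c``); ``d_row``/``d_col`` are the 1D axis factors whose
    Kronecker-consistent product reconstructs ``D`` exactly.
    """

    gamma: float
    H: int
    W: int
    D: np.ndarray = field(repr=False)
    d_row: np.ndarray = field(repr=False)
    d_col: np.ndarray = field(repr=False)

    def dump(self) -> str:
        """Plain-text rendering of ``D`` for debugging."""
        return "\n".join(
            " ".join(f"{v:.6f}" for v in row) for row in self.D
        )


def manhattan_decay(gamma: float, H: int, W: int) -> DecaySpec:
    """Build the decay spec ``D[n, m] = gamma ** d_manhattan(n, m)``."""
    if not (0.0 < gamma <= 1.0):
        raise ValueError(f"gamma must be in (0, 1], got {gamma}")
    if H < 1 or W < 1:
        raise ValueError(f"grid must be at least 1x1, got {H}x{W}")
    rows = np.arange(H)
    cols = np.arange(W)
    d_row = np.power(gamma, np.abs(rows[:, None] - rows[None, :]).astype(float))
    d_col = np.power(gamma, np.abs(cols[:, None] - cols[None, :]).astype(float))
    # kron over (row, col): D[(r1,c1),(r2,c2)] = d_row[r1,r2] * d_col[c1,c2]
    D = np.kron(d_row, d_col)
    return DecaySpec(gamma=float(gamma), H=H, W=W, D=D, d_row=d_row, d_col=d_col)


def default_gamma_schedule(num_heads: int) -> np.ndarray:
    """Per-head decay rates ``1 - 2**(-5 - i)`` (retention-literature ladder)."""
    return 1.0 - np.power(2.0, -5.0 - np.arange(num_heads, dtype=float))
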