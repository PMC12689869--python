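"""Multi-axis Hadamard-product attention block.

The block splits the channel axis into four groups.  Groups 1-3 receive
element-wise (Hadamard) attention along one axis pair each — height/width,
channel/height and channel/width — with additive position embeddings on the
query/key projections and a learned positional bias on the pre-activation
map; group 4 goes through a residual 3x3 convolution.  The four results are
concatenated, mixed by a 3x3 convolution and passed through an exact GELU.

No pairwise score matrix is ever materialized: the attention map is the
softmax of an element-wise product, so the multiply count grows linearly
with the number of pixels.  ``count_multiplies`` instruments a forward pass
to verify that scaling.
"""

from __future__ import annotations

import contextlib

import numpy as np

from ._layers import Conv2d, Module, Parameter
from ._tensor import Tensor, chunk, concat, resize_bilinear, softmax

__all__ = [
    "AXES",
    "chunk4",
    "HadamardAxisAttention",
    "Group4Conv",
    "MAHABlock",
    "count_multiplies",
]

AXES = ("hw", "ch", "cw")

_MULS = {"active": False, "count": 0}


@contextlib.contextmanager
def count_multiplies():
    """Count scalar multiplications performed by MAHA forwards inside the block."""
    prev = (_MULS["active"], _MULS["count"])
    _MULS["active"], _MULS["count"] = True, 0
    holder = {"count": 0}
    try:
        yield holder
    finally:
        holder["count"] = _MULS["count"]
        _MULS["active"], _MULS["count"] = prev


def _tally(n: int) -> None:
    if _MULS["active"]:
        _MULS["count"] += int(n)


def chunk4(x):
    """Split (B, C, H, W) into four channel groups; lossless partition.

    Accepts a Tensor (differentiable) or ndarray; group ``i`` holds channels
    ``[i*C/4, (i+1)*C/4)``.
    """
    if isinstance(x, Tensor):
        if x.shape[1] % 4:
            raise ValueError(f"channel count {x.shape[1]} not divisible by 4")
        return chunk(x, 4, axis=1)
    x = np.asarray(x)
    if x.shape[1] % 4:
        raise ValueError(f"channel count {x.shape[1]} not divisible by 4")
    return list(np.split(x, 4, axis=1))


class HadamardAxisAttention(Module):
    """Element-wise attention normalized over one axis pair.

    ``axis`` picks the attended plane: "hw" normalizes over all spatial
    positions of each channel, "ch" over the channel-height plane at each
    width, "cw" over the channel-width plane at each height.  Position
    embedding tables are sized for a nominal plane and bilinearly resized
    when a feature map of a different size comes through.
    """

    def __init__(self, channels: int, nominal_hw: tuple[int, int], axis: str,
                 rng: np.random.Generator):
        super().__init__()
        if axis not in AXES:
            raise ValueError(f"unknown axis {axis!r}; expected one of {AXES}")
        self.axis = axis
        self.channels = channels
        self.nominal_hw = tuple(nominal_hw)
        self.q_proj = Conv2d(channels, channels, 1, rng)
        self.k_proj = Conv2d(channels, channels, 1, rng)
        self.v_proj = Conv2d(channels, channels, 1, rng)
        h, w = nominal_hw
        plane = {"hw": (1, 1, h, w), "ch": (1, channels, h, 1), "cw": (1, channels, 1, w)}[axis]
        scale = 0.02
        self.pos_q = Parameter(rng.normal(0.0, scale, size=plane))
        self.pos_k = Parameter(rng.normal(0.0, scale, size=plane))
        self.pos_bias = Parameter(rng.normal(0.0, scale, size=plane))

    def _table(self, p: Parameter, H: int, W: int) -> Tensor:
        if self.axis == "ch":
            want_h, want_w = H, 1
        elif self.axis == "cw":
            want_h, want_w = 1, W
        else:
            want_h, want_w = H, W
        if p.shape[2:] == (want_h, want_w):
            return p
        return resize_bilinear(p, (want_h, want_w))

    def _softmax_plane(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if self.axis == "hw":
            return softmax(x.reshape(B, C, H * W), axis=-1).reshape(B, C, H, W)
        if self.axis == "ch":
            t = x.transpose(0, 3, 1, 2).reshape(B, W, C * H)
            t = softmax(t, axis=-1)
            return t.reshape(B, W, C, H).transpose(0, 2, 3, 1)
        t = x.transpose(0, 2, 1, 3).reshape(B, H, C * W)
        t = softmax(t, axis=-1)
        return t.reshape(B, H, C, W).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        B, C, H, W = x.shape
        if C != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {C}")
        q = self.q_proj(x) + self._table(self.pos_q, H, W)
        k = self.k_proj(x) + self._table(self.pos_k, H, W)
        v = self.v_proj(x)
        pre = q * k + self._table(self.pos_bias, H, W)
        weights = self._softmax_plane(pre)
        out = weights * v
        # 3 pointwise projections + q*k + w*v, all linear in B*C*H*W
        _tally(3 * B * C * C * H * W + 2 * B * C * H * W)
        return out

    def attention_weights(self, x: Tensor) -> np.ndarray:
        """Normalized attention map (sums to 1 over the attended plane)."""
        x = x if isinstance(x, Tensor) else Tensor(x)
        q = self.q_proj(x) + self._table(self.pos_q, *x.shape[2:])
        k = self.k_proj(x) + self._table(self.pos_k, *x.shape[2:])
        pre = q * k + self._table(self.pos_bias, *x.shape[2:])
        return self._softmax_plane(pre).data


class Group4Conv(Module):
    """Residual 3x3 convolution for the fourth group."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(channels, channels, 3, rng, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        B, C, H, W = x.shape
        _tally(B * C * C * 9 * H * W)
        return self.conv(x) + x


class MAHABlock(Module):
    """Four-group multi-axis Hadamard attention with a GELU-activated merge."""

    def __init__(self, channels: int, nominal_hw: tuple[int, int], rng: np.random.Generator):
        super().__init__()
        if channels % 4:
            raise ValueError(f"channel count {channels} not divisible by 4")
        self.channels = channels
        gc = channels // 4
        gh = (nominal_hw[0], nominal_hw[1])
        self.attn_hw = HadamardAxisAttention(gc, gh, "hw", rng)
        self.attn_ch = HadamardAxisAttention(gc, gh, "ch", rng)
        self.attn_cw = HadamardAxisAttention(gc, gh, "cw", rng)
        self.group4 = Group4Conv(gc, rng)
        self.merge = Conv2d(channels, channels, 3, rng, padding=1)

    def forward(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        g1, g2, g3, g4 = chunk4(x)
        o1 = self.attn_hw(g1) + g1
        o2 = self.attn_ch(g2) + g2
        o3 = self.attn_cw(g3) + g3
        o4 = self.group4(g4)
        merged = concat([o1, o2, o3, o4], axis=1)
        B, C, H, W = merged.shape
        _tally(B * C * C * 9 * H * W)
        return self.merge(merged).gelu()
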