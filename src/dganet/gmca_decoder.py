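"""Group multi-head cross-attention decoder stage.

Each stage upsamples the previous decoder state, fuses it group-wise with the
two encoder skips under layer normalization, and runs two parallel paths:

* FFAB — four dilated 3x3 convolutions (dilations 1, 2, 5, 7, one per fused
  group) whose outputs are concatenated along channels;
* MIAF — two multi-head cross-attention arms over flattened spatial tokens,
  queries from the upsampled decoder state, keys/values from each encoder
  skip, combined by element-wise addition.

The two path outputs are each projected to the stage width by a 1x1
convolution and summed.  When the token count exceeds ``token_budget`` the
maps are average-pooled before attention and bilinearly restored after.
"""

from __future__ import annotations

import math

import numpy as np

from ._layers import ChannelLayerNorm, Conv2d, Linear, Module
from ._tensor import (Tensor, avgpool2x2, chunk, concat, resize_bilinear,
                      softmax, upsample2x)

__all__ = ["upsample2x", "GroupFuse", "FFAB", "MIAF", "GMCAStage", "FFAB_DILATIONS"]

FFAB_DILATIONS = (1, 2, 5, 7)


def _ensure_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class GroupFuse(Module):
    """Chunk three aligned maps into 4 channel groups and layer-normalize
    the concatenation of corresponding groups."""

    def __init__(self, channels_up: int, channels_fsmf: int, channels_maha: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        for name, c in (("decoder", channels_up), ("fsmf", channels_fsmf),
                        ("maha", channels_maha)):
            if c % 4:
                raise ValueError(f"{name} channel count {c} not divisible by 4")
        self.group_channels = (channels_up + channels_fsmf + channels_maha) // 4
        self.norms = [ChannelLayerNorm(self.group_channels) for _ in range(4)]
        for i, n in enumerate(self.norms):
            setattr(self, f"norm{i}", n)

    def forward(self, up, fsmf, maha) -> list[Tensor]:
        up, fsmf, maha = map(_ensure_tensor, (up, fsmf, maha))
        if not (up.shape[2:] == fsmf.shape[2:] == maha.shape[2:]):
            raise ValueError(
                f"spatial mismatch: {up.shape[2:]} vs {fsmf.shape[2:]} vs {maha.shape[2:]}")
        gu, gf, gm = chunk(up, 4, 1), chunk(fsmf, 4, 1), chunk(maha, 4, 1)
        return [self.norms[i](concat([gu[i], gf[i], gm[i]], axis=1)) for i in range(4)]


class FFAB(Module):
    """Four-branch dilated aggregation; dilation d uses padding d (size preserving)."""

    def __init__(self, group_channels: int, rng: np.random.Generator):
        super().__init__()
        self.group_channels = group_channels
        self.branches = []
        for i, d in enumerate(FFAB_DILATIONS):
            conv = Conv2d(group_channels, group_channels, 3, rng, padding=d, dilation=d)
            self.branches.append(conv)
            setattr(self, f"dilated{d}", conv)

    @property
    def out_channels(self) -> int:
        return 4 * self.group_channels

    def forward(self, groups) -> Tensor:
        if len(groups) != 4:
            raise ValueError(f"FFAB expects 4 fused groups, got {len(groups)}")
        groups = [_ensure_tensor(g) for g in groups]
        shape0 = groups[0].shape
        if any(g.shape != shape0 for g in groups):
            raise ValueError("fused groups must share a shape")
        outs = [conv(g) for conv, g in zip(self.branches, groups)]
        return concat(outs, axis=1)


def _multi_head_attention(q: Tensor, k: Tensor, v: Tensor, heads: int) -> Tensor:
    """softmax(Q K^T / sqrt(D/H)) V per head over (B, L, D) token stacks."""
    B, L, D = q.shape
    Lk = k.shape[1]
    dh = D // heads
    qh = q.reshape(B, L, heads, dh).transpose(0, 2, 1, 3)
    kh = k.reshape(B, Lk, heads, dh).transpose(0, 2, 1, 3)
    vh = v.reshape(B, Lk, heads, dh).transpose(0, 2, 1, 3)
    scores = (qh @ kh.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(D / heads))
    attn = softmax(scores, axis=-1)
    out = attn @ vh
    return out.transpose(0, 2, 1, 3).reshape(B, L, D)


class MIAF(Module):
    """Two-arm multi-head cross-attention over flattened spatial tokens."""

    def __init__(self, channels_up: int, channels_fsmf: int, channels_maha: int,
                 embed_dim: int, heads: int, rng: np.random.Generator,
                 token_budget: int = 4096):
        super().__init__()
        if embed_dim % heads:
            raise ValueError(f"embedding dim {embed_dim} not divisible by {heads} heads")
        self.embed_dim = embed_dim
        self.heads = heads
        self.token_budget = token_budget
        self.q_fl = Linear(channels_up, embed_dim, rng)
        self.k_fl = Linear(channels_fsmf, embed_dim, rng)
        self.v_fl = Linear(channels_fsmf, embed_dim, rng)
        self.q_mh = Linear(channels_up, embed_dim, rng)
        self.k_mh = Linear(channels_maha, embed_dim, rng)
        self.v_mh = Linear(channels_maha, embed_dim, rng)

    @staticmethod
    def _tokens(x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        return x.reshape(B, C, H * W).transpose(0, 2, 1)

    def forward(self, up, fsmf, maha) -> Tensor:
        up, fsmf, maha = map(_ensure_tensor, (up, fsmf, maha))
        if not (up.shape[2:] == fsmf.shape[2:] == maha.shape[2:]):
            raise ValueError("MIAF inputs must share spatial dimensions")
        B, _, H, W = up.shape
        h, w = H, W
        while h * w > self.token_budget and h % 2 == 0 and w % 2 == 0:
            up, fsmf, maha = avgpool2x2(up), avgpool2x2(fsmf), avgpool2x2(maha)
            h, w = h // 2, w // 2
        tu, tf, tm = self._tokens(up), self._tokens(fsmf), self._tokens(maha)
        arm_fl = _multi_head_attention(self.q_fl(tu), self.k_fl(tf), self.v_fl(tf), self.heads)
        arm_mh = _multi_head_attention(self.q_mh(tu), self.k_mh(tm), self.v_mh(tm), self.heads)
        fused = arm_fl + arm_mh
        out = fused.transpose(0, 2, 1).reshape(B, self.embed_dim, h, w)
        if (h, w) != (H, W):
            out = resize_bilinear(out, (H, W))
        return out


class GMCAStage(Module):
    """Full decoder stage: upsample, group-fuse, FFAB + MIAF, project and sum."""

    def __init__(self, channels_prev: int, channels_fsmf: int, channels_maha: int,
                 out_channels: int, rng: np.random.Generator, heads: int = 4,
                 token_budget: int = 4096, upsample: bool = True,
                 combine: str = "add"):
        super().__init__()
        if combine not in ("add", "concat"):
            raise ValueError(f"unknown combine rule {combine!r}")
        self.upsample = upsample
        self.combine = combine
        self.fuse = GroupFuse(channels_prev, channels_fsmf, channels_maha)
        self.ffab = FFAB(self.fuse.group_channels, rng)
        self.miaf = MIAF(channels_prev, channels_fsmf, channels_maha,
                         embed_dim=out_channels, heads=heads,
                         rng=rng, token_budget=token_budget)
        self.proj_ffab = Conv2d(self.ffab.out_channels, out_channels, 1, rng)
        self.proj_miaf = Conv2d(out_channels, out_channels, 1, rng)
        if combine == "concat":
            self.proj_cat = Conv2d(2 * out_channels, out_channels, 1, rng)

    def forward(self, prev, fsmf, maha) -> Tensor:
        prev, fsmf, maha = map(_ensure_tensor, (prev, fsmf, maha))
        up = upsample2x(prev) if self.upsample else prev
        groups = self.fuse(up, fsmf, maha)
        a = self.proj_ffab(self.ffab(groups))
        b = self.proj_miaf(self.miaf(up, fsmf, maha))
        if self.combine == "add":
            return a + b
        return self.proj_cat(concat([a, b], axis=1))
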