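"""Independent brute-force oracles used by the test-suite.

Everything here is deliberately written as literal summations and loops,
sharing no code path with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def dft2_oracle(x: np.ndarray) -> np.ndarray:
    """Direct O(N^4) evaluation of the 2-D DFT of one (H, W) map."""
    H, W = x.shape
    F = np.zeros((H, W), dtype=complex)
    for u in range(H):
        for v in range(W):
            s = 0.0 + 0.0j
            for h in range(H):
                for w in range(W):
                    s += x[h, w] * np.exp(-2j * np.pi * (u * h / H + v * w / W))
            F[u, v] = s
    return F


def idft2_oracle(F: np.ndarray) -> np.ndarray:
    """Direct inverse DFT (complex result; caller takes the real part)."""
    H, W = F.shape
    x = np.zeros((H, W), dtype=complex)
    for h in range(H):
        for w in range(W):
            s = 0.0 + 0.0j
            for u in range(H):
                for v in range(W):
                    s += F[u, v] * np.exp(2j * np.pi * (u * h / H + v * w / W))
            x[h, w] = s / (H * W)
    return x


def conv2d_oracle(x: np.ndarray, w: np.ndarray, b=None, stride: int = 1,
                  padding: int = 0, dilation: int = 1) -> np.ndarray:
    """Naive loop convolution (cross-correlation) over (B,C,H,W)."""
    B, C, H, W = x.shape
    O, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    eh, ew = (kh - 1) * dilation + 1, (kw - 1) * dilation + 1
    Ho = (xp.shape[2] - eh) // stride + 1
    Wo = (xp.shape[3] - ew) // stride + 1
    out = np.zeros((B, O, Ho, Wo))
    for bb in range(B):
        for o in range(O):
            for i in range(Ho):
                for j in range(Wo):
                    acc = 0.0
                    for c in range(C):
                        for ki in range(kh):
                            for kj in range(kw):
                                acc += (xp[bb, c, i * stride + ki * dilation,
                                           j * stride + kj * dilation]
                                        * w[o, c, ki, kj])
                    out[bb, o, i, j] = acc + (0.0 if b is None else b[o])
    return out


def axis_attention_oracle(block, x: np.ndarray) -> np.ndarray:
    """Loop re-implementation of one Hadamard axis-attention forward."""
    B, C, H, W = x.shape

    def proj(conv, with_bias=True):
        wgt = conv.weight.data[:, :, 0, 0]
        out = np.zeros((B, C, H, W))
        for bb in range(B):
            for c in range(C):
                for cc in range(C):
                    out[bb, c] += wgt[c, cc] * x[bb, cc]
                if with_bias and conv.bias is not None:
                    out[bb, c] += conv.bias.data[c]
        return out

    def table(p):
        t = p.data
        assert t.shape[2:] in ((H, W), (C, H), (C, W), (H, 1), (1, W)) or True
        return np.broadcast_to(t, (1, t.shape[1], t.shape[2], t.shape[3]))

    q = proj(block.q_proj) + block.pos_q.data
    k = proj(block.k_proj) + block.pos_k.data
    v = proj(block.v_proj)
    pre = q * k + block.pos_bias.data

    out = np.zeros_like(pre)
    if block.axis == "hw":
        for bb in range(B):
            for c in range(C):
                e = np.exp(pre[bb, c] - pre[bb, c].max())
                out[bb, c] = e / e.sum() * v[bb, c]
    elif block.axis == "ch":
        for bb in range(B):
            for w_ in range(W):
                plane = pre[bb, :, :, w_]
                e = np.exp(plane - plane.max())
                out[bb, :, :, w_] = e / e.sum() * v[bb, :, :, w_]
    else:  # cw
        for bb in range(B):
            for h_ in range(H):
                plane = pre[bb, :, h_, :]
                e = np.exp(plane - plane.max())
                out[bb, :, h_, :] = e / e.sum() * v[bb, :, h_, :]
    return out


def multi_head_attention_oracle(q: np.ndarray, k: np.ndarray, v: np.ndarray,
                                heads: int) -> np.ndarray:
    """Literal per-head scaled dot-product attention over (B, L, D) stacks."""
    B, L, D = q.shape
    Lk = k.shape[1]
    dh = D // heads
    out = np.zeros((B, L, D))
    for bb in range(B):
        for h in range(heads):
            qs = q[bb, :, h * dh:(h + 1) * dh]
            ks = k[bb, :, h * dh:(h + 1) * dh]
            vs = v[bb, :, h * dh:(h + 1) * dh]
            for i in range(L):
                scores = np.array([qs[i] @ ks[j] for j in range(Lk)]) / math.sqrt(D / heads)
                e = np.exp(scores - scores.max())
                a = e / e.sum()
                out[bb, i, h * dh:(h + 1) * dh] = sum(a[j] * vs[j] for j in range(Lk))
    return out


def bilinear_upsample2x_oracle(x: np.ndarray) -> np.ndarray:
    """Per-pixel align_corners=False bilinear x2 upsampling of (B,C,H,W)."""
    B, C, H, W = x.shape
    out = np.zeros((B, C, 2 * H, 2 * W))
    for i in range(2 * H):
        for j in range(2 * W):
            sy = (i + 0.5) / 2.0 - 0.5
            sx = (j + 0.5) / 2.0 - 0.5
            y0, x0 = math.floor(sy), math.floor(sx)
            fy, fx = sy - y0, sx - x0
            y0c, y1c = min(max(y0, 0), H - 1), min(max(y0 + 1, 0), H - 1)
            x0c, x1c = min(max(x0, 0), W - 1), min(max(x0 + 1, 0), W - 1)
            out[:, :, i, j] = ((1 - fy) * (1 - fx) * x[:, :, y0c, x0c]
                               + (1 - fy) * fx * x[:, :, y0c, x1c]
                               + fy * (1 - fx) * x[:, :, y1c, x0c]
                               + fy * fx * x[:, :, y1c, x1c])
    return out


def boundary_oracle(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with >=1 background face-neighbor (edges = background)."""
    out = np.zeros_like(mask, dtype=bool)
    it = np.ndindex(mask.shape)
    for idx in it:
        if not mask[idx]:
            continue
        for ax in range(mask.ndim):
            for d in (-1, 1):
                nb = list(idx)
                nb[ax] += d
                if nb[ax] < 0 or nb[ax] >= mask.shape[ax]:
                    out[idx] = True
                    break
                if not mask[tuple(nb)]:
                    out[idx] = True
                    break
            if out[idx]:
                break
    return out


def surface_metrics_oracle(a: np.ndarray, b: np.ndarray, spacing) -> tuple[float, float]:
    """All-pairs (assd, hd95) between two non-empty masks."""
    spacing = np.asarray(spacing, dtype=float)
    pa = np.argwhere(boundary_oracle(a)) * spacing
    pb = np.argwhere(boundary_oracle(b)) * spacing
    d_ab = [min(np.sqrt(((p - q) ** 2).sum()) for q in pb) for p in pa]
    d_ba = [min(np.sqrt(((p - q) ** 2).sum()) for q in pa) for p in pb]
    assd = 0.5 * (np.mean(d_ab) + np.mean(d_ba))
    hd95 = float(np.percentile(np.asarray(d_ab + d_ba), 95))
    return assd, hd95
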