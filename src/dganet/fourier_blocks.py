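"""Spectral-branch building blocks.

This module provides two surfaces:

* a functional, NumPy-level API around :class:`FeatureMap` and
  :class:`SpectralPair` (``fft2d`` / ``ifft2d`` / ``amplitude_phase``), used
  for analysis and as the reference semantics of the learned blocks, and
* differentiable blocks (:class:`ConvFFTBlock`, :class:`SpectrumLearning`,
  :class:`MultiscaleFusion`, :class:`FSMFUnit`, :class:`DConvBlock`,
  :class:`ConvOpBlock`) used by the encoder.

The spectrum-learning unit runs two independent 1x1-conv branches on the real
and imaginary parts of the spectrum, inverts the transform, applies a 3x3
convolution and adds the input back, then a three-way multi-scale fusion
(plain conv path, down/up conv path, identity path) refines the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._layers import BatchNorm2d, Conv2d, Module, ReLU, Sequential
from ._tensor import Tensor, avgpool2x2, conv2d, fft2, ifft2, maxpool2x2, upsample2x

__all__ = [
    "FeatureMap",
    "SpectralPair",
    "fft2d",
    "ifft2d",
    "amplitude_phase",
    "spectral_energy",
    "ConvFFTBlock",
    "SpectrumLearning",
    "MultiscaleFusion",
    "FSMFUnit",
    "ConvOpBlock",
    "DoubleConv",
    "DConvBlock",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class FeatureMap:
    """Real-valued (batch, channel, height, width) activation map."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"FeatureMap must be 4-D (B,C,H,W), got ndim={self.data.ndim}")
        if min(self.data.shape[2:]) < 1:
            raise ValueError("spatial dimensions must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("FeatureMap entries must be finite")


@dataclass
class SpectralPair:
    """Real/imaginary parts of the 2-D DFT of a real FeatureMap.

    When ``full_spectrum`` is False the last axis holds the non-redundant
    half-spectrum of a real input (W' = W//2 + 1) and ``spatial_width``
    records the original width needed to invert the transform.
    """

    real: np.ndarray
    imag: np.ndarray
    full_spectrum: bool = True
    spatial_width: int | None = None

    def __post_init__(self):
        self.real = np.asarray(self.real, dtype=np.float64)
        self.imag = np.asarray(self.imag, dtype=np.float64)
        if self.real.shape != self.imag.shape:
            raise ValueError("real and imaginary parts must share a shape")
        if self.full_spectrum:
            self.spatial_width = self.real.shape[-1]
        elif self.spatial_width is None:
            raise ValueError("half-spectrum pairs need spatial_width")

    @property
    def amplitude(self) -> np.ndarray:
        return np.hypot(self.real, self.imag)


def _as_array(x) -> np.ndarray:
    return x.data if isinstance(x, FeatureMap) else np.asarray(x, dtype=np.float64)


# ---------------------------------------------------------------------------
# Functional transforms
# ---------------------------------------------------------------------------


def fft2d(x, full_spectrum: bool = False) -> SpectralPair:
    """2-D DFT of a real map over the trailing two axes.

    By default the half-spectrum of the real input is stored; pass
    ``full_spectrum=True`` for the complete (H, W) grid of coefficients.
    """
    arr = _as_array(x)
    if not np.isfinite(arr).all():
        raise ValueError("fft2d input must be finite")
    if full_spectrum:
        spec = np.fft.fft2(arr, axes=(-2, -1))
        return SpectralPair(spec.real, spec.imag, full_spectrum=True)
    spec = np.fft.rfft2(arr, axes=(-2, -1))
    return SpectralPair(spec.real, spec.imag, full_spectrum=False,
                        spatial_width=arr.shape[-1])


def ifft2d(s: SpectralPair) -> FeatureMap:
    """Inverse 2-D DFT; sub-1e-5 imaginary residue of the inversion is dropped."""
    spec = s.real + 1j * s.imag
    if s.full_spectrum:
        out = np.fft.ifft2(spec, axes=(-2, -1))
        out = out.real
    else:
        out = np.fft.irfft2(spec, s=(s.real.shape[-2], s.spatial_width), axes=(-2, -1))
    out = np.asarray(out, dtype=np.float64)
    if out.ndim != 4:
        out = out.reshape((1,) * (4 - out.ndim) + out.shape)
    return FeatureMap(out)


def amplitude_phase(s: SpectralPair) -> tuple[np.ndarray, np.ndarray]:
    """Polar view of a spectrum; zero-magnitude bins get phase 0 by convention."""
    amplitude = np.hypot(s.real, s.imag)
    phase = np.arctan2(s.imag, s.real)
    phase = np.where(amplitude == 0.0, 0.0, phase)
    return amplitude, phase


def spectral_energy(s: SpectralPair) -> np.ndarray:
    """Sum of squared spectral magnitudes per (batch, channel) map.

    Accounts for the conjugate-symmetric columns dropped by the
    half-spectrum storage, so Parseval's identity can be checked in
    either representation.
    """
    mag2 = s.real**2 + s.imag**2
    if s.full_spectrum:
        return mag2.sum(axis=(-2, -1))
    w = np.full(mag2.shape[-1], 2.0)
    w[0] = 1.0
    if s.spatial_width % 2 == 0:
        w[-1] = 1.0
    return (mag2 * w).sum(axis=(-2, -1))


# ---------------------------------------------------------------------------
# Learned blocks
# ---------------------------------------------------------------------------


def _ensure_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(_as_array(x))


class ConvFFTBlock(Module):
    """FFT -> shared 1x1 channel mix of real/imag parts -> inverse FFT.

    The same real-valued 1x1 kernel is applied to both spectral parts (a
    real-linear channel mix of the complex spectrum); the bias acts on the
    real part only so the inverted map stays consistent with a spatial bias.
    """

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.mix = Conv2d(in_channels, out_channels, 1, rng)

    def forward(self, x) -> Tensor:
        x = _ensure_tensor(x)
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"channel mismatch: got {x.shape[1]}, block expects {self.in_channels}")
        re, im = fft2(x)
        re2 = self.mix(re)
        im2 = conv2d(im, self.mix.weight)  # shared weights, no bias on the imaginary part
        return ifft2(re2, im2)


class SpectrumLearning(Module):
    """Residual spectral unit: per-part 1x1 bottlenecks in Fourier space.

    out = conv3x3(IFFT(branch(Re F), branch(Im F))) + x with each branch
    conv1x1 -> LeakyReLU(0.01) -> conv1x1.
    """

    negative_slope = 0.01

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.real_a = Conv2d(channels, channels, 1, rng)
        self.real_b = Conv2d(channels, channels, 1, rng)
        self.imag_a = Conv2d(channels, channels, 1, rng)
        self.imag_b = Conv2d(channels, channels, 1, rng)
        self.post = Conv2d(channels, channels, 3, rng, padding=1)

    def forward(self, x) -> Tensor:
        x = _ensure_tensor(x)
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        re, im = fft2(x)
        re = self.real_b(self.real_a(re).leaky_relu(self.negative_slope))
        im = self.imag_b(self.imag_a(im).leaky_relu(self.negative_slope))
        spatial = ifft2(re, im)
        return self.post(spatial) + x


class MultiscaleFusion(Module):
    """Three-way residual fusion: conv path + down/conv/up path + identity."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.conv_full = Conv2d(channels, channels, 3, rng, padding=1)
        self.bn_full = BatchNorm2d(channels)
        self.conv_half = Conv2d(channels, channels, 3, rng, padding=1)
        self.bn_half = BatchNorm2d(channels)

    def forward(self, x) -> Tensor:
        x = _ensure_tensor(x)
        H, W = x.shape[2:]
        if H % 2 or W % 2:
            raise ValueError(
                f"multi-scale fusion needs even spatial size for its down/up path, got {H}x{W}")
        ch1 = self.bn_full(self.conv_full(x)).relu()
        ch2 = upsample2x(self.bn_half(self.conv_half(avgpool2x2(x))).relu())
        return ch1 + ch2 + x


class FSMFUnit(Module):
    """Spectrum learning followed by multi-scale fusion (channel preserving)."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.spectrum = SpectrumLearning(channels, rng)
        self.fusion = MultiscaleFusion(channels, rng)

    def forward(self, x) -> Tensor:
        return self.fusion(self.spectrum(x))


class ConvOpBlock(Module):
    """3x3 convolution + ReLU, size preserving."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, 3, rng, padding=1)

    def forward(self, x) -> Tensor:
        return self.conv(_ensure_tensor(x)).relu()


class DoubleConv(Module):
    """Two (conv3x3 -> BN -> ReLU) stages, size preserving."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.body = Sequential(
            Conv2d(in_channels, out_channels, 3, rng, padding=1),
            BatchNorm2d(out_channels),
            ReLU(),
            Conv2d(out_channels, out_channels, 3, rng, padding=1),
            BatchNorm2d(out_channels),
            ReLU(),
        )

    def forward(self, x) -> Tensor:
        return self.body(_ensure_tensor(x))


class DConvBlock(Module):
    """DoubleConv followed by 2x2 max-pooling (stride 2); halves resolution."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.convs = DoubleConv(in_channels, out_channels, rng)

    def forward(self, x) -> Tensor:
        x = _ensure_tensor(x)
        H, W = x.shape[2:]
        if H % 2 or W % 2:
            raise ValueError(f"DConv needs even spatial size to pool, got {H}x{W}")
        return maxpool2x2(self.convs(x))

    def pre_pool(self, x) -> Tensor:
        return self.convs(_ensure_tensor(x))
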