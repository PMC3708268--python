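"""Frequency-domain image restoration for blurred, noisy CT slices.

A degraded slice is modelled in the Fourier domain as G(u,v) = F(u,v)·H(u,v)
plus additive noise, where F is the clean image and H the blur transfer
function (typically linear camera/patient motion).  Restoration uses the
regularized estimator

    F_hat(u,v) = |H|^2 · G / (|H|^2 · H + K)

which reduces to plain inverse filtering G/H at K = 0 and attenuates
frequencies where H is small when K > 0.  K trades noise amplification
against residual blur; it is a configuration value here, with
:func:`wiener_k_sweep` available to pick it against a known reference
(only meaningful on phantoms, where the clean image exists).

All spectral operations use the circular (FFT) convolution convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BlurSpec",
    "Histogram",
    "motion_blur",
    "identity_blur",
    "blur_forward",
    "wiener_restore",
    "histogram",
    "mse",
    "wiener_k_sweep",
]


@dataclass
class BlurSpec:
    """Frequency-domain transfer function H(u,v) with regularization K.

    ``transfer`` must match the FFT shape of the images it is applied to.
    ``K`` may be a non-negative scalar (the documented default) or a
    frequency grid of the same shape.
    """

    transfer: np.ndarray
    K: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        self.transfer = np.asarray(self.transfer, dtype=complex)
        if self.transfer.ndim != 2:
            raise ValueError("transfer function must be a 2-D frequency grid")
        if np.any(np.asarray(self.K) < 0):
            raise ValueError("regularization constant K must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.transfer.shape


@dataclass
class Histogram:
    """Equal-width intensity histogram over [0, 1]."""

    bin_edges: np.ndarray
    counts: np.ndarray


def _motion_kernel(length: int, angle_deg: float) -> np.ndarray:
    """Normalized linear-motion point-spread function (DC gain 1)."""
    if length < 1:
        raise ValueError("blur length must be >= 1")
    if length == 1:
        return np.ones((1, 1))
    theta = np.deg2rad(angle_deg)
    # sample `length` points along the line and accumulate onto the grid
    half = (length - 1) / 2.0
    size = length + 1 if length % 2 == 0 else length
    kernel = np.zeros((size, size))
    c = size // 2
    for s in np.linspace(-half, half, length):
        r = int(round(c - s * np.sin(theta)))
        col = int(round(c + s * np.cos(theta)))
        kernel[r, col] += 1.0
    return kernel / kernel.sum()


def motion_blur(shape: tuple[int, int], length: int, angle_deg: float = 0.0,
                K: float | np.ndarray = 0.0) -> BlurSpec:
    """Build the transfer function of a linear-motion blur.

    The kernel is a normalized line of ``length`` pixels at ``angle_deg``
    (0 = horizontal motion), centred at the origin with circular wrap, so
    the resulting H has unit DC gain.
    """
    kernel = _motion_kernel(length, angle_deg)
    padded = np.zeros(shape)
    kh, kw = kernel.shape
    padded[:kh, :kw] = kernel
    padded = np.roll(padded, (-(kh // 2), -(kw // 2)), axis=(0, 1))
    return BlurSpec(transfer=np.fft.fft2(padded), K=K)


def identity_blur(shape: tuple[int, int], K: float | np.ndarray = 0.0) -> BlurSpec:
    """H ≡ 1: the no-blur transfer function."""
    return BlurSpec(transfer=np.ones(shape, dtype=complex), K=K)


def _check_shapes(image: np.ndarray, blur: BlurSpec) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.shape != blur.shape:
        raise ValueError(
            f"image shape {image.shape} does not match transfer shape {blur.shape}")
    return image


def blur_forward(image: np.ndarray, blur: BlurSpec) -> np.ndarray:
    """Apply the degradation model G = F·H (spatial-domain result)."""
    image = _check_shapes(image, blur)
    return np.real(np.fft.ifft2(np.fft.fft2(image) * blur.transfer))


def wiener_restore(degraded: np.ndarray, blur: BlurSpec) -> np.ndarray:
    """Restore a degraded image with F_hat = |H|²G / (|H|²H + K).

    With K = 0 this is exact inverse filtering and requires H to be
    nonzero everywhere; linear-motion transfer functions are sinc-like
    and do have exact zeros at some frequencies for even lengths, in
    which case a positive K is mandatory.
    """
    degraded = _check_shapes(degraded, blur)
    H = blur.transfer
    K = np.asarray(blur.K, dtype=float)
    H2 = np.abs(H) ** 2
    denom = H2 * H + K
    if np.any(np.abs(denom) == 0):
        raise ValueError(
            "inverse-filter singularity: the transfer function has exact zeros "
            "(the sinc-like spectrum of a motion blur vanishes at some "
            "frequencies); use K > 0")
    G = np.fft.fft2(degraded)
    F_hat = H2 * G / denom
    return np.real(np.fft.ifft2(F_hat))


def histogram(image: np.ndarray, n_bins: int = 64) -> Histogram:
    """Intensity histogram with equal-width bins over [0, 1].

    The last bin is right-closed so a pixel at exactly 1.0 is counted.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    counts, edges = np.histogram(np.asarray(image), bins=n_bins, range=(0.0, 1.0))
    return Histogram(bin_edges=edges, counts=counts)


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared pixel difference between two same-shape images."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def wiener_k_sweep(degraded: np.ndarray, blur: BlurSpec, reference: np.ndarray,
                   k_grid: Sequence[float]) -> tuple[float, list[tuple[float, float]]]:
    """Sweep K over a grid and report mse(restored, reference) for each.

    Returns ``(best_k, [(k, mse), ...])``.  Requires a clean reference, so
    it is usable only when ground truth exists (phantom studies).
    """
    results = []
    for k in k_grid:
        restored = wiener_restore(degraded, BlurSpec(transfer=blur.transfer, K=k))
        results.append((float(k), mse(restored, reference)))
    best_k = min(results, key=lambda kr: kr[1])[0]
    return best_k, results
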