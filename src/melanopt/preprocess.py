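"""Artifact removal and sharpening for dermoscopy images.

Thin dark structures — hair strands and superficial vessels, typically
under 10 px across — are removed with directional grey-level closings
(a 10-px vertical line element followed by a 10-px horizontal one), and the
blur this introduces is compensated by subtracting a zero-sum
Laplacian-of-Gaussian response from the closed image.

Images are float arrays in [0, 1], shape (H, W) or (H, W, 3); RGB images
are processed per channel. All border handling is edge replication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "PreprocessConfig",
    "morphological_close_directional",
    "log_kernel",
    "unsharp_filter",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the artifact-removal chain.

    se_len : length in px of the line structuring elements (default 10, so
        structures thinner than 10 px are closed over).
    delta : Laplacian-of-Gaussian scale in px.
    kernel_radius : half-side of the LoG kernel; must cover >= 2*delta.
    clip : clip the final image back to [0, 1].
    """

    se_len: int = 10
    delta: float = 1.5
    kernel_radius: int = 6
    clip: bool = True

    def __post_init__(self):
        if self.se_len < 1:
            raise ValueError("se_len must be >= 1")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.kernel_radius < 2 * self.delta:
            raise ValueError("kernel_radius must be >= 2*delta")


def _check_image(image) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim not in (2, 3):
        raise ValueError(f"expected 2-D or 3-plane image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


def cross_footprint(se_len: int) -> np.ndarray:
    """Cross-shaped structuring element: a vertical and a horizontal line
    arm through each pixel, symmetrized to odd support (2*(se_len//2)+1)."""
    half = se_len // 2
    n = 2 * half + 1
    fp = np.zeros((n, n), dtype=bool)
    fp[:, half] = True
    fp[half, :] = True
    return fp


def _close_2d(plane: np.ndarray, se_len: int) -> np.ndarray:
    return ndimage.grey_closing(plane, footprint=cross_footprint(se_len),
                                mode="nearest")


def morphological_close_directional(image, se_len: int = 10) -> np.ndarray:
    """Remove thin dark structures with a directional-cross grey closing.

    The structuring element is the union of a vertical (90 degree) and a
    horizontal (180 degree) line arm of ``se_len`` px through each pixel.
    The grey closing (dilation then erosion) with this element raises any
    dark structure too thin to contain one of the arms — hair strands and
    vessels under ``se_len`` px across — to the surrounding level, while
    regions wider than ``se_len`` in both axes keep their interior exactly.
    A true closing: idempotent and extensive. RGB images are closed per
    channel.
    """
    img = _check_image(image)
    if se_len < 1:
        raise ValueError("se_len must be >= 1")
    if img.ndim == 2:
        return _close_2d(img, se_len)
    return np.stack([_close_2d(img[..., c], se_len) for c in range(img.shape[-1])], axis=-1)


def log_kernel(delta: float, kernel_radius: int) -> np.ndarray:
    """Discrete Laplacian-of-Gaussian kernel, renormalized to zero sum.

    k(x, y) = -(1 / (pi*delta^4)) * (1 - r2/(2*delta^2)) * exp(-r2/(2*delta^2))
    with r2 = x^2 + y^2, sampled on a (2*kernel_radius+1)^2 grid. The mean is
    subtracted after discretization so the kernel sums exactly to zero and
    flat image regions produce an exactly-zero response.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    r = int(kernel_radius)
    ax = np.arange(-r, r + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx**2 + yy**2
    k = -(1.0 / (math.pi * delta**4)) * (1.0 - r2 / (2.0 * delta**2)) * np.exp(
        -r2 / (2.0 * delta**2)
    )
    return k - k.mean()


def unsharp_filter(image, config: PreprocessConfig) -> np.ndarray:
    """Convolve with the zero-sum LoG kernel (edge-replicated borders)."""
    img = _check_image(image)
    k = log_kernel(config.delta, config.kernel_radius)
    if k.shape[0] > img.shape[0] or k.shape[0] > img.shape[1]:
        raise ValueError("LoG kernel larger than image")
    if img.ndim == 2:
        return ndimage.convolve(img, k, mode="nearest")
    return np.stack(
        [ndimage.convolve(img[..., c], k, mode="nearest") for c in range(img.shape[-1])],
        axis=-1,
    )


def preprocess(image, config: PreprocessConfig | None = None) -> np.ndarray:
    """Full artifact-removal chain: close, LoG response, subtract, clip.

    The LoG response of the closed image is subtracted from the closed image
    itself, yielding a sharpened, hair-free result. With ``config.clip`` the
    output is clipped back to [0, 1].
    """
    if config is None:
        config = PreprocessConfig()
    img = _check_image(image)
    closed = morphological_close_directional(img, config.se_len)
    response = unsharp_filter(closed, config)
    out = closed - response
    if config.clip:
        out = np.clip(out, 0.0, 1.0)
    return out


def to_grayscale(image) -> np.ndarray:
    """Channel mean of an RGB image; identity for 2-D input."""
    img = _check_image(image)
    if img.ndim == 2:
        return img
    return img.mean(axis=-1)
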