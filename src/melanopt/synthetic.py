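"""Synthetic dermoscopy-like images and feature-space datasets.

Every downstream stage (preprocessing, segmentation, CNN features,
classifier) is exercised on images from this generator, so nothing in the
package needs external downloads. Each sample is a textured skin-tone
background with a darker elliptical lesion of irregular boundary, optionally
overlaid with thin dark hair/vessel strands (< 10 px wide), Gaussian blur
and additive noise. The ground-truth mask is the exact lesion support used
to paint the image, recorded before any overlay.

Class appearance follows a simple, learnable rule: melanoma lesions have a
more irregular boundary and a multi-tone fill (a darker inner core);
benign lesions are regular single-tone ellipses.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageGenConfig",
    "LabeledSample",
    "FeatureGenConfig",
    "generate_lesion_sample",
    "generate_dataset",
    "generate_feature_dataset",
    "MELANOMA",
    "NON_MELANOMA",
]

MELANOMA = "melanoma"
NON_MELANOMA = "non_melanoma"

#: per-class appearance ranges: boundary jitter (fraction of radius) and
#: number of fill tones. Melanoma = irregular, multi-tone; benign = regular,
#: single tone.
DEFAULT_CLASS_RULES = {
    MELANOMA: {"boundary_jitter": (0.15, 0.30), "n_tones": (2, 3)},
    NON_MELANOMA: {"boundary_jitter": (0.0, 0.05), "n_tones": (1, 1)},
}


@dataclass(frozen=True)
class ImageGenConfig:
    """Geometry, appearance and noise parameters of a synthetic sample.

    Defaults emulate a down-scaled dermoscopy acquisition: a 96x96 frame,
    a lesion about 40% of the frame across, a handful of 1-3 px hairs,
    mild blur and sensor noise.
    """

    height: int = 96
    width: int = 96
    lesion_axes: tuple = (20, 14)
    boundary_jitter: float = 0.1
    lesion_darkness: float = 0.35
    n_hairs: int = 6
    hair_width_range: tuple = (1, 3)
    blur_sigma: float = 0.8
    noise_sigma: float = 0.02
    class_rules: dict = field(default_factory=lambda: DEFAULT_CLASS_RULES)
    seed: int = 0

    def __post_init__(self):
        if self.height < 8 or self.width < 8:
            raise ValueError("frame must be at least 8x8")
        a, b = self.lesion_axes
        if a <= 0 or b <= 0:
            raise ValueError("lesion axes must be positive")
        # lesion (with maximal jitter) must fit inside the frame border
        margin = 1.0 + max(self.boundary_jitter, 0.35)
        if 2 * a * margin >= self.width - 2 or 2 * b * margin >= self.height - 2:
            raise ValueError("lesion larger than frame")
        if not (0 <= self.lesion_darkness <= 1):
            raise ValueError("lesion_darkness must be in [0, 1]")
        lo, hi = self.hair_width_range
        if hi >= 10:
            raise ValueError("hair widths must stay below 10 px")
        if self.n_hairs < 0 or self.blur_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("counts and sigmas must be non-negative")


@dataclass(frozen=True)
class LabeledSample:
    """One synthetic dermoscopy sample: RGB image, binary mask, class label."""

    image: np.ndarray
    mask: np.ndarray
    label: str

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("mask shape must equal image shape")


def _background(h, w, rng) -> np.ndarray:
    """Skin-tone background: base level times a low-frequency gradient."""
    yy, xx = np.mgrid[0:h, 0:w]
    yy = yy / max(h - 1, 1)
    xx = xx / max(w - 1, 1)
    phase = rng.uniform(0, 2 * np.pi, size=3)
    amp = rng.uniform(0.02, 0.06, size=3)
    grad = (
        1.0
        + amp[0] * np.cos(2 * np.pi * 0.7 * xx + phase[0])
        + amp[1] * np.cos(2 * np.pi * 0.5 * yy + phase[1])
        + amp[2] * np.cos(2 * np.pi * 0.6 * (xx + yy) + phase[2])
    )
    return 0.72 * grad


def _lesion_mask(cfg: ImageGenConfig, jitter: float, rng) -> np.ndarray:
    """Ellipse with sinusoidal radial perturbation of the boundary."""
    h, w = cfg.height, cfg.width
    a, b = cfg.lesion_axes
    cy = h / 2 + rng.uniform(-2, 2)
    cx = w / 2 + rng.uniform(-2, 2)
    yy, xx = np.mgrid[0:h, 0:w]
    dx = (xx - cx) / a
    dy = (yy - cy) / b
    r = np.sqrt(dx**2 + dy**2)
    theta = np.arctan2(dy, dx)
    bound = np.ones_like(r)
    if jitter > 0:
        n_lobes = rng.integers(3, 8, size=2)
        ph = rng.uniform(0, 2 * np.pi, size=2)
        wts = rng.uniform(0.3, 1.0, size=2)
        wts = wts / wts.sum()
        bound = 1.0 + jitter * (
            wts[0] * np.sin(n_lobes[0] * theta + ph[0])
            + wts[1] * np.sin(n_lobes[1] * theta + ph[1])
        )
    return r <= bound


def _paint_lesion(gray, mask, cfg, n_tones, rng) -> np.ndarray:
    """Darken the lesion area; extra tones are darker concentric cores."""
    out = gray.copy()
    out[mask] -= cfg.lesion_darkness
    if n_tones > 1:
        dist = ndimage.distance_transform_edt(mask)
        dmax = dist.max()
        if dmax > 0:
            for k in range(1, n_tones):
                frac = rng.uniform(0.35, 0.65) * (n_tones - k) / (n_tones - 1)
                extra = rng.uniform(0.10, 0.20)
                out[dist > frac * dmax] -= extra
    return out


def _draw_hairs(gray, cfg, rng) -> np.ndarray:
    """Overlay thin dark curved strands (random quadratic curves)."""
    out = gray.copy()
    h, w = out.shape
    lo, hi = cfg.hair_width_range
    for _ in range(cfg.n_hairs):
        width = int(rng.integers(lo, hi + 1))
        # quadratic Bezier through three random points
        p = rng.uniform([0, 0], [h - 1, w - 1], size=(3, 2))
        t = np.linspace(0, 1, 4 * max(h, w))[:, None]
        curve = (1 - t) ** 2 * p[0] + 2 * (1 - t) * t * p[1] + t**2 * p[2]
        rr = np.clip(np.round(curve[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.round(curve[:, 1]).astype(int), 0, w - 1)
        strand = np.zeros((h, w), dtype=bool)
        strand[rr, cc] = True
        if width > 1:
            # 3x3 dilation grows thickness by 2 px per iteration
            strand = ndimage.binary_dilation(
                strand, structure=ndimage.generate_binary_structure(2, 2),
                iterations=max(1, (width - 1) // 2),
            )
        dark = rng.uniform(0.08, 0.20)
        out[strand] = np.minimum(out[strand], dark + rng.uniform(0, 0.05))
    return out


def _tint(gray) -> np.ndarray:
    """Map a grayscale plane to skin-tinted RGB."""
    tint = np.array([1.00, 0.80, 0.72])
    return np.clip(gray[..., None] * tint[None, None, :], 0.0, 1.0)


def generate_lesion_sample(config: ImageGenConfig, label: str) -> LabeledSample:
    """Generate one labeled sample; deterministic given (config, seed).

    The returned mask is the exact lesion support used to paint the image,
    recorded before hair, blur or noise overlays are applied.
    """
    if label not in (MELANOMA, NON_MELANOMA):
        raise ValueError(f"unknown label {label!r}")
    rng = np.random.default_rng(config.seed)
    rules = config.class_rules.get(label)
    if rules is not None:
        jit_lo, jit_hi = rules["boundary_jitter"]
        jitter = float(rng.uniform(jit_lo, jit_hi))
        t_lo, t_hi = rules["n_tones"]
        n_tones = int(rng.integers(t_lo, t_hi + 1))
    else:
        jitter = config.boundary_jitter
        n_tones = 1

    gray = _background(config.height, config.width, rng)
    mask = _lesion_mask(config, jitter, rng)
    gray = _paint_lesion(gray, mask, config, n_tones, rng)
    if config.n_hairs > 0:
        gray = _draw_hairs(gray, config, rng)
    if config.blur_sigma > 0:
        gray = ndimage.gaussian_filter(gray, config.blur_sigma, mode="nearest")
    if config.noise_sigma > 0:
        gray = gray + rng.normal(0.0, config.noise_sigma, size=gray.shape)
    image = _tint(np.clip(gray, 0.0, 1.0))
    return LabeledSample(image=image, mask=mask, label=label)


def generate_dataset(config: ImageGenConfig, n: int, melanoma_fraction: float,
                     out_dir) -> Path:
    """Write ``n`` samples as PNGs plus a ``manifest.csv`` (filename,label).

    Per-sample seeds are derived from ``config.seed``; the melanoma count is
    ``round(n * melanoma_fraction)``. Masks are stored next to the images as
    ``<stem>_mask.png`` with values {0, 255}. Returns the manifest path.
    """
    import imageio.v3 as iio

    if not (0 <= melanoma_fraction <= 1):
        raise ValueError("melanoma_fraction must be in [0, 1]")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_mel = int(round(n * melanoma_fraction))
    labels = [MELANOMA] * n_mel + [NON_MELANOMA] * (n - n_mel)
    seeds = np.random.SeedSequence(config.seed).generate_state(max(n, 1)) % (2**31)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label"])
        for i, label in enumerate(labels):
            sample = generate_lesion_sample(replace(config, seed=int(seeds[i])), label)
            stem = f"sample_{i:04d}"
            iio.imwrite(out / f"{stem}.png",
                        (sample.image * 255).round().astype(np.uint8))
            iio.imwrite(out / f"{stem}_mask.png",
                        np.where(sample.mask, 255, 0).astype(np.uint8))
            writer.writerow([f"{stem}.png", label])
    return manifest


@dataclass(frozen=True)
class FeatureGenConfig:
    """Two Gaussian clouds in feature space, means ``separation`` apart
    along a random unit direction; emulates the 100-dimensional embedding
    produced by the CNN's last fully connected layer."""

    n_per_class: int = 100
    dim: int = 100
    separation: float = 3.0
    noise_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.dim < 1 or self.n_per_class < 1:
            raise ValueError("dim and n_per_class must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def generate_feature_dataset(config: FeatureGenConfig):
    """Return (features, labels): labels are 0 (non-melanoma) / 1 (melanoma).

    Class means sit at +-separation/2 along a random unit direction;
    isotropic Gaussian noise of scale ``noise_sigma`` is added.
    """
    rng = np.random.default_rng(config.seed)
    direction = rng.normal(size=config.dim)
    direction /= np.linalg.norm(direction)
    n = config.n_per_class
    mean0 = -0.5 * config.separation * direction
    mean1 = +0.5 * config.separation * direction
    x0 = mean0 + config.noise_sigma * rng.normal(size=(n, config.dim))
    x1 = mean1 + config.noise_sigma * rng.normal(size=(n, config.dim))
    features = np.vstack([x0, x1])
    labels = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    return features, labels
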