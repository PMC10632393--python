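"""Lesion segmentation: Kohonen (SOM) pixel clustering plus greedy
boundary refinement.

A small self-organizing map quantizes the grayscale intensities of the
preprocessed image; the cluster whose codebook value is darkest seeds a
binary lesion mask (lesions are darker than the surrounding skin). A greedy
search then iterates the mask toward a region whose inside/outside means
best explain each boundary pixel: per iteration the update

    u' = u + [(X - K(I_out))^2 - (X - K(I_in))^2] * |grad u|

is binarized at > 0, where K(I_in) / K(I_out) are the codebook coefficients
closest to the current inside / outside mean intensity. Because the update
is weighted by |grad u| only pixels at the current boundary can change
state, so the mask grows or shrinks by at most one pixel per iteration and
stops at a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, transform

__all__ = [
    "SOMConfig",
    "SOMModel",
    "DegenerateSegmentationError",
    "DegenerateRegionError",
    "kohonen_update",
    "train_som",
    "assign_labels",
    "initial_mask",
    "gsa_refine",
    "extract_roi",
    "segment_image",
    "dice",
]


class DegenerateSegmentationError(RuntimeError):
    """All pixels fell into a single cluster; no lesion/background split."""


class DegenerateRegionError(RuntimeError):
    """The working mask is empty or covers the whole image."""


@dataclass(frozen=True)
class SOMConfig:
    """Competitive-layer shape and training schedule.

    The default 2x2 grid gives four intensity clusters; training passes over
    a strided pixel subsample with a linearly decaying learning rate.
    """

    grid_rows: int = 2
    grid_cols: int = 2
    alpha0: float = 0.5
    epochs: int = 2
    sample_stride: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.grid_rows * self.grid_cols < 2:
            raise ValueError("grid must have at least 2 units")
        if not (0.0 <= self.alpha0 <= 1.0):
            raise ValueError("alpha0 must be in [0, 1]")
        if self.epochs < 1 or self.sample_stride < 1:
            raise ValueError("epochs and sample_stride must be >= 1")


@dataclass
class SOMModel:
    """Trained codebook of scalar intensity prototypes on a rectangular grid."""

    codebook: np.ndarray  # shape (grid_rows, grid_cols)
    trained: bool = False

    @property
    def units(self) -> np.ndarray:
        """Codebook flattened to unit order (row-major)."""
        return self.codebook.ravel()


def kohonen_update(w_old: float, x: float, alpha: float) -> float:
    """Winner update rule: w_new = (1 - alpha) * w_old + alpha * x."""
    return (1.0 - alpha) * w_old + alpha * x


def train_som(pixels, config: SOMConfig) -> SOMModel:
    """Train the competitive layer on a 1-D intensity sample.

    Winner-take-all: per input the unit at minimum Euclidean (here absolute)
    distance is updated toward the input, all other units are unchanged.
    The learning rate decays linearly, alpha_t = alpha0 * (1 - t/total).
    Inputs are shuffled per epoch; fully deterministic given config.seed.
    """
    x = np.asarray(pixels, dtype=float).ravel()
    n_units = config.grid_rows * config.grid_cols
    if x.size == 0:
        raise ValueError("empty pixel sample")
    if np.unique(x).size < n_units:
        raise ValueError("need at least as many distinct pixels as units")
    rng = np.random.default_rng(config.seed)
    # spread the initial codebook over the observed intensity range
    codebook = np.linspace(x.min(), x.max(), n_units)
    total = config.epochs * x.size
    t = 0
    for _ in range(config.epochs):
        order = rng.permutation(x.size)
        for i in order:
            alpha = config.alpha0 * (1.0 - t / total)
            winner = int(np.argmin(np.abs(codebook - x[i])))  # ties: lowest index
            codebook[winner] = kohonen_update(codebook[winner], x[i], alpha)
            t += 1
    return SOMModel(codebook=codebook.reshape(config.grid_rows, config.grid_cols),
                    trained=True)


def assign_labels(model: SOMModel, image) -> np.ndarray:
    """Label each pixel with its nearest codebook unit (row-major index).

    Ties break toward the lowest unit index. The label map covers every
    pixel and the per-unit pixel sets are disjoint by construction.
    """
    if not model.trained:
        raise RuntimeError("model is not trained")
    img = np.asarray(image, dtype=float)
    dist = np.abs(img[..., None] - model.units[None, None, :])
    return np.argmin(dist, axis=-1)


def darkest_unit(model: SOMModel) -> int:
    """Index of the unit with the darkest codebook value (ties: lowest)."""
    return int(np.argmin(model.units))


def initial_mask(labels, model: SOMModel, clean: bool = True) -> np.ndarray:
    """Binary lesion seed: pixels of the darkest cluster, cleaned up.

    Foreground components touching the image border are removed (the outer
    connected region is background) and holes inside the largest remaining
    component are filled. With ``clean=False`` the raw darkest-cluster mask
    is returned.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise DegenerateSegmentationError("all pixels in one cluster")
    fg = labels == darkest_unit(model)
    if not clean:
        return fg
    comps, n = measure.label(fg, return_num=True, connectivity=1)
    if n == 0:
        raise DegenerateSegmentationError("no foreground pixels")
    border = np.zeros_like(fg)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    touching = np.unique(comps[border & fg])
    keep = fg.copy()
    for c in touching:
        if c != 0:
            keep[comps == c] = False
    if not keep.any():
        raise DegenerateSegmentationError("all foreground components touch the border")
    comps2 = measure.label(keep, connectivity=1)
    sizes = np.bincount(comps2.ravel())
    sizes[0] = 0
    largest = int(np.argmax(sizes))
    filled = ndimage.binary_fill_holes(comps2 == largest)
    return keep | filled


def _central_gradients(u: np.ndarray):
    """Central differences of the mask with edge-replicated borders."""
    up = np.pad(u.astype(float), 1, mode="edge")
    gx = (up[1:-1, 2:] - up[1:-1, :-2]) / 2.0
    gy = (up[2:, 1:-1] - up[:-2, 1:-1]) / 2.0
    return gx, gy


def _nearest_coefficient(units: np.ndarray, value: float) -> float:
    """Codebook coefficient closest to ``value`` (ties: lowest index)."""
    return float(units[int(np.argmin(np.abs(units - value)))])


def gsa_refine(u, X, model: SOMModel, max_iter: int = 100) -> np.ndarray:
    """Greedy boundary refinement of the lesion mask to a fixed point.

    Each iteration recomputes the inside/outside mean of X over the current
    mask, looks up the nearest codebook coefficients K(I_in), K(I_out),
    applies the gradient-weighted quadratic update and re-binarizes at > 0.
    Stops when the mask no longer changes or after ``max_iter`` iterations.
    """
    u = np.asarray(u).astype(bool)
    X = np.asarray(X, dtype=float)
    if u.shape != X.shape:
        raise ValueError("mask and intensity grid must share a shape")
    if not u.any() or u.all():
        raise DegenerateRegionError("mask is empty or covers the whole image")
    units = model.units
    for _ in range(max_iter):
        mean_in = X[u].mean()
        mean_out = X[~u].mean()
        k_in = _nearest_coefficient(units, mean_in)
        k_out = _nearest_coefficient(units, mean_out)
        gx, gy = _central_gradients(u)
        grad_mag = np.sqrt(gx**2 + gy**2)
        u_prime = u.astype(float) + ((X - k_out) ** 2 - (X - k_in) ** 2) * grad_mag
        new_u = u_prime > 0
        if not new_u.any() or new_u.all():
            break  # refinement degenerated; keep the last valid mask
        if np.array_equal(new_u, u):
            break
        u = new_u
    return u


def extract_roi(image, mask, out_side: int = 150) -> np.ndarray:
    """Crop the mask's bounding box, pad to square (edge replication),
    resize to ``out_side`` x ``out_side`` (bilinear)."""
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise DegenerateRegionError("empty mask")
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    crop = img[r0:r1, c0:c1]
    h, w = crop.shape[:2]
    side = max(h, w)
    pad_r = side - h
    pad_c = side - w
    pad = ((pad_r // 2, pad_r - pad_r // 2), (pad_c // 2, pad_c - pad_c // 2))
    if crop.ndim == 3:
        pad = pad + ((0, 0),)
    crop = np.pad(crop, pad, mode="edge")
    out_shape = (out_side, out_side) + crop.shape[2:]
    out = transform.resize(crop, out_shape, order=1, mode="edge",
                           anti_aliasing=side > out_side, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def segment_image(preprocessed_gray, config: SOMConfig | None = None,
                  max_iter: int = 100):
    """Full segmentation of a preprocessed grayscale image.

    Trains the SOM on a strided pixel subsample, labels every pixel, seeds
    the mask from the darkest cluster and refines it greedily.

    Returns (mask, model).
    """
    if config is None:
        config = SOMConfig()
    X = np.asarray(preprocessed_gray, dtype=float)
    sample = X[:: config.sample_stride, :: config.sample_stride]
    model = train_som(sample.ravel(), config)
    labels = assign_labels(model, X)
    u0 = initial_mask(labels, model)
    mask = gsa_refine(u0, X, model, max_iter=max_iter)
    return mask, model


def dice(mask_a, mask_b) -> float:
    """Dice overlap coefficient of two binary masks."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
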