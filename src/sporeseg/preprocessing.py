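"""Image preprocessing for training and inference.

The pipeline applied to every raw frame is

1. brightness normalization, ``I_norm = (I - mu) / sigma`` with the
   per-image mean and population standard deviation;
2. global histogram equalization on a re-quantization of the
   normalized image to a fixed number of gray levels (default 256),
   using the cumulative transform ``T(r) = sum_{k<=r} n_k / N``;
3. tiling into fixed-size patches (default 256x256), keeping only
   patches whose ground-truth mask is more than 5% foreground;
4. geometric augmentation (rotation, scaling, flips) applied
   identically to image and mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_annotation import BinaryMask, GrayImage

__all__ = [
    "HistogramModel",
    "Patch",
    "normalize_image",
    "quantize",
    "equalize_histogram",
    "extract_patches",
    "flip_patch",
    "rotate90_patch",
    "scale_patch",
    "augment",
]

logger = logging.getLogger(__name__)

DEFAULT_PATCH_SIZE = 256
DEFAULT_MIN_OCCUPANCY = 0.05


def normalize_image(image: GrayImage) -> GrayImage:
    """Zero-mean, unit-variance brightness normalization.

    Uses the population standard deviation over all pixels.  A constant
    image (sigma = 0) is returned as all zeros with a logged warning so
    batch processing never aborts.
    """
    pix = image.pixels.astype(np.float64)
    mu = pix.mean()
    sigma = pix.std()
    if sigma == 0:
        logger.warning("constant image: normalization returns zeros")
        return GrayImage(np.zeros_like(pix), px_per_um=image.px_per_um)
    return GrayImage((pix - mu) / sigma, px_per_um=image.px_per_um)


@dataclass
class HistogramModel:
    """Discrete gray-level histogram and its cumulative transform.

    ``T[r] = sum_{k<=r} p[k]`` with ``p[k] = n_k / N``; T is
    non-decreasing and reaches 1 at the top level.
    """

    n_k: np.ndarray
    N: int
    p_rk: np.ndarray
    T: np.ndarray

    @classmethod
    def from_levels(cls, quantized: np.ndarray, levels: int) -> "HistogramModel":
        n_k = np.bincount(quantized.ravel(), minlength=levels).astype(np.int64)
        N = int(n_k.sum())
        p = n_k / N
        return cls(n_k=n_k, N=N, p_rk=p, T=np.cumsum(p))


def quantize(image: GrayImage, levels: int = 256) -> np.ndarray:
    """Min-max re-quantization of a (typically normalized, real-valued)
    image to integer gray levels 0..levels-1."""
    pix = image.pixels.astype(np.float64)
    lo, hi = pix.min(), pix.max()
    if hi == lo:
        return np.zeros(pix.shape, dtype=np.intp)
    scaled = (pix - lo) / (hi - lo) * (levels - 1)
    return np.rint(scaled).astype(np.intp)


def equalize_histogram(image: GrayImage, levels: int = 256) -> GrayImage:
    """Global histogram equalization.

    The image is re-quantized to ``levels`` integer gray levels, the
    cumulative transform T is built from the level histogram, and each
    pixel with level r is mapped to ``round((levels - 1) * T(r))``.
    The mapping is monotone non-decreasing, so pixel rank order is
    preserved.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    q = quantize(image, levels)
    model = HistogramModel.from_levels(q, levels)
    lut = np.rint((levels - 1) * model.T).astype(np.intp)
    return GrayImage(lut[q], px_per_um=image.px_per_um)


@dataclass
class Patch:
    """An aligned (image, mask) tile cut from a source frame."""

    image: GrayImage
    mask: BinaryMask
    origin: tuple[int, int] = (0, 0)  # (row, col) in the source frame

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )


def extract_patches(
    image: GrayImage,
    mask: BinaryMask,
    size: int = DEFAULT_PATCH_SIZE,
    min_occupancy: float = DEFAULT_MIN_OCCUPANCY,
) -> list[Patch]:
    """Cut a frame into a non-overlapping grid of size x size patches.

    The grid starts at the top-left corner; right/bottom remainders are
    discarded.  A patch is kept iff the foreground fraction of its mask
    strictly exceeds ``min_occupancy`` (default 5%).
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    h, w = image.shape
    if size > h or size > w:
        raise ValueError(f"patch size {size} exceeds image dimensions {(h, w)}")
    if not 0 <= min_occupancy < 1:
        raise ValueError("min_occupancy must be in [0, 1)")
    kept = []
    for r in range(0, h - size + 1, size):
        for c in range(0, w - size + 1, size):
            sub_mask = mask.pixels[r : r + size, c : c + size]
            if sub_mask.mean() > min_occupancy:
                kept.append(
                    Patch(
                        image=GrayImage(
                            image.pixels[r : r + size, c : c + size],
                            px_per_um=image.px_per_um,
                        ),
                        mask=BinaryMask(sub_mask),
                        origin=(r, c),
                    )
                )
    return kept


def preprocess_frame(image: GrayImage, levels: int = 256, equalize: bool = True) -> GrayImage:
    """Full inference-time preprocessing of a raw frame.

    Applies brightness normalization then (optionally) histogram
    equalization, and rescales the result to [-1, 1] for the network.
    """
    out = normalize_image(image)
    if equalize:
        out = equalize_histogram(out, levels=levels)
        scaled = out.pixels.astype(np.float64) / (levels - 1) * 2.0 - 1.0
        return GrayImage(scaled, px_per_um=image.px_per_um)
    return out


# -- geometric augmentation -------------------------------------------

def flip_patch(patch: Patch, axis: int) -> Patch:
    """Mirror a patch along axis 0 (vertical flip) or 1 (horizontal)."""
    return Patch(
        image=GrayImage(np.flip(patch.image.pixels, axis=axis).copy(),
                        px_per_um=patch.image.px_per_um),
        mask=BinaryMask(np.flip(patch.mask.pixels, axis=axis).copy()),
        origin=patch.origin,
    )


def rotate90_patch(patch: Patch, k: int) -> Patch:
    """Rotate a patch by k * 90 degrees counter-clockwise."""
    return Patch(
        image=GrayImage(np.rot90(patch.image.pixels, k).copy(),
                        px_per_um=patch.image.px_per_um),
        mask=BinaryMask(np.rot90(patch.mask.pixels, k).copy()),
        origin=patch.origin,
    )


def scale_patch(patch: Patch, factor: float) -> Patch:
    """Rescale a patch and crop/pad back to its original size.

    The image is resampled bilinearly, the mask with nearest-neighbour
    so it stays binary.  Upscaled patches are centre-cropped; downscaled
    patches are centre-padded (reflect for the image, background for the
    mask).
    """
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    size = patch.image.shape
    img = ndimage.zoom(patch.image.pixels.astype(np.float64), factor, order=1)
    msk = ndimage.zoom(patch.mask.pixels.astype(np.uint8), factor, order=0)

    def fit(arr, pad_mode):
        out_h, out_w = size
        h, w = arr.shape
        if h >= out_h:
            top = (h - out_h) // 2
            arr = arr[top : top + out_h]
        else:
            pad = out_h - h
            arr = np.pad(arr, ((pad // 2, pad - pad // 2), (0, 0)), mode=pad_mode)
        if arr.shape[1] >= out_w:
            left = (arr.shape[1] - out_w) // 2
            arr = arr[:, left : left + out_w]
        else:
            pad = out_w - arr.shape[1]
            arr = np.pad(arr, ((0, 0), (pad // 2, pad - pad // 2)), mode=pad_mode)
        return arr

    return Patch(
        image=GrayImage(fit(img, "reflect"), px_per_um=patch.image.px_per_um),
        mask=BinaryMask(fit(msk, "constant") > 0),
        origin=patch.origin,
    )


def augment(
    patch: Patch,
    ops: set[str] = frozenset({"rotate", "scale", "flip"}),
    seed: int = 0,
    scale_range: tuple[float, float] = (0.8, 1.2),
) -> list[Patch]:
    """Generate augmented variants of a patch (original included first).

    ``ops`` may contain ``rotate`` (one random multiple of 90 degrees),
    ``scale`` (one random factor in ``scale_range``) and ``flip``
    (horizontal and vertical mirrors).  The same geometric transform is
    applied to image and mask; results are deterministic given ``seed``.
    """
    unknown = set(ops) - {"rotate", "scale", "flip"}
    if unknown:
        raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out = [patch]
    if "rotate" in ops:
        out.append(rotate90_patch(patch, int(rng.integers(1, 4))))
    if "scale" in ops:
        out.append(scale_patch(patch, float(rng.uniform(*scale_range))))
    if "flip" in ops:
        out.append(flip_patch(patch, 1))
        out.append(flip_patch(patch, 0))
    return out
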