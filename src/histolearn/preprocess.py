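"""Image preprocessing and augmentation.

Pipeline order, matching how the training stages consume images: decode →
resize → crop → per-image standardization → (training only) geometric
augmentation and mixup. Per-image standardization uses each image's own
per-channel mean and standard deviation, so brightness and stain-intensity
offsets between slides are removed before the network sees them.

Mixup is applied only to labeled training batches — never to evaluation or
pseudo-labeling inputs, whose confidence scores must come from unmixed
images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.transform import resize as _sk_resize

logger = logging.getLogger("histolearn")

__all__ = [
    "EPS_STD",
    "ImageTensor",
    "AugmentConfig",
    "load_image",
    "normalize_image",
    "resize_and_crop",
    "standard_augment",
    "mixup_batch",
]

#: Guard added to the standard deviation so constant channels map to zero.
EPS_STD = 1e-7


@dataclass
class ImageTensor:
    """An H×W×3 float image with provenance and a normalization flag."""

    pixels: np.ndarray
    provenance: str = ""
    normalized: bool = False

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected H×W×3 pixels, got {self.pixels.shape}")


@dataclass
class AugmentConfig:
    """Geometric-augmentation and mixup settings.

    Magnitudes default to mild values typical for histology: fractional
    shifts up to 10% of the image side, rotations up to ±15 degrees, both
    flips enabled, mixup Beta(0.2, 0.2).
    """

    shift_fraction: float = 0.1
    rotation_degrees: float = 15.0
    hflip: bool = True
    vflip: bool = True
    mixup_alpha: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.shift_fraction <= 0.5:
            raise ValueError("shift_fraction must be in [0, 0.5]")
        if not 0 <= self.rotation_degrees <= 180:
            raise ValueError("rotation_degrees must be in [0, 180]")
        if self.mixup_alpha <= 0:
            raise ValueError("mixup_alpha must be positive")


def load_image(path: str, provenance: str = "") -> ImageTensor:
    """Decode a PNG/JPEG/TIFF file to a float image on [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0
    return ImageTensor(pixels=arr, provenance=provenance or str(path))


def normalize_image(img: ImageTensor) -> ImageTensor:
    """Standardize each channel by the image's own mean and std.

    (x − mean) / (std + ε) per channel; a constant channel maps to zeros.
    """
    x = img.pixels
    if not np.all(np.isfinite(x)):
        raise ValueError("image contains non-finite pixels")
    # float64 statistics: order-insensitive and exact for constant channels
    x64 = x.astype(np.float64)
    mean = x64.mean(axis=(0, 1), keepdims=True)
    std = x64.std(axis=(0, 1), keepdims=True)
    out = ((x64 - mean) / (std + EPS_STD)).astype(np.float32)
    return ImageTensor(pixels=out, provenance=img.provenance, normalized=True)


def resize_and_crop(img: ImageTensor,
                    resize_to: tuple[int, int] = (350, 240),
                    crop_to: tuple[int, int] = (224, 224),
                    mode: str = "center",
                    seed: int = 0) -> ImageTensor:
    """Resize to ``resize_to`` (width, height) then crop to ``crop_to``.

    ``mode="center"`` is deterministic and seed-independent;
    ``mode="random"`` places the crop uniformly, deterministically for a
    given seed. Training uses random crops; evaluation and pseudo-labeling
    use the center crop.
    """
    rw, rh = resize_to
    ch, cw = crop_to
    if ch > rh or cw > rw:
        raise ValueError(f"crop {crop_to} does not fit inside resized "
                         f"image {resize_to} (width, height)")
    x = img.pixels
    if x.shape[0] != rh or x.shape[1] != rw:
        x = _sk_resize(x, (rh, rw), order=1, mode="reflect",
                       anti_aliasing=True, preserve_range=True
                       ).astype(np.float32)
    if mode == "center":
        top, left = (rh - ch) // 2, (rw - cw) // 2
    elif mode == "random":
        rng = np.random.default_rng(seed)
        top = int(rng.integers(0, rh - ch + 1))
        left = int(rng.integers(0, rw - cw + 1))
    else:
        raise ValueError(f"unknown crop mode {mode!r}")
    return ImageTensor(pixels=x[top:top + ch, left:left + cw],
                       provenance=img.provenance, normalized=img.normalized)


def standard_augment(img: ImageTensor, cfg: AugmentConfig,
                     rng: np.random.Generator | None = None) -> ImageTensor:
    """Seeded random shift, horizontal/vertical flip, and rotation.

    With all magnitudes zero and both flips disabled this is the identity.
    Flips fire with probability 0.5 each when enabled; shift offsets and the
    rotation angle are drawn uniformly within their configured bounds.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    x = img.pixels
    h, w = x.shape[:2]
    if cfg.shift_fraction > 0:
        dy = float(rng.uniform(-cfg.shift_fraction, cfg.shift_fraction)) * h
        dx = float(rng.uniform(-cfg.shift_fraction, cfg.shift_fraction)) * w
        x = ndimage.shift(x, (dy, dx, 0), order=1, mode="reflect")
    if cfg.hflip and rng.random() < 0.5:
        x = x[:, ::-1]
    if cfg.vflip and rng.random() < 0.5:
        x = x[::-1]
    if cfg.rotation_degrees > 0:
        angle = float(rng.uniform(-cfg.rotation_degrees, cfg.rotation_degrees))
        x = ndimage.rotate(x, angle, axes=(1, 0), reshape=False,
                           order=1, mode="reflect")
    return ImageTensor(pixels=np.ascontiguousarray(x, dtype=np.float32),
                       provenance=img.provenance, normalized=img.normalized)


def mixup_batch(images: np.ndarray, labels: np.ndarray, alpha: float = 0.2,
                seed: int = 0, lam: np.ndarray | None = None,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Convex pairwise mixing of a batch with Beta(alpha, alpha) weights.

    Each output i is λ_i·x_i + (1−λ_i)·x_π(i) for a random permutation π,
    with the same λ_i applied to the one-hot labels, which therefore stay in
    the probability simplex. ``lam`` overrides the sampled weights (used for
    deterministic checks). A batch of size 1 is returned unchanged with a
    warning.
    """
    images = np.asarray(images)
    labels = np.asarray(labels, dtype=np.float32)
    n = images.shape[0]
    if n != labels.shape[0]:
        raise ValueError("images and labels disagree on batch size")
    if n < 2:
        logger.warning("mixup on a batch of size %d is a no-op", n)
        return images, labels
    rng = np.random.default_rng(seed)
    if lam is None:
        lam = rng.beta(alpha, alpha, size=n).astype(np.float32)
    else:
        lam = np.broadcast_to(np.asarray(lam, dtype=np.float32), (n,)).copy()
    perm = rng.permutation(n)
    lam_x = lam.reshape((n,) + (1,) * (images.ndim - 1))
    mixed = lam_x * images + (1 - lam_x) * images[perm]
    mixed_labels = lam[:, None] * labels + (1 - lam[:, None]) * labels[perm]
    return mixed.astype(images.dtype, copy=False), mixed_labels
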