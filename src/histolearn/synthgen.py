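"""Synthetic two-class "histology-like" image generation.

Emulates the structure of a magnification-stratified benign/malignant
histology collection so the full pipeline is exercisable without any real
data: each image is a field of Poisson-count elliptical "nuclei" in a
hematoxylin/eosin-like palette over a pink stroma background. The two
classes differ in nucleus density, nucleus size and within-nucleus
chromatin texture, all scaled by a single separation parameter δ: at δ = 0
the class-conditional image distributions are identical (any classifier is
at chance), and growing δ makes the task monotonically easier. The
magnification tier multiplies nucleus radii, mimicking optical zoom.

This generator makes no attempt at visual realism, stain physics, or
subtype structure — separability controlled by one scalar is the point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .datamodel import CLASSES, MAGNIFICATIONS, ImageRecord, Manifest
from .preprocess import ImageTensor

__all__ = ["SyntheticSpec", "generate_image", "write_dataset", "make_arrays"]

# H&E-like palette (RGB on [0, 1])
_BACKGROUND = np.array([0.91, 0.76, 0.84], dtype=np.float32)   # eosin stroma
_NUCLEUS = np.array([0.33, 0.21, 0.52], dtype=np.float32)      # hematoxylin


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; class separability is the single dial δ.

    The benign class uses ``nucleus_density`` and ``nucleus_radius`` as-is;
    the malignant class multiplies density by (1 + δ), radius by
    (1 + 0.25·δ), and adds chromatin texture of amplitude 0.06·δ. δ = 2
    therefore gives the malignant class three times the benign nucleus
    density.
    """

    n_per_cell: int = 12
    image_size: tuple[int, int] = (64, 64)
    nucleus_density: float = 14.0       # mean nuclei per benign image
    nucleus_radius: float = 3.0         # mean nucleus radius, pixels
    separation: float = 1.5             # effect size δ >= 0
    noise_sd: float = 0.04              # additive Gaussian pixel noise
    magnification_scale: dict[int, float] = field(
        default_factory=lambda: {40: 0.6, 100: 0.85, 200: 1.2, 400: 1.7})
    seed: int = 0

    def __post_init__(self):
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if min(self.image_size) < 16:
            raise ValueError("image_size must be at least 16x16")

    def class_params(self, class_label: str) -> tuple[float, float, float]:
        """(mean density, mean radius, chromatin amplitude) for a class."""
        if class_label == "malignant":
            return (self.nucleus_density * (1 + self.separation),
                    self.nucleus_radius * (1 + 0.25 * self.separation),
                    0.06 * self.separation)
        return self.nucleus_density, self.nucleus_radius, 0.0


def _paint_nucleus(img: np.ndarray, rng: np.random.Generator,
                   radius: float, chromatin: float) -> None:
    h, w = img.shape[:2]
    cy, cx = rng.uniform(0, h), rng.uniform(0, w)
    rx = radius * rng.uniform(0.7, 1.0)
    ry = radius * rng.uniform(1.0, 1.5)
    theta = rng.uniform(0, np.pi)
    color = _NUCLEUS + rng.normal(0, 0.03, 3).astype(np.float32)

    half = int(np.ceil(max(rx, ry))) + 1
    y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
    x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    u = (dx * np.cos(theta) + dy * np.sin(theta)) / rx
    v = (-dx * np.sin(theta) + dy * np.cos(theta)) / ry
    d2 = u * u + v * v
    alpha = np.clip(1.5 * (1.0 - d2), 0.0, 1.0).astype(np.float32)  # soft edge
    patch = img[y0:y1, x0:x1]
    tint = color[None, None, :]
    if chromatin > 0:
        tint = tint + rng.normal(0, chromatin,
                                 patch.shape).astype(np.float32)
    patch[:] = (1 - alpha[..., None]) * patch + alpha[..., None] * tint


def generate_image(spec: SyntheticSpec, class_label: str, magnification: int,
                   index: int) -> ImageTensor:
    """One synthetic image, deterministic in (seed, class, tier, index)."""
    if class_label not in CLASSES:
        raise ValueError(f"unknown class {class_label!r}")
    if magnification not in MAGNIFICATIONS:
        raise ValueError(f"unknown magnification {magnification}")
    rng = np.random.default_rng(
        [spec.seed, CLASSES.index(class_label), magnification, index])
    h, w = spec.image_size
    img = np.empty((h, w, 3), dtype=np.float32)
    img[:] = _BACKGROUND + rng.normal(0, 0.02, 3).astype(np.float32)

    density, radius, chromatin = spec.class_params(class_label)
    radius = radius * spec.magnification_scale.get(magnification, 1.0)
    # scale density with image area relative to the 64x64 reference field
    n_nuclei = rng.poisson(density * (h * w) / (64 * 64))
    for _ in range(n_nuclei):
        r = radius * rng.lognormal(0.0, 0.25)
        _paint_nucleus(img, rng, r, chromatin)

    img += rng.normal(0, spec.noise_sd, img.shape).astype(np.float32)
    np.clip(img, 0.0, 1.0, out=img)
    return ImageTensor(pixels=img,
                       provenance=f"synthetic:{class_label}:{magnification}X:{index}")


def write_dataset(spec: SyntheticSpec, root: str | Path) -> Manifest:
    """Write the full grid of images as PNGs in the scanning layout.

    Layout: ``root/<magnification>X/<class>/img_<class>_<mag>x_<index>.png``.
    The returned manifest carries exactly the metadata a directory scan of
    the written tree recovers.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    records: list[ImageRecord] = []
    for mag in MAGNIFICATIONS:
        for cls in CLASSES:
            outdir = root / f"{mag}X" / cls
            outdir.mkdir(parents=True, exist_ok=True)
            for idx in range(spec.n_per_cell):
                img = generate_image(spec, cls, mag, idx)
                arr = (img.pixels * 255.0 + 0.5).astype(np.uint8)
                fname = f"img_{cls}_{mag}x_{idx:03d}.png"
                fpath = outdir / fname
                Image.fromarray(arr).save(fpath)
                records.append(ImageRecord(
                    id=str(Path(f"{mag}X") / cls / fname), path=str(fpath),
                    magnification=mag, class_label=cls))
    records.sort(key=lambda r: r.path)
    return Manifest(records=records, source_root=str(root), seed=spec.seed)


def make_arrays(spec: SyntheticSpec, n_per_class: int, magnification: int = 200,
                ) -> tuple[np.ndarray, np.ndarray]:
    """In-memory dataset for one tier: (images N×H×W×3, integer labels).

    Bypasses disk entirely; label 0 is benign, 1 malignant, interleaved.
    """
    images, labels = [], []
    for idx in range(n_per_class):
        for ci, cls in enumerate(CLASSES):
            images.append(generate_image(spec, cls, magnification, idx).pixels)
            labels.append(ci)
    return np.stack(images), np.asarray(labels, dtype=np.int64)
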