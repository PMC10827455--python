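"""Shared fixtures and helpers for the test suite.

All image data is generated programmatically by the synthetic-histology
module; nothing is read from outside the repository.
"""

from __future__ import annotations

import numpy as np
import pytest

import histolearn as H


def make_normalized_arrays(separation: float, seed: int, n_per_class: int,
                           magnification: int = 200,
                           image_size: tuple[int, int] = (64, 64),
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic images, per-image standardized, with integer labels."""
    spec = H.SyntheticSpec(separation=separation, seed=seed,
                           image_size=image_size)
    X, y = H.make_arrays(spec, n_per_class=n_per_class,
                         magnification=magnification)
    Xn = np.stack([H.normalize_image(H.ImageTensor(x)).pixels for x in X])
    return Xn, y


def make_synthetic_records(n_per_stratum: int) -> H.Manifest:
    """A manifest of fabricated records (no files on disk) for split tests."""
    records = []
    for mag in H.MAGNIFICATIONS:
        for cls in H.CLASSES:
            for i in range(n_per_stratum):
                rid = f"{mag}X/{cls}/img_{i:03d}.png"
                records.append(H.ImageRecord(
                    id=rid, path=f"/nonexistent/{rid}",
                    magnification=mag, class_label=cls))
    return H.Manifest(records=records)


@pytest.fixture(scope="session")
def small_spec() -> H.ArchitectureSpec:
    return H.ArchitectureSpec.small()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
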