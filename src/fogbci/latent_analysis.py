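"""Interpretability analyses of the latent image space.

Three views of what the encoder-plus-forest pipeline has learned:

* per-class pixel-wise average latent images;
* their "log-positive" transforms — natural log of the strictly positive
  pixels, with non-positive pixels masked out (not zero-filled, so a masked
  pixel is never confused with ln 1 = 0);
* the forest's per-pixel Mean Decrease in Impurity (Gini importance) map,
  un-flattened with the same row-major convention the classifier uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .autoencoder import LATENT_SHAPE, N_LATENT_FEATURES
from .classification import unflatten_latent
from .errors import ShapeError, ValidationError
from .records import CLASS_NAMES


@dataclass
class ClassImageSet:
    """One 16 x 21 image per class, in class-code order."""

    images: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.images) != set(CLASS_NAMES):
            raise ValidationError(
                f"expected images for classes {CLASS_NAMES}, got {sorted(self.images)}"
            )
        for cls, img in self.images.items():
            if img.shape != LATENT_SHAPE:
                raise ShapeError(f"image for {cls} must be {LATENT_SHAPE}")

    def __getitem__(self, cls: str) -> np.ndarray:
        return self.images[cls]

    def log_images(self) -> dict[str, np.ma.MaskedArray]:
        """Log-positive transform of each class image."""
        return {cls: log_positive_image(img) for cls, img in self.images.items()}


@dataclass
class ImportanceMap:
    """Non-negative 16 x 21 per-pixel importance; sums to 1 when normalized."""

    values: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != LATENT_SHAPE:
            raise ShapeError(f"importance map must be {LATENT_SHAPE}")
        if np.any(self.values < 0):
            raise ValidationError("importances must be non-negative")
        if self.normalized and abs(self.values.sum() - 1.0) > 1e-9:
            raise ValidationError("normalized importance map must sum to 1")

    def top_pixel(self) -> tuple[int, int]:
        """(row, column) of the most important pixel."""
        row, col = np.unravel_index(np.argmax(self.values), LATENT_SHAPE)
        return int(row), int(col)


def class_average_images(
    images: np.ndarray | Sequence[np.ndarray], labels: Sequence[int] | np.ndarray
) -> ClassImageSet:
    """Pixel-wise mean latent image per class.

    ``labels`` are integer class codes aligned with ``images``; every class
    must contribute at least one image.
    """
    images = np.asarray(images, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if images.ndim != 3 or images.shape[1:] != LATENT_SHAPE:
        raise ShapeError(f"images must be (n, {LATENT_SHAPE[0]}, {LATENT_SHAPE[1]})")
    if len(labels) != len(images):
        raise ValidationError("labels not aligned with images")
    out = {}
    for code, cls in enumerate(CLASS_NAMES):
        mask = labels == code
        if not np.any(mask):
            raise ValidationError(f"class {cls} has no images to average")
        out[cls] = images[mask].mean(axis=0)
    return ClassImageSet(images=out)


def log_positive_image(image: np.ndarray) -> np.ma.MaskedArray:
    """Natural log of strictly positive pixels; others masked.

    An all-non-positive image yields a fully masked array rather than an
    error.
    """
    image = np.asarray(image, dtype=np.float64)
    positive = image > 0
    out = np.ma.masked_array(
        np.where(positive, np.log(np.where(positive, image, 1.0)), 0.0),
        mask=~positive,
    )
    return out


def importance_map(model, normalize: bool = True) -> ImportanceMap:
    """Per-pixel Mean Decrease in Impurity from a fitted forest.

    MDI averages, over the trees, the impurity decrease attributed to splits
    on each feature, weighted by the fraction of samples reaching the node;
    the 336 per-feature values are un-flattened to 16 x 21 with the
    classifier's row-major convention.
    """
    importances = getattr(model, "feature_importances_", None)
    if importances is None:
        raise ValidationError("model exposes no impurity-based feature importances")
    importances = np.asarray(importances, dtype=np.float64)
    if importances.shape != (N_LATENT_FEATURES,):
        raise ShapeError(
            f"model must be trained on {N_LATENT_FEATURES} features, "
            f"got {importances.shape[0]}"
        )
    values = unflatten_latent(importances)
    if normalize:
        total = values.sum()
        if total > 0:
            values = values / total
    return ImportanceMap(values=values, normalized=normalize and values.sum() > 0)


def save_matrix(path, matrix: np.ndarray) -> None:
    """Write a matrix (masked entries as 'nan') as comma-delimited text."""
    data = np.ma.filled(np.ma.asarray(matrix, dtype=float), np.nan)
    np.savetxt(path, data, delimiter=",", fmt="%.10g")


def save_heatmap(path, matrix: np.ndarray, title: str = "") -> None:
    """Render a matrix as a heat-map image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(matrix, aspect="auto", cmap="viridis")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
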