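"""Co-located patch-pair extraction and patch vectorization.

Training signals for operator learning are square patches sampled at the
same pixel centres in two aligned images of different modalities. Patches
are vectorized row-major; the default normalization removes each patch's
own mean so that operators respond to structure rather than brightness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imaging import DimensionError, ImageGrid, ValidationError

logger = logging.getLogger("cosreg")


class Normalization(str, Enum):
    NONE = "NONE"
    ZERO_MEAN = "ZERO_MEAN"


@dataclass
class PatchEnsemblePair:
    """Column-aligned vectorized patch matrices from two modalities.

    ``X_a`` and ``X_b`` are ``(n, N)`` with ``n = patch_size**2``; column
    ``i`` of both matrices was extracted at ``centers[i]``.
    """

    X_a: np.ndarray
    X_b: np.ndarray
    patch_size: int
    centers: np.ndarray
    normalization: Normalization = Normalization.ZERO_MEAN

    def __post_init__(self) -> None:
        self.X_a = np.asarray(self.X_a, float)
        self.X_b = np.asarray(self.X_b, float)
        if self.X_a.shape != self.X_b.shape:
            raise DimensionError("X_a and X_b must have identical shapes")
        if self.X_a.shape[0] != self.patch_size**2:
            raise DimensionError(
                f"rows {self.X_a.shape[0]} != patch_size**2 = {self.patch_size ** 2}"
            )
        self.centers = np.asarray(self.centers)
        self.normalization = Normalization(self.normalization)

    @property
    def n(self) -> int:
        return self.X_a.shape[0]

    @property
    def count(self) -> int:
        return self.X_a.shape[1]

    def save(self, path) -> None:
        """Binary array container + JSON sidecar."""
        path = Path(path)
        np.savez_compressed(
            path, X_a=self.X_a, X_b=self.X_b, centers=self.centers
        )
        meta = {
            "patch_size": self.patch_size,
            "normalization": self.normalization.value,
            "sha256_X_a": hashlib.sha256(np.ascontiguousarray(self.X_a)).hexdigest(),
            "sha256_X_b": hashlib.sha256(np.ascontiguousarray(self.X_b)).hexdigest(),
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "PatchEnsemblePair":
        data = np.load(str(path))
        meta = json.loads(Path(str(path) + ".json").read_text())
        return cls(
            data["X_a"], data["X_b"], int(meta["patch_size"]), data["centers"],
            Normalization(meta["normalization"]),
        )


def _window_matrix(pixels: np.ndarray, centers: np.ndarray, patch_size: int) -> np.ndarray:
    """(n, N) matrix of row-major vectorized windows at integer centres."""
    half = patch_size // 2
    view = np.lib.stride_tricks.sliding_window_view(pixels, (patch_size, patch_size))
    wins = view[centers[:, 0] - half, centers[:, 1] - half]  # (N, p, p)
    return wins.reshape(len(centers), patch_size**2).T.astype(float)


def extract_patch_pairs(
    img_a: ImageGrid,
    img_b: ImageGrid,
    patch_size: int = 7,
    count: int = 20000,
    seed: int = 0,
    normalization: Normalization = Normalization.ZERO_MEAN,
) -> PatchEnsemblePair:
    """Sample ``count`` co-located patch pairs uniformly at random.

    Sampling is without replacement when the image holds enough valid
    centres, with replacement (and a warning) otherwise.
    """
    normalization = Normalization(normalization)
    if img_a.shape != img_b.shape:
        raise DimensionError(f"image shapes differ: {img_a.shape} vs {img_b.shape}")
    if patch_size % 2 == 0:
        raise ValidationError("patch_size must be odd (centre pixel must exist)")
    if count < 1:
        raise ValidationError("count must be >= 1")
    h, w = img_a.shape
    half = patch_size // 2
    ny, nx = h - 2 * half, w - 2 * half
    if ny <= 0 or nx <= 0:
        raise ValidationError("image smaller than patch")
    n_valid = ny * nx
    rng = np.random.default_rng(seed)
    if count <= n_valid:
        flat = rng.choice(n_valid, size=count, replace=False)
    else:
        warnings.warn(
            f"requested {count} patches but only {n_valid} valid centres; "
            "sampling with replacement",
            stacklevel=2,
        )
        flat = rng.integers(0, n_valid, size=count)
    centers = np.stack([flat // nx + half, flat % nx + half], axis=1)

    X_a = _window_matrix(img_a.pixels, centers, patch_size)
    X_b = _window_matrix(img_b.pixels, centers, patch_size)
    if normalization is Normalization.ZERO_MEAN:
        X_a = X_a - X_a.mean(axis=0, keepdims=True)
        X_b = X_b - X_b.mean(axis=0, keepdims=True)
    return PatchEnsemblePair(X_a, X_b, patch_size, centers, normalization)


def vectorize_patch(image: ImageGrid, center, patch_size: int) -> np.ndarray:
    """Row-major vectorized ``patch_size`` window around an integer centre."""
    cy, cx = int(round(center[0])), int(round(center[1]))
    if (cy, cx) != (int(center[0]), int(center[1])) or not np.allclose(
        center, (cy, cx)
    ):
        return patch_at(image, center, patch_size)
    half = patch_size // 2
    h, w = image.shape
    if not (half <= cy <= h - 1 - half and half <= cx <= w - 1 - half):
        raise ValidationError(f"centre {center} window exits image of shape {image.shape}")
    win = image.pixels[cy - half : cy + half + 1, cx - half : cx + half + 1]
    return win.reshape(-1).astype(float)


def patches_at(pixels: np.ndarray, centers: np.ndarray, patch_size: int) -> np.ndarray:
    """Bilinear off-grid patches at float centres; returns (n, M).

    Window pixels outside the domain are edge-clamped; centres themselves
    must lie inside the image.
    """
    pixels = np.asarray(pixels, float)
    centers = np.atleast_2d(np.asarray(centers, float))
    h, w = pixels.shape
    if np.any(centers[:, 0] < 0) or np.any(centers[:, 0] > h - 1) or np.any(
        centers[:, 1] < 0
    ) or np.any(centers[:, 1] > w - 1):
        raise ValidationError("patch centre outside image domain")
    half = patch_size // 2
    off = np.arange(-half, half + 1, dtype=float)
    oy, ox = np.meshgrid(off, off, indexing="ij")
    yy = centers[:, 0][:, None] + oy.reshape(-1)[None, :]  # (M, n)
    xx = centers[:, 1][:, None] + ox.reshape(-1)[None, :]
    vals = ndimage.map_coordinates(
        pixels, np.stack([yy.ravel(), xx.ravel()]), order=1, mode="nearest"
    )
    return vals.reshape(centers.shape[0], patch_size**2).T


def patch_at(image: ImageGrid, center, patch_size: int) -> np.ndarray:
    """Single off-grid patch (row-major n-vector) sampled bilinearly."""
    return patches_at(image.pixels, np.asarray([center], float), patch_size)[:, 0]
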