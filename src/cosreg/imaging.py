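"""Core 2D image, transform and landmark data model.

Conventions used throughout the package:

* pixel indices are 0-based, ordered ``(row=y, col=x)``, with pixel centres
  at integer coordinates;
* physical positions are millimetres, ``mm = index * spacing + origin``;
* warping is backward: ``warp(image, T)(x) = image(x + d(x))`` where the
  displacement ``d`` is stored in pixels on the grid of the warped image.

Displacement fields are arrays of shape ``(2, H, W)`` whose channels are the
per-pixel ``(dy, dx)`` shifts in pixels.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field as _field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger("cosreg")


class Modality(str, Enum):
    MR = "MR"
    PA = "PA"
    US = "US"
    OTHER = "OTHER"


class Interpolation(str, Enum):
    BILINEAR = "BILINEAR"
    NEAREST = "NEAREST"


class Boundary(str, Enum):
    CONSTANT_ZERO = "CONSTANT_ZERO"
    EDGE_CLAMP = "EDGE_CLAMP"


class TransformKind(str, Enum):
    IDENTITY = "IDENTITY"
    BSPLINE_FFD = "BSPLINE_FFD"
    DENSE = "DENSE"


class DimensionError(ValueError):
    """Shapes or dimensionality do not match the 2D pipeline contract."""


class ValidationError(ValueError):
    """Values violate a data-model invariant (non-finite, non-positive...)."""


class FormatError(ValueError):
    """A file could not be interpreted under the declared format."""


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------


@dataclass
class ImageGrid:
    """A 2D scalar image with physical pixel spacing.

    Parameters
    ----------
    pixels : ndarray, shape (H, W)
        Scalar intensities in arbitrary units.
    spacing : (dy, dx)
        Pixel spacing in mm/pixel, strictly positive.
    modality : Modality
        Which imaging modality produced the image.
    origin : (y0, x0)
        Physical position (mm) of pixel (0, 0).
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    modality: Modality = Modality.OTHER
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise DimensionError(
                f"ImageGrid requires a 2D array, got shape {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("ImageGrid pixels must be finite")
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        self.modality = Modality(self.modality)
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def px_to_mm(self, points_px: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_px, dtype=float))
        return pts * np.asarray(self.spacing) + np.asarray(self.origin)

    def mm_to_px(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def with_pixels(self, pixels: np.ndarray) -> "ImageGrid":
        return ImageGrid(pixels, self.spacing, self.modality, self.origin)


@dataclass
class DeformationField:
    """Dense per-pixel displacement (dy, dx) in pixels, shape (2, H, W)."""

    displacement: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 3 or self.displacement.shape[0] != 2:
            raise DimensionError(
                "DeformationField requires shape (2, H, W), got "
                f"{self.displacement.shape}"
            )
        if not np.all(np.isfinite(self.displacement)):
            raise ValidationError("DeformationField must be finite everywhere")
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.displacement.shape[1:]  # type: ignore[return-value]

    @property
    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.displacement**2, axis=0))


def ffd_control_shape(domain_shape: Sequence[int], grid_spacing_px: float) -> tuple[int, int]:
    """Number of control points needed to cover ``domain_shape`` at the given spacing."""
    h, w = int(domain_shape[0]), int(domain_shape[1])
    ncy = int(np.ceil((h - 1) / grid_spacing_px)) + 1
    ncx = int(np.ceil((w - 1) / grid_spacing_px)) + 1
    return ncy, ncx


@dataclass
class Transform:
    """A spatial mapping ``T x = x + d(x)`` over a fixed pixel domain.

    ``parameters`` is ``None`` for IDENTITY, a control-point displacement
    array of shape ``(2, ncy, ncx)`` (pixels) for BSPLINE_FFD, or a
    :class:`DeformationField` for DENSE.
    """

    kind: TransformKind
    parameters: object = None
    domain_shape: tuple[int, int] = (0, 0)
    grid_spacing_px: float = 16.0

    def __post_init__(self) -> None:
        self.kind = TransformKind(self.kind)
        self.domain_shape = (int(self.domain_shape[0]), int(self.domain_shape[1]))
        if self.kind is TransformKind.BSPLINE_FFD:
            ctrl = np.asarray(self.parameters, dtype=float)
            if ctrl.ndim != 3 or ctrl.shape[0] != 2:
                raise DimensionError(
                    f"FFD control array must have shape (2, ncy, ncx), got {ctrl.shape}"
                )
            if not np.all(np.isfinite(ctrl)):
                raise ValidationError("FFD control displacements must be finite")
            self.parameters = ctrl
        elif self.kind is TransformKind.DENSE:
            if not isinstance(self.parameters, DeformationField):
                self.parameters = DeformationField(np.asarray(self.parameters))
            if self.parameters.shape != self.domain_shape:
                raise DimensionError(
                    f"dense field shape {self.parameters.shape} != domain "
                    f"{self.domain_shape}"
                )

    # -- constructors -------------------------------------------------------

    @classmethod
    def identity(cls, domain_shape: Sequence[int]) -> "Transform":
        return cls(TransformKind.IDENTITY, None, tuple(domain_shape))

    @classmethod
    def from_field(cls, fld: DeformationField) -> "Transform":
        return cls(TransformKind.DENSE, fld, fld.shape)

    @classmethod
    def bspline(
        cls,
        control: np.ndarray,
        domain_shape: Sequence[int],
        grid_spacing_px: float,
    ) -> "Transform":
        return cls(TransformKind.BSPLINE_FFD, control, tuple(domain_shape), grid_spacing_px)

    # -- evaluation ---------------------------------------------------------

    def displacement_at(self, points_px: np.ndarray) -> np.ndarray:
        """Interpolate the displacement (pixels) at arbitrary pixel positions.

        Parameters
        ----------
        points_px : ndarray, shape (M, 2)
            (y, x) pixel coordinates.

        Returns
        -------
        ndarray, shape (M, 2) of (dy, dx) in pixels.
        """
        pts = np.atleast_2d(np.asarray(points_px, dtype=float))
        if self.kind is TransformKind.IDENTITY:
            return np.zeros_like(pts)
        if self.kind is TransformKind.DENSE:
            fld = self.parameters.displacement  # type: ignore[union-attr]
            coords = pts.T  # (2, M)
            out = np.empty_like(pts)
            for ch in range(2):
                out[:, ch] = ndimage.map_coordinates(
                    fld[ch], coords, order=1, mode="nearest"
                )
            return out
        # BSPLINE_FFD: control values are cubic B-spline coefficients on the
        # control lattice; prefilter=False keeps them as coefficients (true FFD).
        ctrl = self.parameters  # type: ignore[assignment]
        coords = pts.T / self.grid_spacing_px
        out = np.empty_like(pts)
        for ch in range(2):
            out[:, ch] = ndimage.map_coordinates(
                ctrl[ch], coords, order=3, mode="nearest", prefilter=False
            )
        return out

    def to_dense_field(self, spacing: tuple[float, float] = (1.0, 1.0)) -> DeformationField:
        h, w = self.domain_shape
        if self.kind is TransformKind.IDENTITY:
            return DeformationField(np.zeros((2, h, w)), spacing)
        if self.kind is TransformKind.DENSE:
            fld = self.parameters
            return DeformationField(fld.displacement.copy(), spacing)
        yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        pts = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(float)
        disp = self.displacement_at(pts)
        return DeformationField(disp.T.reshape(2, h, w), spacing)


@dataclass
class LandmarkSet:
    """Labelled (y, x) points in mm."""

    points: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 2)
        if self.points.shape[1] != 2:
            raise DimensionError(
                f"LandmarkSet points must be (M, 2), got {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("landmark coordinates must be finite")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != len(self.points):
            raise ValidationError("labels and points length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("landmark labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {"label": self.labels, "y_mm": self.points[:, 0], "x_mm": self.points[:, 1]}
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LandmarkSet":
        df = pd.read_csv(path)
        missing = {"label", "y_mm", "x_mm"} - set(df.columns)
        if missing:
            raise FormatError(f"landmark CSV missing columns {sorted(missing)}")
        return cls(df[["y_mm", "x_mm"]].to_numpy(float), list(df["label"].astype(str)))


# ---------------------------------------------------------------------------
# warping and point mapping
# ---------------------------------------------------------------------------

_ORDER = {Interpolation.BILINEAR: 1, Interpolation.NEAREST: 0}
_MODE = {Boundary.CONSTANT_ZERO: "constant", Boundary.EDGE_CLAMP: "nearest"}


def warp_image(
    image: ImageGrid,
    transform: Transform,
    interpolation: Interpolation = Interpolation.BILINEAR,
    boundary: Boundary = Boundary.EDGE_CLAMP,
) -> ImageGrid:
    """Backward-warp ``image``: ``out(x) = image(x + d(x))``.

    The output grid is identical in shape, spacing and origin to the input.
    """
    interpolation = Interpolation(interpolation)
    boundary = Boundary(boundary)
    if transform.domain_shape != image.shape:
        raise DimensionError(
            f"transform domain {transform.domain_shape} != image shape {image.shape}"
        )
    fld = transform.to_dense_field(image.spacing).displacement
    h, w = image.shape
    yy, xx = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    coords = np.stack([yy + fld[0], xx + fld[1]])
    out = ndimage.map_coordinates(
        image.pixels.astype(float),
        coords,
        order=_ORDER[interpolation],
        mode=_MODE[boundary],
        cval=0.0,
    )
    return image.with_pixels(out)


def transform_points(
    points: LandmarkSet, transform: Transform, image: ImageGrid
) -> LandmarkSet:
    """Move each landmark by the displacement interpolated at its location.

    Applies the same mapping the registration cost uses for patch centres
    (``x -> x + d(x)`` in pixels, converted back to mm). Points outside the
    image domain are excluded and logged.
    """
    px = image.mm_to_px(points.points)
    h, w = image.shape
    inside = (
        (px[:, 0] >= 0) & (px[:, 0] <= h - 1) & (px[:, 1] >= 0) & (px[:, 1] <= w - 1)
    )
    if not np.all(inside):
        dropped = [l for l, ok in zip(points.labels, inside) if not ok]
        logger.warning("transform_points: dropping out-of-domain landmarks %s", dropped)
    px_in = px[inside]
    disp = transform.displacement_at(px_in) if len(px_in) else np.zeros((0, 2))
    moved_mm = image.px_to_mm(px_in + disp)
    labels = [l for l, ok in zip(points.labels, inside) if ok]
    return LandmarkSet(moved_mm, labels)


def invert_field(fld: DeformationField, n_iter: int = 30) -> DeformationField:
    """Approximate inverse displacement by fixed-point iteration.

    Solves ``d_inv(x) = -d(x + d_inv(x))``; accurate for smooth fields whose
    Jacobian stays away from singularity.
    """
    d = fld.displacement
    h, w = fld.shape
    yy, xx = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    dinv = np.zeros_like(d)
    for _ in range(n_iter):
        coords = np.stack([yy + dinv[0], xx + dinv[1]])
        sampled = np.stack(
            [ndimage.map_coordinates(d[ch], coords, order=1, mode="nearest") for ch in range(2)]
        )
        dinv = -sampled
    return DeformationField(dinv, fld.spacing)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


class ImageFormat(str, Enum):
    PNG = "PNG"
    TIFF = "TIFF"
    NIFTI = "NIFTI"


def _infer_format(path: Path) -> ImageFormat:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return ImageFormat.NIFTI
    if name.endswith(".png"):
        return ImageFormat.PNG
    if name.endswith((".tif", ".tiff")):
        return ImageFormat.TIFF
    raise FormatError(f"cannot infer image format from {path.name!r}")


def read_image(path, fmt: Optional[ImageFormat] = None) -> ImageGrid:
    """Read a 2D image. PNG/TIFF get a default 1 mm spacing (with a warning);
    NIfTI spacing comes from the header."""
    path = Path(path)
    fmt = ImageFormat(fmt) if fmt is not None else _infer_format(path)
    if fmt is ImageFormat.NIFTI:
        img = nib.load(str(path))
        data = np.squeeze(np.asanyarray(img.dataobj))
        if data.ndim != 2:
            raise FormatError(
                f"{path.name}: expected a 2D image, got {data.ndim} axes "
                f"(shape {data.shape})"
            )
        zooms = img.header.get_zooms()[:2]
        return ImageGrid(np.asarray(data, float), (float(zooms[0]), float(zooms[1])))
    import imageio.v3 as iio

    arr = iio.imread(path)
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise FormatError(
            f"{path.name}: expected a single-channel 2D image, got {arr.ndim} axes "
            f"(shape {arr.shape})"
        )
    warnings.warn(
        f"{path.name}: {fmt.value} carries no spacing; defaulting to (1.0, 1.0) mm",
        stacklevel=2,
    )
    return ImageGrid(arr, (1.0, 1.0))


def write_image(image: ImageGrid, path, fmt: Optional[ImageFormat] = None) -> None:
    path = Path(path)
    fmt = ImageFormat(fmt) if fmt is not None else _infer_format(path)
    if fmt is ImageFormat.NIFTI:
        affine = np.diag([image.spacing[0], image.spacing[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(np.asarray(image.pixels, np.float64), affine), str(path))
        return
    if fmt is ImageFormat.PNG:
        if not np.issubdtype(image.pixels.dtype, np.integer):
            raise FormatError(
                "PNG output requires uint8/uint16 pixels; convert explicitly "
                f"(got dtype {image.pixels.dtype})"
            )
        import imageio.v3 as iio

        iio.imwrite(path, image.pixels)
        return
    import tifffile

    tifffile.imwrite(path, image.pixels)


def save_deformation_field(fld: DeformationField, path) -> None:
    """NIfTI (H, W, 2) volume + JSON sidecar recording convention and units."""
    path = Path(path)
    data = np.moveaxis(fld.displacement, 0, -1)  # (H, W, 2)
    affine = np.diag([fld.spacing[0], fld.spacing[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, np.float64), affine), str(path))
    sidecar = {
        "convention": "backward warp: out(x) = image(x + d(x))",
        "channels": ["dy", "dx"],
        "units": "pixels",
        "spacing_mm": list(fld.spacing),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_deformation_field(path) -> DeformationField:
    path = Path(path)
    img = nib.load(str(path))
    data = np.squeeze(np.asanyarray(img.dataobj))
    if data.ndim != 3 or data.shape[-1] != 2:
        raise FormatError(
            f"{path.name}: expected an (H, W, 2) displacement volume, got shape {data.shape}"
        )
    spacing = img.header.get_zooms()[:2]
    return DeformationField(np.moveaxis(np.asarray(data, float), -1, 0), (float(spacing[0]), float(spacing[1])))
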