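"""Synthetic brain-mimicking phantom with embedded tubular vessels.

Generates paired MR-like / PA-like / US-like renderings of the same scene,
ground-truth vessel-centreline landmarks, and smooth random deformation
fields, so the whole registration pipeline can be exercised end to end with
known ground truth.

The geometry emulates a desk-scale tissue slab (default 150 x 40 mm with a
curved, head-like top surface) containing thin tubular vessels (default
inner diameters 1.2 and 1.4 mm). The contrast models are simple analytic
renderings, not physics simulation:

* MR-like: bright tissue with a smooth intensity texture, mildly dark
  vessels, additive Gaussian noise;
* PA-like: near-zero tissue signal, bright vessels, multiplicative depth
  attenuation ``exp(-rate * depth_mm)`` of the illumination reaching each
  pixel, additive Gaussian noise;
* US-like: multiplicative speckle on tissue with weak vessel contrast.

All generators are reproducible from integer seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .imaging import DeformationField, ImageGrid, LandmarkSet, Modality, ValidationError

logger = logging.getLogger("cosreg")


class GenerationError(RuntimeError):
    """Phantom geometry could not be realized within the retry budget."""


@dataclass
class PhantomSpec:
    """Geometry, contrast and noise parameters of the synthetic phantom."""

    body_width_mm: float = 150.0
    body_height_mm: float = 40.0
    curved_top: bool = True
    curve_depth_mm: float = 10.0
    vessel_diameters_mm: tuple[float, ...] = (1.2, 1.4)
    vessel_count: int = 2
    vessel_wiggle_mm: float = 7.0  # tortuosity amplitude of the centrelines
    vessel_wiggle_cycles: float = 5.0  # bends per vessel span
    noise_sigma: dict = field(
        default_factory=lambda: {"MR": 0.02, "PA": 0.02, "US": 0.02}
    )
    pa_attenuation_per_mm: float = 0.1
    mr_texture_amplitude: float = 0.15
    mr_texture_sigma_px: float = 6.0
    us_speckle_strength: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.vessel_diameters_mm):
            raise ValidationError("vessel diameters must be positive")
        if self.body_width_mm <= 0 or self.body_height_mm <= 0:
            raise ValidationError("body dimensions must be positive")
        if self.vessel_count < 1:
            raise ValidationError("vessel_count must be >= 1")


@dataclass
class DeformationSpec:
    """Smooth random deformation: bandlimited noise rescaled to a peak magnitude."""

    max_displacement_px: float = 8.0
    smoothness_sigma_px: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_displacement_px < 0:
            raise ValidationError("max_displacement_px must be >= 0")
        if self.smoothness_sigma_px < 1:
            raise ValidationError("smoothness_sigma_px must be >= 1")


@dataclass
class PhantomScene:
    """Full output of the generator, including masks the 5-tuple API omits."""

    mr: ImageGrid
    pa: ImageGrid
    us: ImageGrid
    landmarks: LandmarkSet
    vessel_mask: np.ndarray
    body_mask: np.ndarray
    depth_mm: np.ndarray
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def _body_geometry(spec: PhantomSpec, shape_px, spacing_mm):
    """Body mask and per-pixel depth (mm below the top surface)."""
    h, w = shape_px
    dy, dx = spacing_mm
    y_mm = np.arange(h) * dy
    x_mm = np.arange(w) * dx
    height_mm, width_mm = h * dy, w * dx
    if spec.body_width_mm > width_mm or spec.body_height_mm + spec.curve_depth_mm > height_mm:
        raise GenerationError(
            f"body {spec.body_width_mm}x{spec.body_height_mm} mm (+ curve) does not "
            f"fit a {width_mm:.1f}x{height_mm:.1f} mm canvas"
        )
    xc = width_mm / 2.0
    half_w = spec.body_width_mm / 2.0
    y_bot = (height_mm + spec.body_height_mm) / 2.0
    u = np.clip((x_mm - xc) / half_w, -1.0, 1.0)
    curve = spec.curve_depth_mm * u**2 if spec.curved_top else np.zeros_like(u)
    y_top = (y_bot - spec.body_height_mm) + curve  # per-column top surface
    inside_x = np.abs(x_mm - xc) <= half_w
    yy = y_mm[:, None]
    body = inside_x[None, :] & (yy >= y_top[None, :]) & (yy <= y_bot)
    depth = np.where(body, yy - y_top[None, :], 0.0)
    return body, depth, y_top, y_bot, xc, half_w


def _smooth_noise(rng, n, sigma, amplitude):
    z = ndimage.gaussian_filter1d(rng.standard_normal(n), sigma, mode="nearest")
    peak = np.max(np.abs(z))
    return z * (amplitude / peak) if peak > 0 else z


def _vessel_centerlines(spec, rng, shape_px, spacing_mm, y_top, y_bot, xc, half_w,
                        max_retries: int = 50):
    """Smooth left-to-right tube centrelines kept inside the body."""
    dy, dx = spacing_mm
    diameters = [
        spec.vessel_diameters_mm[i % len(spec.vessel_diameters_mm)]
        for i in range(spec.vessel_count)
    ]
    thickness = y_bot - y_top  # per-column available thickness (mm)
    x_mm = np.arange(shape_px[1]) * dx
    lines = []
    for i, diam in enumerate(diameters):
        margin = diam / 2.0 + 1.0  # keep the wall + 1 mm inside the body
        for attempt in range(max_retries):
            x_lo, x_hi = xc - 0.45 * spec.body_width_mm, xc + 0.45 * spec.body_width_mm
            cols = (x_mm >= x_lo) & (x_mm <= x_hi)
            xs = x_mm[cols]
            base = rng.uniform(0.2, 0.8)
            wiggle = _smooth_noise(
                rng,
                len(xs),
                sigma=max(len(xs) / (3.0 * spec.vessel_wiggle_cycles), 1.0),
                amplitude=spec.vessel_wiggle_mm,
            )
            ys = y_top[cols] + base * thickness[cols] + wiggle
            lo = y_top[cols] + margin
            hi = y_bot - margin
            if np.all(hi > lo):
                ys = np.clip(ys, lo, hi)
                lines.append((np.asarray(xs), np.asarray(ys), diam))
                break
        else:
            raise GenerationError(
                f"vessel {i} could not be placed inside the body after {max_retries} tries"
            )
    return lines


def _rasterize_vessels(lines, shape_px, spacing_mm, body):
    """Vessel interior mask from distance to densely sampled centrelines."""
    dy, dx = spacing_mm
    mask = np.zeros(shape_px, dtype=bool)
    for xs, ys, diam in lines:
        # densify the polyline so the rasterized centreline is connected
        t = np.linspace(0, 1, len(xs))
        tq = np.linspace(0, 1, max(4 * len(xs), 256))
        xq = np.interp(tq, t, xs)
        yq = np.interp(tq, t, ys)
        on = np.zeros(shape_px, dtype=bool)
        iy = np.clip(np.round(yq / dy).astype(int), 0, shape_px[0] - 1)
        ix = np.clip(np.round(xq / dx).astype(int), 0, shape_px[1] - 1)
        on[iy, ix] = True
        dist = ndimage.distance_transform_edt(~on, sampling=(dy, dx))
        mask |= dist <= diam / 2.0
    return mask & body


# ---------------------------------------------------------------------------
# modality renderings (pure functions; testable in isolation)
# ---------------------------------------------------------------------------


def render_pa(
    body: np.ndarray,
    vessels: np.ndarray,
    depth_mm: np.ndarray,
    attenuation_per_mm: float,
    tissue_absorption: float = 0.008,
    vessel_absorption: float = 1.0,
) -> np.ndarray:
    """PA-like image: absorption times depth-attenuated fluence."""
    fluence = np.exp(-attenuation_per_mm * depth_mm)
    absorption = np.where(vessels, vessel_absorption, np.where(body, tissue_absorption, 0.0))
    return absorption * fluence


def render_mr(
    body: np.ndarray,
    vessels: np.ndarray,
    texture: np.ndarray,
    tissue_level: float = 0.8,
    vessel_level: float = 0.35,
    background: float = 0.05,
) -> np.ndarray:
    img = np.full(body.shape, background)
    img[body] = tissue_level + texture[body]
    img[vessels] = vessel_level
    return img


def render_us(
    body: np.ndarray,
    vessels: np.ndarray,
    speckle: np.ndarray,
    tissue_level: float = 0.45,
    vessel_contrast: float = 0.15,
    background: float = 0.02,
) -> np.ndarray:
    img = np.full(body.shape, background)
    img[body] = tissue_level * speckle[body]
    img[vessels] += vessel_contrast
    return img


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_scene(
    spec: PhantomSpec,
    shape_px: Sequence[int] = (256, 256),
    spacing_mm: Sequence[float] = (0.6, 0.6),
) -> PhantomScene:
    """Generate the full phantom scene (images, masks, landmarks)."""
    shape_px = (int(shape_px[0]), int(shape_px[1]))
    spacing_mm = (float(spacing_mm[0]), float(spacing_mm[1]))
    rng = np.random.default_rng(spec.seed)

    body, depth, y_top, y_bot, xc, half_w = _body_geometry(spec, shape_px, spacing_mm)
    lines = _vessel_centerlines(spec, rng, shape_px, spacing_mm, y_top, y_bot, xc, half_w)
    vessels = _rasterize_vessels(lines, shape_px, spacing_mm, body)

    # landmarks: three points per vessel on the centreline
    pts, labels = [], []
    for vi, (xs, ys, _d) in enumerate(lines):
        for pi, frac in enumerate((0.25, 0.5, 0.75)):
            j = int(frac * (len(xs) - 1))
            pts.append((ys[j], xs[j]))
            labels.append(f"V{vi + 1}P{pi + 1}")
    landmarks = LandmarkSet(np.asarray(pts), labels)

    texture = ndimage.gaussian_filter(
        rng.standard_normal(shape_px), spec.mr_texture_sigma_px, mode="nearest"
    )
    peak = np.max(np.abs(texture))
    if peak > 0:
        texture *= spec.mr_texture_amplitude / peak
    # gamma speckle with unit mean, variance controlled by speckle strength
    k = max(1.0 / max(spec.us_speckle_strength, 1e-6) ** 2, 1.0)
    speckle = rng.gamma(shape=k, scale=1.0 / k, size=shape_px)

    mr = render_mr(body, vessels, texture)
    pa = render_pa(body, vessels, depth, spec.pa_attenuation_per_mm)
    us = render_us(body, vessels, speckle)

    sig = {m: float(spec.noise_sigma.get(m, 0.0)) for m in ("MR", "PA", "US")}
    mr = mr + sig["MR"] * rng.standard_normal(shape_px)
    pa = pa + sig["PA"] * rng.standard_normal(shape_px)
    us = us + sig["US"] * rng.standard_normal(shape_px)

    return PhantomScene(
        mr=ImageGrid(mr, spacing_mm, Modality.MR),
        pa=ImageGrid(pa, spacing_mm, Modality.PA),
        us=ImageGrid(us, spacing_mm, Modality.US),
        landmarks=landmarks,
        vessel_mask=vessels,
        body_mask=body,
        depth_mm=depth,
        spec=spec,
    )


def generate_phantom(
    spec: PhantomSpec,
    shape_px: Sequence[int] = (256, 256),
    spacing_mm: Sequence[float] = (0.6, 0.6),
):
    """Spec-level API: ``(mr, pa, us, landmarks, vessel_mask)``."""
    s = generate_scene(spec, shape_px, spacing_mm)
    return s.mr, s.pa, s.us, s.landmarks, s.vessel_mask


def generate_deformation(spec: DeformationSpec, shape_px: Sequence[int]) -> DeformationField:
    """Smooth zero-mean random displacement with peak magnitude ``max_displacement_px``.

    Independent Gaussian noise per channel is smoothed with the stated sigma,
    de-meaned per channel, and rescaled so the maximum vector magnitude equals
    ``max_displacement_px`` exactly.
    """
    shape_px = (int(shape_px[0]), int(shape_px[1]))
    if spec.max_displacement_px == 0:
        return DeformationField(np.zeros((2, *shape_px)))
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal((2, *shape_px))
    # periodic smoothing keeps the field statistically stationary; edge modes
    # would inflate border variance and park the peak magnitude in a corner
    fld = ndimage.gaussian_filter(
        noise, sigma=(0, spec.smoothness_sigma_px, spec.smoothness_sigma_px), mode="wrap"
    )
    fld -= fld.mean(axis=(1, 2), keepdims=True)
    mag = np.sqrt(np.sum(fld**2, axis=0))
    peak = mag.max()
    if peak == 0:  # pragma: no cover - smoothing of nonzero noise never flattens to 0
        return DeformationField(fld)
    fld *= spec.max_displacement_px / peak
    return DeformationField(fld)
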