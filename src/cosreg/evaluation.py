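"""Registration accuracy metrics: TRE, displacement-field RMSE, HD95.

All metrics are reported in millimetres. RMSE is interpreted as the root
mean square of the residual displacement-vector error between the known
and recovered fields over an evaluation mask (an intensity-difference RMSE
is available separately as a clearly labelled secondary reading). The
Hausdorff distance applies the 95th percentile to each directed
nearest-neighbour distance distribution (linear-interpolation percentile)
and takes the outer maximum of the two directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .imaging import (
    DeformationField,
    DimensionError,
    ImageGrid,
    LandmarkSet,
    Transform,
    ValidationError,
    transform_points,
)
from .registration import RegistrationResult

logger = logging.getLogger("cosreg")


@dataclass
class EvalRow:
    """Metrics of a single registration run."""

    method: str
    rmse_mm: float
    tre_mm: float
    tre_per_target: dict
    hd95_mm: float
    hd_mm: float
    intensity_rmse: Optional[float] = None
    n_targets: int = 0


@dataclass
class EvalReport:
    """Mean +/- std aggregate over repeated runs (one row per method)."""

    method: str
    rmse_mm_mean: float
    rmse_mm_std: Optional[float]
    tre_mm_mean: float
    tre_mm_std: Optional[float]
    hd95_mm_mean: float
    hd95_mm_std: Optional[float]
    n_runs: int
    n_targets: int


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def tre(gt_targets: LandmarkSet, recovered_targets: LandmarkSet):
    """Per-target Euclidean distances (mm) between matching labels + mean."""
    gt = dict(zip(gt_targets.labels, gt_targets.points))
    rec = dict(zip(recovered_targets.labels, recovered_targets.points))
    missing = sorted(set(gt) ^ set(rec))
    if missing:
        raise ValidationError(f"label mismatch between landmark sets: {missing}")
    per = {
        lab: float(np.linalg.norm(np.asarray(gt[lab]) - np.asarray(rec[lab])))
        for lab in gt_targets.labels
    }
    return per, float(np.mean(list(per.values())))


def displacement_rmse(
    gt_field: DeformationField,
    recovered_field: DeformationField,
    mask: Optional[np.ndarray] = None,
    spacing: Optional[tuple] = None,
) -> float:
    """RMS of the residual displacement-vector error over ``mask``, in mm."""
    if gt_field.shape != recovered_field.shape:
        raise DimensionError(
            f"field shapes differ: {gt_field.shape} vs {recovered_field.shape}"
        )
    spacing = spacing or gt_field.spacing
    if mask is None:
        mask = np.ones(gt_field.shape, dtype=bool)
    if not np.any(mask):
        raise ValidationError("empty evaluation mask")
    res = gt_field.displacement - recovered_field.displacement
    res_mm = res * np.asarray(spacing, float)[:, None, None]
    sq = np.sum(res_mm**2, axis=0)[mask]
    return float(np.sqrt(np.mean(sq)))


def intensity_rmse(a: ImageGrid, b: ImageGrid, mask: Optional[np.ndarray] = None) -> float:
    """Secondary reading: RMS intensity difference (image units, not mm)."""
    if a.shape != b.shape:
        raise DimensionError("image shapes differ")
    diff = (a.pixels - b.pixels)[mask] if mask is not None else (a.pixels - b.pixels)
    return float(np.sqrt(np.mean(diff**2)))


def hausdorff_distance(
    points_a: np.ndarray, points_b: np.ndarray, percentile: float = 95.0
) -> float:
    """Percentile Hausdorff distance between two point sets in mm.

    ``percentile=100`` recovers the classical maximum Hausdorff distance.
    """
    A = np.atleast_2d(np.asarray(points_a, float))
    B = np.atleast_2d(np.asarray(points_b, float))
    if len(A) == 0 or len(B) == 0:
        raise ValidationError("point sets must be non-empty")
    d_ab = cKDTree(B).query(A)[0]
    d_ba = cKDTree(A).query(B)[0]
    return float(
        max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile))
    )


def hausdorff95(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """95th-percentile Hausdorff distance (outlier-robust boundary metric)."""
    return hausdorff_distance(points_a, points_b, 95.0)


# ---------------------------------------------------------------------------
# run-level evaluation
# ---------------------------------------------------------------------------


def _invert_at_points(fld: DeformationField, pts_px: np.ndarray, n_iter: int = 40):
    """Solve x + d(x) = p per point by fixed-point iteration (x in pixels)."""
    d = fld.displacement
    x = pts_px.copy().astype(float)
    for _ in range(n_iter):
        disp = np.stack(
            [
                ndimage.map_coordinates(d[ch], x.T, order=1, mode="nearest")
                for ch in range(2)
            ],
            axis=1,
        )
        x = pts_px - disp
    return x


def mask_boundary_points(mask: np.ndarray) -> np.ndarray:
    """Pixel coordinates (y, x) of the mask's inner boundary."""
    er = ndimage.binary_erosion(mask)
    by, bx = np.nonzero(mask & ~er)
    return np.stack([by, bx], axis=1).astype(float)


def evaluate_run(
    gt: dict,
    result: RegistrationResult,
    spacing: tuple,
    border_px: int = 8,
) -> EvalRow:
    """Score one registration run against synthetic ground truth.

    ``gt`` holds ``field`` (the true :class:`DeformationField` applied to
    the float image), ``landmarks`` (reference-frame :class:`LandmarkSet`,
    mm) and ``mask`` (reference-frame structure mask). Metrics that need a
    missing ground-truth entry are reported as NaN, not zero.

    TRE/HD95 follow the transform convention of the registrar: the true
    field maps float-frame pixels to the reference frame, so float-frame
    target locations are obtained by inverting the true field (which the
    evaluation owns exactly) and then pushed through the recovered
    transform.
    """
    gt_field: Optional[DeformationField] = gt.get("field")
    landmarks: Optional[LandmarkSet] = gt.get("landmarks")
    mask: Optional[np.ndarray] = gt.get("mask")
    t_rec: Transform = result.transform

    rmse = float("nan")
    if gt_field is not None:
        rec_field = t_rec.to_dense_field(spacing)
        h, w = gt_field.shape
        eval_mask = np.zeros((h, w), dtype=bool)
        b = min(border_px, h // 4, w // 4)
        eval_mask[b : h - b, b : w - b] = True
        rmse = displacement_rmse(gt_field, rec_field, eval_mask, spacing)

    tre_mean, per = float("nan"), {}
    n_targets = 0
    if landmarks is not None and gt_field is not None and len(landmarks):
        sp = np.asarray(spacing, float)
        ref_px = landmarks.points / sp
        flt_px = _invert_at_points(gt_field, ref_px)
        ref_img = ImageGrid(np.zeros(gt_field.shape), spacing)
        flt_lms = LandmarkSet(flt_px * sp, landmarks.labels)
        mapped = transform_points(flt_lms, t_rec, ref_img)
        kept = LandmarkSet(
            np.asarray([p for p, l in zip(landmarks.points, landmarks.labels) if l in mapped.labels]),
            [l for l in landmarks.labels if l in mapped.labels],
        )
        per, tre_mean = tre(kept, mapped)
        n_targets = len(kept)

    hd95 = hd = float("nan")
    if mask is not None and gt_field is not None and np.any(mask):
        sp = np.asarray(spacing, float)
        bpts = mask_boundary_points(mask)
        flt_b = _invert_at_points(gt_field, bpts)
        disp = t_rec.displacement_at(flt_b)
        reg_b = (flt_b + disp) * sp
        ref_b = bpts * sp
        hd95 = hausdorff95(reg_b, ref_b)
        hd = hausdorff_distance(reg_b, ref_b, 100.0)

    return EvalRow(
        method=result.metadata.get("method", "?"),
        rmse_mm=rmse,
        tre_mm=tre_mean,
        tre_per_target=per,
        hd95_mm=hd95,
        hd_mm=hd,
        n_targets=n_targets,
    )


def aggregate(rows: list[EvalRow]) -> EvalReport:
    """Mean +/- std over runs of one method; std omitted for a single run."""
    if not rows:
        raise ValidationError("no rows to aggregate")
    method = rows[0].method
    def stats(vals):
        vals = np.asarray(vals, float)
        mean = float(np.mean(vals))
        std = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
        return mean, std
    rm, rs = stats([r.rmse_mm for r in rows])
    tm, ts = stats([r.tre_mm for r in rows])
    hm, hs = stats([r.hd95_mm for r in rows])
    return EvalReport(
        method=method,
        rmse_mm_mean=rm,
        rmse_mm_std=rs,
        tre_mm_mean=tm,
        tre_mm_std=ts,
        hd95_mm_mean=hm,
        hd95_mm_std=hs,
        n_runs=len(rows),
        n_targets=rows[0].n_targets,
    )


def report_table(reports: list[EvalReport]) -> pd.DataFrame:
    """Tabular layout: one row per method, mean +/- std per metric."""
    def fmt(mean, std):
        if std is None:
            return f"{mean:.2f}"
        return f"{mean:.2f} +/- {std:.2f}"
    return pd.DataFrame(
        [
            {
                "method": r.method,
                "RMSE_mm": fmt(r.rmse_mm_mean, r.rmse_mm_std),
                "TRE_mm": fmt(r.tre_mm_mean, r.tre_mm_std),
                "HD95_mm": fmt(r.hd95_mm_mean, r.hd95_mm_std),
                "n_runs": r.n_runs,
                "n_targets": r.n_targets,
            }
            for r in reports
        ]
    )
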