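"""Deformable registration under the coupled co-sparsity cost, plus an NMI
baseline sharing the identical optimization scaffold.

The transform is a cubic B-spline free-form deformation optimized coarse to
fine by first-order descent with a backtracking line search; gradients are
central finite differences on the control-point displacements (step 0.5
px). Coarse levels are realized by Gaussian smoothing at native resolution
(with a doubled control spacing at the coarsest levels) rather than by
decimation: the analysis operators are tied to the native pixel scale, and
decimation would erase the few-pixel-wide vessel structures that carry the
cross-modality signal. The cost is sampled at patch centres laid out
on a grid with stride equal to the patch size, so the windows tile the
interior of the image. The displacement interpolated at a centre translates
its whole window (a locally rigid approximation), which makes the sampled
reference patch a plain off-grid bilinear read.

The similarity term is pluggable and is the ONLY thing that differs between
the two registrars:

* JACSM: mean joint log-square surrogate of the fixed learned operator
  responses on (float on-grid, reference off-grid) patch pairs;
* NMI: normalized mutual information of the joint histogram of the pooled
  patch-pixel correspondences (negated for minimization).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field as _field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage

from .cosparse import AnalysisOperator, _joint_g_columns
from .imaging import (
    DeformationField,
    DimensionError,
    ImageGrid,
    Transform,
    TransformKind,
    ValidationError,
    ffd_control_shape,
    invert_field,
    warp_image,
)
from .patches import patches_at

logger = logging.getLogger("cosreg")


class RegistrationError(RuntimeError):
    pass


@dataclass
class OptimizerConfig:
    max_iter_per_level: int = 30
    step_init: float = 1.0  # largest control-point motion (px) of the first step
    step_max: float = 4.0
    step_shrink: float = 0.5
    tol_rel: float = 1e-4
    max_backtracks: int = 12
    fd_step_px: float = 0.5


@dataclass
class RegistrationConfig:
    transform_model: str = "BSPLINE_FFD"
    grid_spacing_px: float = 16.0
    pyramid_levels: int = 3
    sample_centers: str = "GRID"  # GRID | RANDOM
    n_cost_patches: int = 1000  # RANDOM sampling only
    patch_size: int = 7
    margin_px: int = 4  # extra interior margin beyond the patch half-width
    # keep only centres whose float patch carries signal (std above this
    # quantile); metric-agnostic, so both registrars see identical centres
    center_energy_quantile: float = 0.7
    nu: float = 1e3
    nu_anneal: float = 1.0  # optional: nu divided by this per level above the finest
    bending_weight: float = 0.2  # weight of the control-lattice bending energy
    init_shift_px: float = 0.0  # optional coarse-level multi-start over constant shifts
    nmi_bins: int = 32
    optimizer: OptimizerConfig = _field(default_factory=OptimizerConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pyramid_levels < 1:
            raise ValidationError("pyramid_levels must be >= 1")
        if self.grid_spacing_px < self.patch_size:
            raise ValidationError("grid_spacing_px must be >= patch_size")


@dataclass
class RegistrationResult:
    transform: Transform
    warped_float: ImageGrid
    cost_trace: list
    converged: bool
    metadata: dict


# ---------------------------------------------------------------------------
# similarity metrics over patch-centre correspondences
# ---------------------------------------------------------------------------


class _JacsmMetric:
    """Mean joint co-sparsity of operator responses; separable over centres.

    ``nu`` controls how sharply the log-square surrogate saturates; the
    registrar anneals it over levels (graduated non-convexity): small values
    make the cost nearly quadratic in the stacked response, widening basins,
    and the final level uses the model's own nu.
    """

    name = "JACSM"

    def __init__(self, op_float: AnalysisOperator, op_ref: AnalysisOperator, nu: float):
        self.of = op_float.omega
        self.orf = op_ref.omega
        self.nu = nu

    def prepare(self, float_patches: np.ndarray) -> None:
        xf = float_patches - float_patches.mean(axis=0, keepdims=True)
        self.A = self.of @ xf  # (k, M), fixed during optimization

    def _percenter(self, ref_patches: np.ndarray, idx) -> np.ndarray:
        xr = ref_patches - ref_patches.mean(axis=0, keepdims=True)
        B = self.orf @ xr
        return _joint_g_columns(self.A[:, idx], B, self.nu)

    def evaluate(self, ref_patches: np.ndarray, valid: np.ndarray):
        c = self._percenter(ref_patches, slice(None))
        nv = int(valid.sum())
        if nv == 0:
            raise RegistrationError("all cost centres dropped out of the domain")
        cost = float(c[valid].sum()) / nv
        return cost, {"c": c, "valid": valid, "sum": float(c[valid].sum()), "nv": nv}

    def delta(self, aux, idx, new_ref_patches, new_valid):
        c_new = self._percenter(new_ref_patches, idx)
        old_v = aux["valid"][idx]
        s = aux["sum"] - float(aux["c"][idx][old_v].sum()) + float(c_new[new_valid].sum())
        nv = aux["nv"] - int(old_v.sum()) + int(new_valid.sum())
        if nv == 0:
            raise RegistrationError("all cost centres dropped out of the domain")
        return s / nv


class _NmiMetric:
    """Negated NMI of pooled patch-pixel correspondences (incremental hist)."""

    name = "NMI"

    def __init__(self, bins: int, float_range, ref_range):
        self.bins = bins
        self.fr = float_range
        self.rr = ref_range

    def _digitize(self, vals, rng_):
        lo, hi = rng_
        span = max(hi - lo, 1e-12)
        return np.clip(((vals - lo) / span * self.bins).astype(np.int64), 0, self.bins - 1)

    def prepare(self, float_patches: np.ndarray) -> None:
        self.F = self._digitize(float_patches, self.fr)  # (n, M)

    def _pairs(self, R_bins, idx):
        return (self.F[:, idx] * self.bins + R_bins).ravel()

    def _nmi_from_hist(self, H):
        total = H.sum()
        if total == 0:
            raise RegistrationError("all cost centres dropped out of the domain")
        pxy = H / total
        px = pxy.sum(axis=1)
        py = pxy.sum(axis=0)
        def ent(p):
            p = p[p > 0]
            return float(-np.sum(p * np.log(p)))
        hxy = ent(pxy.ravel())
        if hxy == 0:
            return 2.0
        return (ent(px) + ent(py)) / hxy

    def evaluate(self, ref_patches: np.ndarray, valid: np.ndarray):
        R = self._digitize(ref_patches, self.rr)  # (n, M)
        vidx = np.flatnonzero(valid)
        H = np.bincount(
            self._pairs(R[:, vidx], vidx), minlength=self.bins**2
        ).astype(float)
        cost = -self._nmi_from_hist(H.reshape(self.bins, self.bins))
        return cost, {"R": R, "valid": valid, "H": H}

    def delta(self, aux, idx, new_ref_patches, new_valid):
        R_new = self._digitize(new_ref_patches, self.rr)
        H = aux["H"].copy()
        old_v = np.flatnonzero(aux["valid"][idx])
        if old_v.size:
            sub = np.bincount(
                self._pairs(aux["R"][:, idx[old_v]], idx[old_v]), minlength=self.bins**2
            )
            H -= sub
        new_v = np.flatnonzero(new_valid)
        if new_v.size:
            add = np.bincount(
                (self.F[:, idx[new_v]] * self.bins + R_new[:, new_v]).ravel(),
                minlength=self.bins**2,
            )
            H += add
        return -self._nmi_from_hist(H.reshape(self.bins, self.bins))


# ---------------------------------------------------------------------------
# per-level problem
# ---------------------------------------------------------------------------


def _grid_centers(shape, patch_size, margin_px, stride=None):
    half = patch_size // 2
    m = half + margin_px
    stride = stride or patch_size
    ys = np.arange(m, shape[0] - m, stride)
    xs = np.arange(m, shape[1] - m, stride)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    return np.stack([yy.ravel(), xx.ravel()], axis=1).astype(float)


class _LevelProblem:
    def __init__(self, ref_px, flt_px, centers, patch_size, grid_spacing, metric):
        self.ref = np.asarray(ref_px, float)
        self.flt = np.asarray(flt_px, float)
        self.centers = centers
        self.p = patch_size
        self.half = patch_size // 2
        self.sp = grid_spacing
        self.metric = metric
        self.shape = self.ref.shape
        metric.prepare(patches_at(self.flt, centers, patch_size))
        self.ctrl_shape = (2, *ffd_control_shape(self.shape, grid_spacing))
        # centres influenced by each control point (cubic support: 2 cells)
        gy = centers[:, 0] / grid_spacing
        gx = centers[:, 1] / grid_spacing
        self.affected = {}
        for i in range(self.ctrl_shape[1]):
            for j in range(self.ctrl_shape[2]):
                sel = (np.abs(gy - i) < 2.0) & (np.abs(gx - j) < 2.0)
                self.affected[(i, j)] = np.flatnonzero(sel)

    def _disp(self, ctrl, idx=None):
        t = Transform.bspline(ctrl, self.shape, self.sp)
        pts = self.centers if idx is None else self.centers[idx]
        return t.displacement_at(pts)

    def _ref_patches(self, tcenters):
        h, w = self.shape
        valid = (
            (tcenters[:, 0] >= self.half)
            & (tcenters[:, 0] <= h - 1 - self.half)
            & (tcenters[:, 1] >= self.half)
            & (tcenters[:, 1] <= w - 1 - self.half)
        )
        clamped = np.clip(tcenters, [0, 0], [h - 1, w - 1])
        return patches_at(self.ref, clamped, self.p), valid

    def state(self, ctrl):
        tc = self.centers + self._disp(ctrl)
        patches, valid = self._ref_patches(tc)
        cost, aux = self.metric.evaluate(patches, valid)
        return cost, aux

    def cost(self, ctrl):
        return self.state(ctrl)[0]

    def cost_perturbed(self, aux, idx, ctrl):
        tc = self.centers[idx] + self._disp(ctrl, idx)
        patches, valid = self._ref_patches(tc)
        return self.metric.delta(aux, idx, patches, valid)

    def fd_gradient(self, ctrl, aux, h):
        g = np.zeros_like(ctrl)
        for i in range(self.ctrl_shape[1]):
            for j in range(self.ctrl_shape[2]):
                idx = self.affected[(i, j)]
                if idx.size == 0:
                    continue
                for ch in range(2):
                    orig = ctrl[ch, i, j]
                    ctrl[ch, i, j] = orig + h
                    cp = self.cost_perturbed(aux, idx, ctrl)
                    ctrl[ch, i, j] = orig - h
                    cm = self.cost_perturbed(aux, idx, ctrl)
                    ctrl[ch, i, j] = orig
                    g[ch, i, j] = (cp - cm) / (2 * h)
        return g


def _bending_value_grad(ctrl: np.ndarray):
    """Mean squared second differences of the control lattice + gradient.

    Discrete thin-plate bending energy of the FFD: penalizes non-physical
    high-curvature wiggles of the recovered field without biasing smooth
    large-scale deformation.
    """
    val = 0.0
    grad = np.zeros_like(ctrl)
    n_terms = 0
    for axis, w in ((1, 1.0), (2, 1.0)):
        d2 = np.diff(ctrl, n=2, axis=axis)
        val += w * float(np.sum(d2**2))
        n_terms += d2[0].size
        g = np.zeros_like(ctrl)
        sl = [slice(None)] * 3
        sl[axis] = slice(0, -2)
        g[tuple(sl)] += d2
        sl[axis] = slice(1, -1)
        g[tuple(sl)] += -2 * d2
        sl[axis] = slice(2, None)
        g[tuple(sl)] += d2
        grad += 2 * w * g
    # mixed derivative
    dxy = np.diff(np.diff(ctrl, axis=1), axis=2)
    val += 2.0 * float(np.sum(dxy**2))
    n_terms += dxy[0].size
    g = np.zeros_like(ctrl)
    g[:, :-1, :-1] += dxy
    g[:, :-1, 1:] -= dxy
    g[:, 1:, :-1] -= dxy
    g[:, 1:, 1:] += dxy
    grad += 4.0 * g
    n_terms = max(n_terms, 1)
    return val / n_terms, grad / n_terms


def _optimize_level(prob: _LevelProblem, ctrl, opt: OptimizerConfig, lam: float = 0.0):
    def total(c):
        return prob.cost(c) + (lam * _bending_value_grad(c)[0] if lam else 0.0)

    cost, aux = prob.state(ctrl)
    if not np.isfinite(cost):
        raise RegistrationError(
            "non-finite cost at initialization: check operator/patch-size consistency"
        )
    if lam:
        cost += lam * _bending_value_grad(ctrl)[0]
    trace = [cost]
    step = opt.step_init
    for _it in range(opt.max_iter_per_level):
        g = prob.fd_gradient(ctrl, aux, opt.fd_step_px)
        if lam:
            g = g + lam * _bending_value_grad(ctrl)[1]
        gmax = float(np.max(np.abs(g)))
        if gmax == 0:
            break
        # normalize so `step` is the largest control-point motion in pixels;
        # keeps the line search scale-free across similarity metrics
        direction = g / gmax
        slope = float(np.sum(g * direction))
        accepted = False
        for _bt in range(opt.max_backtracks):
            trial = ctrl - step * direction
            c_t = total(trial)
            if c_t <= cost - 1e-4 * step * slope:
                accepted = True
                break
            step *= opt.step_shrink
        if not accepted:
            break
        rel = (cost - c_t) / max(abs(cost), 1e-12)
        ctrl = trial
        cost, aux = prob.state(ctrl)
        if lam:
            cost += lam * _bending_value_grad(ctrl)[0]
        trace.append(cost)
        step = min(step * 2.0, opt.step_max)
        if rel < opt.tol_rel:
            break
    return ctrl, trace


def _level_schedule(levels: int, base_spacing: float):
    """Coarse-to-fine (smoothing sigma, FFD grid spacing) per level.

    Coarseness is realized by Gaussian smoothing at native resolution, not
    by decimation: the analysis operators are learned at the native pixel
    scale, and decimating would both invalidate their patch statistics and
    erase the few-pixel-wide vessels that carry the registration signal.
    """
    sched = []
    for i in range(levels):
        sigma = float(2 ** (levels - 2 - i)) if i < levels - 1 else 0.0
        sp = base_spacing * (2.0 if i < levels - 2 else 1.0)
        sched.append((sigma, sp))
    return sched


def _resample_ctrl(ctrl, shape, sp_old, sp_new):
    """Re-express an FFD on a different control spacing (same domain)."""
    t = Transform.bspline(ctrl, shape, sp_old)
    ncy, ncx = ffd_control_shape(shape, sp_new)
    yy, xx = np.meshgrid(np.arange(ncy) * sp_new, np.arange(ncx) * sp_new, indexing="ij")
    pts = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(float)
    return t.displacement_at(pts).T.reshape(2, ncy, ncx)


def _register(
    reference: ImageGrid,
    float_img: ImageGrid,
    metric_builder: Callable[[np.ndarray, np.ndarray], object],
    cfg: RegistrationConfig,
    metadata: dict,
) -> RegistrationResult:
    if reference.spacing != float_img.spacing:
        logger.warning(
            "resampling float image from spacing %s to reference spacing %s",
            float_img.spacing,
            reference.spacing,
        )
        from scipy.ndimage import zoom

        factors = (
            float_img.spacing[0] / reference.spacing[0],
            float_img.spacing[1] / reference.spacing[1],
        )
        float_img = ImageGrid(
            zoom(float_img.pixels, factors, order=1),
            reference.spacing,
            float_img.modality,
            float_img.origin,
        )
    if reference.shape != float_img.shape:
        raise DimensionError(
            f"reference {reference.shape} and float {float_img.shape} shapes differ"
        )

    rng = np.random.default_rng(cfg.seed)
    shape = reference.shape

    ctrl = None
    prev_sp = None
    cost_trace = []
    level_meta = []
    schedule = _level_schedule(cfg.pyramid_levels, cfg.grid_spacing_px)
    for level, (sigma, sp) in enumerate(schedule):
        nu_level = cfg.nu / cfg.nu_anneal ** (len(schedule) - 1 - level)
        ref_px = ndimage.gaussian_filter(reference.pixels, sigma) if sigma else reference.pixels
        flt_px = ndimage.gaussian_filter(float_img.pixels, sigma) if sigma else float_img.pixels
        if cfg.sample_centers.upper() == "GRID":
            centers = _grid_centers(shape, cfg.patch_size, cfg.margin_px)
        else:
            all_c = _grid_centers(shape, cfg.patch_size, cfg.margin_px, stride=1)
            take = min(cfg.n_cost_patches, len(all_c))
            centers = all_c[rng.choice(len(all_c), size=take, replace=False)]
        if cfg.center_energy_quantile > 0 and len(centers):
            en = patches_at(flt_px, centers, cfg.patch_size).std(axis=0)
            keep = en >= np.quantile(en, cfg.center_energy_quantile)
            if keep.sum() >= 8:  # never filter down to a degenerate handful
                centers = centers[keep]
        if len(centers) == 0:
            raise RegistrationError(f"no valid cost centres at level shape {shape}")
        metric = metric_builder(ref_px, flt_px, nu_level)
        prob = _LevelProblem(ref_px, flt_px, centers, cfg.patch_size, sp, metric)
        if ctrl is None:
            ctrl = np.zeros(prob.ctrl_shape)
            if cfg.init_shift_px > 0:
                # deterministic multi-start: seed the coarsest level with the
                # best constant shift on a small 3x3 grid
                d = cfg.init_shift_px
                best = (prob.cost(ctrl), ctrl)
                for dy in (-d, 0.0, d):
                    for dx in (-d, 0.0, d):
                        if dy == 0.0 and dx == 0.0:
                            continue
                        cand = ctrl.copy()
                        cand[0] += dy
                        cand[1] += dx
                        c = prob.cost(cand)
                        if c < best[0]:
                            best = (c, cand)
                ctrl = best[1]
        elif sp != prev_sp:
            ctrl = _resample_ctrl(ctrl, shape, prev_sp, sp)
        # express curvature relative to the finest control spacing so the
        # bending weight means the same thing at every level
        lam = cfg.bending_weight * (cfg.grid_spacing_px / sp) ** 4
        ctrl, trace = _optimize_level(prob, ctrl, cfg.optimizer, lam)
        cost_trace.append(trace)
        level_meta.append(
            {"sigma": sigma, "grid_spacing_px": sp, "n_centers": int(len(centers))}
        )
        prev_sp = sp

    transform = Transform.bspline(ctrl, reference.shape, prev_sp)
    dense = transform.to_dense_field(reference.spacing)
    warped = warp_image(float_img, Transform.from_field(invert_field(dense)))
    # converged: every level stopped on tolerance / zero gradient, not the
    # iteration cap
    converged = all(len(t) - 1 < cfg.optimizer.max_iter_per_level for t in cost_trace)
    metadata = dict(metadata)
    metadata.update(
        {
            "levels": level_meta,
            "config": {
                "grid_spacing_px": cfg.grid_spacing_px,
                "pyramid_levels": cfg.pyramid_levels,
                "patch_size": cfg.patch_size,
                "sample_centers": cfg.sample_centers,
                "nu": cfg.nu,
                "nmi_bins": cfg.nmi_bins,
                "seed": cfg.seed,
            },
            "point_mapping": "transform maps float-frame pixel x to reference frame "
            "x + d(x); warped_float resamples the float through the numerical "
            "inverse of d",
        }
    )
    return RegistrationResult(transform, warped, cost_trace, converged, metadata)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def coupled_cost(
    reference: ImageGrid,
    float_img: ImageGrid,
    transform: Transform,
    ops: tuple[AnalysisOperator, AnalysisOperator],
    centers: np.ndarray,
    nu: float = 1e3,
) -> float:
    """Mean joint co-sparsity of (float on-grid, reference off-grid) patches.

    ``ops`` is ``(op_float, op_ref)``; patches are zero-mean normalized as
    in training. Centres whose transformed window exits the reference
    domain are dropped (logged) and the mean renormalized.
    """
    op_f, op_r = ops
    if op_f.n != op_r.n:
        raise DimensionError("operators disagree on patch dimension")
    patch_size = int(round(np.sqrt(op_f.n)))
    if patch_size**2 != op_f.n:
        raise ValidationError("operator column count is not a square patch size")
    centers = np.atleast_2d(np.asarray(centers, float))
    metric = _JacsmMetric(op_f, op_r, nu)
    metric.prepare(patches_at(float_img.pixels, centers, patch_size))
    disp = transform.displacement_at(centers)
    tc = centers + disp
    h, w = reference.shape
    half = patch_size // 2
    valid = (
        (tc[:, 0] >= half)
        & (tc[:, 0] <= h - 1 - half)
        & (tc[:, 1] >= half)
        & (tc[:, 1] <= w - 1 - half)
    )
    n_drop = int((~valid).sum())
    if n_drop:
        logger.info("coupled_cost: dropped %d/%d centres out of domain", n_drop, len(tc))
    patches, _ = (
        patches_at(reference.pixels, np.clip(tc, [0, 0], [h - 1, w - 1]), patch_size),
        valid,
    )
    cost, _aux = metric.evaluate(patches, valid)
    return cost


def nmi_metric(
    a: ImageGrid, b: ImageGrid, bins: int = 32, mask: Optional[np.ndarray] = None
) -> float:
    """Normalized mutual information ``(H(A) + H(B)) / H(A, B)`` in [1, 2].

    Bin edges span each image's own min..max. Two constant images return
    2.0; a single constant image is degenerate (NMI = 1) and is flagged
    with a warning.
    """
    if a.shape != b.shape:
        raise DimensionError("images must share a shape")
    if bins < 8:
        raise ValidationError("bins must be >= 8")
    av = a.pixels[mask] if mask is not None else a.pixels.ravel()
    bv = b.pixels[mask] if mask is not None else b.pixels.ravel()
    const_a = np.ptp(av) == 0
    const_b = np.ptp(bv) == 0
    if const_a and const_b:
        return 2.0
    if const_a or const_b:
        import warnings

        warnings.warn("NMI of a constant image is degenerate (returns 1.0)", stacklevel=2)
        return 1.0
    H, _, _ = np.histogram2d(av, bv, bins=bins)
    pxy = H / H.sum()

    def ent(p):
        p = p[p > 0]
        return float(-np.sum(p * np.log(p)))

    return (ent(pxy.sum(axis=1)) + ent(pxy.sum(axis=0))) / ent(pxy.ravel())


def register_jacsm(
    reference: ImageGrid,
    float_img: ImageGrid,
    ops: tuple[AnalysisOperator, AnalysisOperator],
    reg_cfg: Optional[RegistrationConfig] = None,
) -> RegistrationResult:
    """Register ``float_img`` to ``reference`` with fixed learned operators.

    ``ops`` is ``(op_float, op_ref)`` — e.g. ``(Omega_PA, Omega_MR)`` when a
    deformed PA image is registered to an MR reference.
    """
    cfg = reg_cfg or RegistrationConfig()
    op_f, op_r = ops
    if op_f.n != op_r.n or op_f.n != cfg.patch_size**2:
        raise DimensionError(
            f"operator patch dimension {op_f.n} != patch_size**2 = {cfg.patch_size ** 2}"
        )

    def build(ref_px, flt_px, nu_level):
        return _JacsmMetric(op_f, op_r, nu_level)

    meta = {
        "method": "JACSM",
        "operator_hashes": [
            hashlib.sha256(np.ascontiguousarray(op.omega)).hexdigest()[:16]
            for op in ops
        ],
    }
    return _register(reference, float_img, build, cfg, meta)


def register_nmi(
    reference: ImageGrid,
    float_img: ImageGrid,
    reg_cfg: Optional[RegistrationConfig] = None,
) -> RegistrationResult:
    """NMI baseline: identical transform model, pyramid and optimizer as
    :func:`register_jacsm`; only the similarity term differs."""
    cfg = reg_cfg or RegistrationConfig()

    def build(ref_px, flt_px, nu_level):
        return _NmiMetric(
            cfg.nmi_bins,
            (float(flt_px.min()), float(flt_px.max())),
            (float(ref_px.min()), float(ref_px.max())),
        )

    return _register(reference, float_img, build, cfg, {"method": "NMI"})
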