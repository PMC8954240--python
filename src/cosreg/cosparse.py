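"""Joint co-sparse analysis model: penalties, objective, and ADMM learning.

The analysis (co-sparse) model assumes that for a signal ``x`` there is an
over-complete analysis operator ``Omega`` (k x n, k > n, unit-norm rows)
whose response ``Omega x`` is sparse: the *zero* responses (the co-support)
encode the low-dimensional subspace the signal lives in. For a pair of
modalities, a joint model couples two operators through a shared sparsity
pattern of the stacked responses.

Learning minimizes, over the oblique manifold (unit Euclidean row norms),

    (1/N) sum_i g(Omega_a x_a,i, Omega_b x_b,i)
        + kappa * [h(Omega_a) + h(Omega_b)] + mu * [r(Omega_a) + r(Omega_b)]

where ``g`` is the joint log-square sparsity surrogate
``sum_k log(1 + nu (a_k + b_k)^2)`` — the response of the concatenated
operator ``[Omega_a | Omega_b]`` to the stacked signal — ``h`` is a
log-determinant full-rank
penalty and ``r`` a pairwise-row coherence penalty. The penalties are added
(they diverge for degenerate operators, so subtracting them would reward
degeneracy). The solver is an ADMM on the splitting ``Y = [Omega_a X_a;
Omega_b X_b]`` with a proximal update for the coefficient block, a
penalized least-squares descent with row retraction for the operator
block, and a scaled dual ascent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .imaging import DimensionError, ValidationError
from .patches import Normalization, PatchEnsemblePair

logger = logging.getLogger("cosreg")

_UNIT_ROW_TOL = 1e-8


class ADMMDivergenceError(RuntimeError):
    def __init__(self, message: str, state: "ADMMState"):
        super().__init__(message)
        self.state = state


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class AnalysisOperator:
    """k x n analysis operator with unit Euclidean row norms, k > n."""

    omega: np.ndarray
    modality: str = "OTHER"

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, float)
        if self.omega.ndim != 2:
            raise DimensionError("omega must be a 2D matrix")
        norms = np.linalg.norm(self.omega, axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_ROW_TOL):
            raise ValidationError(
                f"rows must have unit norm (max deviation {np.max(np.abs(norms - 1)):.2e})"
            )

    @property
    def k(self) -> int:
        return self.omega.shape[0]

    @property
    def n(self) -> int:
        return self.omega.shape[1]


@dataclass
class SparsityConfig:
    """Weights of the learning objective.

    nu : positive weight inside the log-square surrogate (large nu makes the
        surrogate approach the zero norm).
    kappa : weight of the full-rank (log-det) penalty.
    mu : weight of the row-coherence penalty.
    k_rows : operator row count (over-completeness, k_rows > n).
    m_norm : normalizer of the Gram matrix inside ``h``; defaults to k_rows
        (row-averaged Gram).
    zero_tol : threshold under which a response counts as zero (co-support).
    """

    nu: float = 1e3
    kappa: float = 10.0
    mu: float = 0.01
    k_rows: int = 98
    m_norm: Optional[int] = None
    zero_tol: float = 1e-8

    def __post_init__(self) -> None:
        if min(self.nu, self.kappa, self.mu, self.zero_tol) <= 0:
            raise ValidationError("nu, kappa, mu and zero_tol must be positive")
        if self.m_norm is None:
            self.m_norm = self.k_rows


@dataclass
class ADMMConfig:
    rho: float = 0.3
    max_iter: int = 100
    tol_primal: float = 1e-6
    tol_dual: float = 1e-6
    n_inner: int = 5  # operator-block descent steps per outer iteration


@dataclass
class ADMMState:
    """Per-iteration trace of the solver."""

    rho: float
    iterations: int = 0
    converged: bool = False
    objective_trace: list = field(default_factory=list)
    primal_residuals: list = field(default_factory=list)
    dual_residuals: list = field(default_factory=list)
    row_norm_deviation: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# sparsity surrogates, co-support, constraint penalties
# ---------------------------------------------------------------------------


def sparsity_g(alpha: np.ndarray, nu: float) -> float:
    """Log-square sparsity surrogate ``sum_k log(1 + nu * alpha_k^2)``."""
    alpha = np.asarray(alpha, float)
    return float(np.sum(np.log1p(nu * alpha**2)))


def joint_sparsity_g(alpha_a: np.ndarray, alpha_b: np.ndarray, nu: float) -> float:
    """Coupled surrogate ``sum_k log(1 + nu (a_k + b_k)^2)``.

    The two analyzed vectors are stacked additively row by row (rows of the
    two operators are paired by index), which is the response of the
    concatenated operator ``[Omega_a | Omega_b]`` to the stacked signal
    ``[x_a; x_b]``. Joint co-sparsity therefore rewards a *common* sparse
    component the two modalities share (responses cancelling at
    alignment); zeroing one modality's patch does not lower the surrogate,
    which is what makes the registration cost collapse-free. Symmetric in
    its arguments; reduces to :func:`sparsity_g` when one argument is zero.
    """
    a = np.asarray(alpha_a, float)
    b = np.asarray(alpha_b, float)
    if a.shape != b.shape:
        raise DimensionError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sum(np.log1p(nu * (a + b) ** 2)))


def cosupport(omega: AnalysisOperator, x: np.ndarray, zero_tol: float = 1e-8) -> np.ndarray:
    """Indices ``j`` with ``|(Omega x)_j| <= zero_tol`` (sorted, 0-based)."""
    x = np.asarray(x, float)
    if x.shape[0] != omega.n:
        raise DimensionError(f"dim(x)={x.shape[0]} != n={omega.n}")
    return np.flatnonzero(np.abs(omega.omega @ x) <= zero_tol)


def rank_penalty_h(omega: AnalysisOperator, m_norm: Optional[int] = None) -> float:
    """Full-rank penalty ``-(1/(n log n)) log det((1/m) Omega^T Omega)``.

    Computed from the eigenvalues of the Gram matrix (numerically stable);
    returns ``+inf`` with a warning when the operator is rank deficient.
    """
    W = omega.omega
    n = omega.n
    m = omega.k if m_norm is None else m_norm
    eig = np.linalg.eigvalsh(W.T @ W)
    if eig[0] <= 0:
        warnings.warn("rank-deficient operator: h = +inf", stacklevel=2)
        return float("inf")
    logdet = float(np.sum(np.log(eig))) - n * np.log(m)
    return -logdet / (n * np.log(n))


def coherence_penalty_r(omega: AnalysisOperator) -> float:
    """Row-coherence penalty ``-sum_{k<l} log(1 - (Omega_k . Omega_l)^2)``.

    Finite iff no two rows are parallel or antiparallel; the offending pair
    is logged when infinite.
    """
    W = omega.omega
    C = W @ W.T
    iu = np.triu_indices(omega.k, k=1)
    c2 = C[iu] ** 2
    bad = c2 >= 1.0
    if np.any(bad):
        i = int(np.argmax(bad))
        logger.warning(
            "parallel rows (%d, %d): coherence penalty is +inf", iu[0][i], iu[1][i]
        )
        return float("inf")
    return float(-np.sum(np.log(1.0 - c2)))


def _joint_g_columns(A: np.ndarray, B: np.ndarray, nu: float) -> np.ndarray:
    """Per-column joint surrogate of two (k, N) response matrices."""
    return np.sum(np.log1p(nu * (A + B) ** 2), axis=0)


def mean_joint_sparsity(
    op_a: AnalysisOperator, op_b: AnalysisOperator, X_a: np.ndarray, X_b: np.ndarray, nu: float
) -> float:
    """Mean joint co-sparsity surrogate over an ensemble (the data term)."""
    return float(np.mean(_joint_g_columns(op_a.omega @ X_a, op_b.omega @ X_b, nu)))


def learning_objective(
    pair: tuple[AnalysisOperator, AnalysisOperator],
    ensembles: PatchEnsemblePair,
    cfg: SparsityConfig,
) -> float:
    """Full learning objective: data term plus weighted h and r penalties."""
    op_a, op_b = pair
    if op_a.n != ensembles.n or op_b.n != ensembles.n:
        raise DimensionError(
            f"operator n ({op_a.n}, {op_b.n}) != ensemble patch dim {ensembles.n}"
        )
    data = mean_joint_sparsity(op_a, op_b, ensembles.X_a, ensembles.X_b, cfg.nu)
    pen_h = rank_penalty_h(op_a, cfg.m_norm) + rank_penalty_h(op_b, cfg.m_norm)
    pen_r = coherence_penalty_r(op_a) + coherence_penalty_r(op_b)
    return data + cfg.kappa * pen_h + cfg.mu * pen_r


# ---------------------------------------------------------------------------
# ADMM solver
# ---------------------------------------------------------------------------


def _normalize_rows(W: np.ndarray) -> np.ndarray:
    return W / np.linalg.norm(W, axis=1, keepdims=True)


def _joint_prox(S: np.ndarray, nu: float, rho: float, a_w: float, tol: float = 1e-10,
                max_newton: int = 60) -> np.ndarray:
    """Proximal map of the log-square surrogate (1-D magnitude form).

    Solves, elementwise for the magnitude ``t >= 0``,

        min_t  a_w * log(1 + nu t^2) + (rho/2) (t - s)^2

    The surrogate is even, so the prox of a signed input is the signed
    solution for its magnitude; ``S`` holds input magnitudes. Safeguarded
    Newton on the stationarity condition, bracketed in ``[0, s]``.
    """
    S = np.asarray(S, float)
    lo = np.zeros_like(S)
    hi = S.copy()
    t = S.copy()

    def fprime(t):
        return 2.0 * a_w * nu * t / (1.0 + nu * t**2) + rho * (t - S)

    for _ in range(max_newton):
        f = fprime(t)
        # maintain the bracket: root has f(lo) <= 0 <= f(hi)
        neg = f < 0
        lo = np.where(neg, t, lo)
        hi = np.where(neg, hi, t)
        d = 1.0 + nu * t**2
        f2 = 2.0 * a_w * nu * (1.0 - nu * t**2) / d**2 + rho
        with np.errstate(divide="ignore", invalid="ignore"):
            t_new = t - f / f2
        bad = ~np.isfinite(t_new) | (t_new <= lo) | (t_new >= hi) | (f2 <= 0)
        t_new = np.where(bad, 0.5 * (lo + hi), t_new)
        if np.max(np.abs(t_new - t)) < tol:
            t = t_new
            break
        t = t_new
    return t


def _omega_penalty_value_grad(
    W: np.ndarray, kappa: float, mu: float, m_norm: int
) -> tuple[float, np.ndarray]:
    """Value and gradient of ``kappa*h(W) + mu*r(W)`` (unit rows assumed)."""
    n = W.shape[1]
    G = W.T @ W
    eig = np.linalg.eigvalsh(G)
    if eig[0] <= 1e-14:
        return float("inf"), np.zeros_like(W)
    c_n = 1.0 / (n * np.log(n))
    h_val = -c_n * (float(np.sum(np.log(eig))) - n * np.log(m_norm))
    h_grad = -c_n * 2.0 * (W @ np.linalg.inv(G))

    C = W @ W.T
    np.fill_diagonal(C, 0.0)
    one_minus = 1.0 - C**2
    if np.any(one_minus[~np.eye(len(C), dtype=bool)] <= 0):
        return float("inf"), np.zeros_like(W)
    iu = np.triu_indices(len(C), k=1)
    r_val = float(-np.sum(np.log(one_minus[iu])))
    B = 2.0 * C / one_minus
    r_grad = B @ W

    return kappa * h_val + mu * r_val, kappa * h_grad + mu * r_grad


def _omega_block_value(W, X, M, rho, kappa, mu, m_norm):
    R = W @ X - M
    pen, _ = _omega_penalty_value_grad(W, kappa, mu, m_norm)
    return 0.5 * rho * float(np.sum(R * R)) + pen


def _update_omega(W, X, M, rho, kappa, mu, m_norm, n_inner, step):
    """A few retracted gradient-descent steps on the operator sub-problem.

    Each accepted step is followed by retraction of every row to unit norm
    (projection onto the oblique manifold); backtracking guarantees the
    block objective does not increase.
    """
    val = _omega_block_value(W, X, M, rho, kappa, mu, m_norm)
    for _ in range(n_inner):
        R = W @ X - M
        pen, pen_grad = _omega_penalty_value_grad(W, kappa, mu, m_norm)
        grad = rho * (R @ X.T) + pen_grad
        gn2 = float(np.sum(grad * grad))
        if gn2 == 0:
            break
        accepted = False
        for _bt in range(30):
            W_try = _normalize_rows(W - step * grad)
            v_try = _omega_block_value(W_try, X, M, rho, kappa, mu, m_norm)
            if v_try < val:
                W, val = W_try, v_try
                step *= 1.5
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
    return W, step


def learn_operators(
    ensembles: PatchEnsemblePair,
    cfg: Optional[SparsityConfig] = None,
    admm: Optional[ADMMConfig] = None,
    seed: int = 0,
) -> tuple[AnalysisOperator, AnalysisOperator, ADMMState]:
    """Learn a pair of analysis operators by ADMM.

    The pair is initialized from a single seeded random unit-row draw, with
    the sign of the second operator chosen to minimize the initial joint
    data term (see the inline note). Returns the two operators and the
    full solver trace.
    """
    cfg = cfg or SparsityConfig()
    admm = admm or ADMMConfig()
    n = ensembles.n
    if cfg.k_rows <= n:
        raise ValidationError(f"k_rows must exceed patch dimension n={n}")
    X_a, X_b = ensembles.X_a, ensembles.X_b
    N = ensembles.count
    rho, nu = admm.rho, cfg.nu
    a_w = 1.0 / N

    rng = np.random.default_rng(seed)
    W0 = _normalize_rows(rng.standard_normal((cfg.k_rows, n)))
    # Both operators start from one seeded draw, up to sign: the stacked
    # response is then W0 (x_a + x_b) or W0 (x_a - x_b). Pick the
    # orientation with the smaller initial data term — for identical (or
    # positively correlated) ensembles that is the antisymmetric pair,
    # whose cancellation at alignment is exact and is preserved by the
    # symmetric update dynamics; for anticorrelated modality pairs the
    # symmetric orientation starts nearer the cancelling solution.
    g_sym = float(np.mean(_joint_g_columns(W0 @ X_a, W0 @ X_b, nu)))
    g_anti = float(np.mean(_joint_g_columns(W0 @ X_a, -(W0 @ X_b), nu)))
    sign = 1.0 if g_sym < g_anti else -1.0
    Wa, Wb = W0.copy(), sign * W0.copy()

    Ya, Yb = Wa @ X_a, Wb @ X_b
    La = np.zeros_like(Ya)
    Lb = np.zeros_like(Yb)

    state = ADMMState(rho=rho)
    step_a = step_b = 1e-3
    scale = np.sqrt(Ya.size + Yb.size)

    def record_objective(Wa, Wb):
        pen_a, _ = _omega_penalty_value_grad(Wa, cfg.kappa, cfg.mu, cfg.m_norm)
        pen_b, _ = _omega_penalty_value_grad(Wb, cfg.kappa, cfg.mu, cfg.m_norm)
        data = float(np.mean(_joint_g_columns(Wa @ X_a, Wb @ X_b, nu)))
        return data + pen_a + pen_b

    state.objective_trace.append(record_objective(Wa, Wb))
    for it in range(admm.max_iter):
        # --- y-block: separable prox of the joint surrogate -----------------
        # g depends on the pair only through the sum c = u + v, so the 2-D
        # prox reduces to a 1-D prox on c (effective penalty rho/2) followed
        # by an equal split of the correction between the two blocks.
        Pa = Wa @ X_a + La / rho
        Pb = Wb @ X_b + Lb / rho
        s0 = Pa + Pb
        T = _joint_prox(np.abs(s0), nu, rho / 2.0, a_w)
        shift = (np.sign(s0) * T - s0) / 2.0
        Ya_new, Yb_new = Pa + shift, Pb + shift

        # --- x-block: penalized least squares + oblique retraction ----------
        Ma = Ya_new - La / rho
        Mb = Yb_new - Lb / rho
        Wa_new, step_a = _update_omega(
            Wa, X_a, Ma, rho, cfg.kappa, cfg.mu, cfg.m_norm, admm.n_inner, step_a
        )
        Wb_new, step_b = _update_omega(
            Wb, X_b, Mb, rho, cfg.kappa, cfg.mu, cfg.m_norm, admm.n_inner, step_b
        )
        # monotone safeguard: the block update minimizes the augmented
        # Lagrangian, which near convergence can nudge the true objective
        # up by a hair; keep the previous operators in that case
        obj_new = record_objective(Wa_new, Wb_new)
        if obj_new <= state.objective_trace[-1]:
            Wa, Wb = Wa_new, Wb_new
        else:
            obj_new = state.objective_trace[-1]

        # --- dual ascent -----------------------------------------------------
        Ra = Wa @ X_a - Ya_new
        Rb = Wb @ X_b - Yb_new
        La = La + rho * Ra
        Lb = Lb + rho * Rb

        primal = float(np.sqrt(np.sum(Ra**2) + np.sum(Rb**2))) / scale
        dual = (
            rho
            * float(np.sqrt(np.sum((Ya_new - Ya) ** 2) + np.sum((Yb_new - Yb) ** 2)))
            / scale
        )
        Ya, Yb = Ya_new, Yb_new

        state.iterations = it + 1
        state.primal_residuals.append(primal)
        state.dual_residuals.append(dual)
        dev = max(
            float(np.max(np.abs(np.linalg.norm(Wa, axis=1) - 1.0))),
            float(np.max(np.abs(np.linalg.norm(Wb, axis=1) - 1.0))),
        )
        state.row_norm_deviation.append(dev)
        state.objective_trace.append(obj_new)

        if not np.isfinite(primal) or (
            it >= 20 and primal > 10.0 * state.primal_residuals[it - 20]
        ):
            raise ADMMDivergenceError(
                f"ADMM diverged at iteration {it + 1} (primal residual {primal:.3e})",
                state,
            )
        if primal < admm.tol_primal and dual < admm.tol_dual:
            state.converged = True
            break

    op_a = AnalysisOperator(_normalize_rows(Wa), "A")
    op_b = AnalysisOperator(_normalize_rows(Wb), "B")
    return op_a, op_b, state
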