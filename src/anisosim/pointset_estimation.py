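"""Least-squares transform estimation between paired, weighted 3D point sets.

Given paired points ``x_i ↦ y_i`` with nonnegative weights ``w_i``, every
fitter minimizes the weighted sum of squared residuals

    C(A, t) = Σ_i w_i ‖y_i − (A x_i + t)‖²         [mm²]

over its transform class.  The optimal translation is always
``t̂ = ȳ − Â x̄`` (weighted barycenters), so the problem reduces to the
linear part acting on barycentric coordinates.

Affine, rigid and similarity estimates are closed form (the rotation via the
classical unit-quaternion eigenvector method).  The anisotropic similarity
``A = R·diag(S)·Uᵀ`` with fixed frame ``U`` has no closed form; it is solved
by an alternating scheme in quaternion form.  Writing ``x̃_i = Uᵀ x′_i`` and
``ξ_i = diag(S) x̃_i``, the criterion becomes the quadratic form

    C̃(q, S) = qᵀ B q,   B = Σ_i w_i · (−(Q_{y′_i} + P_{ξ_i})²)

with ``Q, P`` the matricial quaternions.  Each sweep:

  (a) rotation step — with ``S`` fixed, ``q̂`` is the unit eigenvector of the
      smallest eigenvalue of ``B``;
  (b) scaling step — with ``q̂`` fixed,
      ``ŝ_j = [Σ_i w_i x̃²_ji]⁻¹ · q̂ᵀ (Σ_i w_i Q_{y′_i} ∂P_{ξ_i}/∂s_j) q̂``,
      where ``∂P_{ξ_i}/∂s_j = P_{x̃_ji e_j}`` by linearity of ``P`` in its
      (pure-quaternion) argument.

Each step is the exact minimizer of its sub-problem, so the cost is
non-increasing across sweeps.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np

from .transform_core import (
    AnisoSimDecomposition,
    LinearTransform3D,
    ScalingFrame,
    UnitQuaternion,
    canonical_quat,
    quat_matrices,
    quat_to_rotation,
    rotation_to_quat,
)

__all__ = [
    "DegeneratePointSetError",
    "DegenerateDirectionError",
    "IllPosedFitError",
    "PairedPointSet",
    "FitReport",
    "cost",
    "optimal_translation",
    "fit_affine",
    "fit_rigid",
    "fit_similarity",
    "fit_anisotropic_similarity",
    "scaling_derivative_matrix",
    "load_paired_points",
    "save_paired_points",
]


class DegeneratePointSetError(ValueError):
    """Point geometry too degenerate for the requested transform class."""


class DegenerateDirectionError(DegeneratePointSetError):
    """No spread along one of the constrained scaling directions."""

    def __init__(self, direction: int):
        self.direction = direction
        super().__init__(
            f"zero weighted spread along scaling direction {direction + 1}; "
            "the scaling factor there is unidentifiable"
        )


class IllPosedFitError(ValueError):
    """The alternating scheme produced a non-positive scaling estimate."""


@dataclass(frozen=True)
class PairedPointSet:
    """Paired 3D points ``x_i ↦ y_i`` with nonnegative weights (default 1)."""

    x: np.ndarray
    y: np.ndarray
    w: Optional[np.ndarray] = None

    def __post_init__(self):
        x = np.atleast_2d(np.asarray(self.x, dtype=float))
        y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if x.shape != y.shape or x.shape[1] != 3:
            raise ValueError("x and y must be matching (M, 3) arrays")
        w = self.w
        if w is None:
            w = np.ones(len(x))
        w = np.asarray(w, dtype=float).reshape(-1)
        if w.shape != (len(x),):
            raise ValueError("weights must match the number of pairs")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be nonnegative with at least one > 0")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "w", w)

    def __len__(self) -> int:
        return len(self.x)

    @property
    def barycenters(self) -> Tuple[np.ndarray, np.ndarray]:
        """Weighted barycenters ``(x̄, ȳ)``."""
        wsum = self.w.sum()
        return self.w @ self.x / wsum, self.w @ self.y / wsum

    @property
    def centered(self) -> Tuple[np.ndarray, np.ndarray]:
        """Barycentric coordinates ``(x′, y′)``."""
        xb, yb = self.barycenters
        return self.x - xb, self.y - yb


@dataclass
class FitReport:
    """Result of a point-set fit: transform, cost and convergence diagnostics."""

    transform: LinearTransform3D
    final_cost: float
    n_iterations: int = 0
    converged: bool = True
    decomposition: Optional[AnisoSimDecomposition] = None
    quaternion: Optional[UnitQuaternion] = None
    cost_trace: List[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Criterion and translation
# ---------------------------------------------------------------------------

def cost(pts: PairedPointSet, T: LinearTransform3D) -> float:
    """Weighted sum of squared residuals ``Σ_i w_i ‖y_i − (A x_i + t)‖²``."""
    r = pts.y - T.apply(pts.x)
    return float(pts.w @ np.einsum("ij,ij->i", r, r))


def optimal_translation(A: np.ndarray, pts: PairedPointSet) -> np.ndarray:
    """``t̂ = ȳ − A x̄`` with weighted barycenters."""
    xb, yb = pts.barycenters
    return yb - np.asarray(A, dtype=float) @ xb


def _require_pairs(pts: PairedPointSet, m_min: int, what: str) -> None:
    if len(pts) < m_min:
        raise DegeneratePointSetError(
            f"{what} needs at least {m_min} point pairs, got {len(pts)}"
        )


# ---------------------------------------------------------------------------
# Closed-form fitters
# ---------------------------------------------------------------------------

def fit_affine(pts: PairedPointSet) -> FitReport:
    """Unconstrained 12-dof weighted least squares (closed form)."""
    _require_pairs(pts, 4, "affine fit")
    xp, yp = pts.centered
    w = pts.w
    Cxx = (xp * w[:, None]).T @ xp
    if np.linalg.cond(Cxx) > 1e12:
        raise DegeneratePointSetError(
            "points are (nearly) coplanar; affine fit is rank-deficient"
        )
    Cyx = (yp * w[:, None]).T @ xp
    A = Cyx @ np.linalg.inv(Cxx)
    T = LinearTransform3D(A, optimal_translation(A, pts), kind="affine")
    return FitReport(transform=T, final_cost=cost(pts, T))


def _stacked_quat_matrices(v: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized ``quat_matrices`` for an (M, 3) array of pure quaternions."""
    M = len(v)
    a, b, c = v[:, 0], v[:, 1], v[:, 2]
    z = np.zeros(M)
    Q = np.empty((M, 4, 4))
    P = np.empty((M, 4, 4))
    Q[:, 0] = np.stack([z, -a, -b, -c], axis=1)
    Q[:, 1] = np.stack([a, z, -c, b], axis=1)
    Q[:, 2] = np.stack([b, c, z, -a], axis=1)
    Q[:, 3] = np.stack([c, -b, a, z], axis=1)
    P[:, 0] = np.stack([z, a, b, c], axis=1)
    P[:, 1] = np.stack([-a, z, -c, b], axis=1)
    P[:, 2] = np.stack([-b, c, z, -a], axis=1)
    P[:, 3] = np.stack([-c, -b, a, z], axis=1)
    return Q, P


def _rotation_quaternion(
    B: np.ndarray, previous: Optional[np.ndarray] = None
) -> np.ndarray:
    """Unit eigenvector of B's smallest eigenvalue, with continuity tie-break."""
    evals, evecs = np.linalg.eigh(B)
    q = evecs[:, 0]
    scale = np.linalg.norm(B)
    if previous is not None and evals[1] - evals[0] < 1e-10 * max(scale, 1.0):
        # near-degenerate pair: pick the eigenvector closest to the last iterate
        dots = np.abs(evecs[:, :2].T @ previous)
        q = evecs[:, int(np.argmax(dots))]
    if previous is not None and q @ previous < 0:
        q = -q
    return canonical_quat(q)


def fit_rigid(pts: PairedPointSet) -> FitReport:
    """6-dof weighted least squares via the quaternion eigenvector method."""
    _require_pairs(pts, 3, "rigid fit")
    xp, yp = pts.centered
    if np.linalg.matrix_rank((xp * pts.w[:, None]).T @ xp, tol=1e-9) < 2:
        raise DegeneratePointSetError("points are (nearly) collinear; rotation is unidentifiable")
    Qy, _ = _stacked_quat_matrices(yp)
    _, Px = _stacked_quat_matrices(xp)
    Ssum = Qy + Px
    B = -np.einsum("i,ijk,ikl->jl", pts.w, Ssum, Ssum)
    q = _rotation_quaternion(B)
    R = quat_to_rotation(q)
    T = LinearTransform3D(R, optimal_translation(R, pts), kind="rigid")
    return FitReport(
        transform=T, final_cost=cost(pts, T), quaternion=UnitQuaternion(q)
    )


def fit_similarity(pts: PairedPointSet) -> FitReport:
    """7-dof fit: the rigid rotation plus the optimal single scale.

    The optimal rotation does not depend on a positive isotropic scale, so it
    equals the rigid one; the scale is then the 1-D least-squares slope
    ``s = Σ w y′·(R x′) / Σ w ‖x′‖²``.
    """
    rep = fit_rigid(pts)
    R = rep.transform.matrix
    xp, yp = pts.centered
    w = pts.w
    denom = float(w @ np.einsum("ij,ij->i", xp, xp))
    if denom <= 0:
        raise DegeneratePointSetError("zero spread; scale is unidentifiable")
    s = float(w @ np.einsum("ij,ij->i", yp, xp @ R.T)) / denom
    if s <= 0:
        raise IllPosedFitError("optimal similarity scale is non-positive")
    A = s * R
    T = LinearTransform3D(A, optimal_translation(A, pts), kind="similarity")
    return FitReport(
        transform=T, final_cost=cost(pts, T), quaternion=rep.quaternion
    )


# ---------------------------------------------------------------------------
# Anisotropic similarity: alternating quaternion scheme
# ---------------------------------------------------------------------------

def scaling_derivative_matrix(x_tilde: np.ndarray, j: int) -> np.ndarray:
    """``∂P_{ξ}/∂s_j`` for ``ξ = diag(S) x̃`` — sparse, symmetric placement.

    ``ξ`` depends on ``s_j`` only through its ``j``-th component, and ``P`` is
    linear in its argument, so the derivative is ``P`` of the pure quaternion
    ``x̃_j e_j``.  (Locked against finite differences in the test suite.)
    """
    e = np.zeros(3)
    e[j] = x_tilde[j]
    _, P = quat_matrices(np.concatenate([[0.0], e]))
    return P


def _aniso_sweeps(
    pts: PairedPointSet,
    frame: ScalingFrame,
    q0: np.ndarray,
    S0: np.ndarray,
    tol: float,
    max_iter: int,
) -> Tuple[np.ndarray, np.ndarray, List[float], bool, int]:
    """Run alternating (rotation, scaling) sweeps from a given start."""
    xp, yp = pts.centered
    w = pts.w
    xt = xp @ frame.U  # x̃_i = Uᵀ x′_i, rows
    denom = w @ (xt**2)  # Σ_i w_i x̃²_ji per direction j
    for j in range(3):
        if denom[j] <= 1e-12 * max(denom.max(), 1.0):
            raise DegenerateDirectionError(j)

    Qy, _ = _stacked_quat_matrices(yp)
    # scaling-step matrices: Σ_i w_i Q_{y′_i} ∂P_{ξ_i}/∂s_j = (Σ_i w_i x̃_ji Q_{y′_i}) P_{e_j}
    Pe = [quat_matrices(np.array([0.0, *e]))[1] for e in np.eye(3)]
    Cj = [
        np.einsum("i,ijk->jk", w * xt[:, j], Qy) @ Pe[j] for j in range(3)
    ]

    def eval_cost(q: np.ndarray, S: np.ndarray) -> float:
        A = quat_to_rotation(q) @ np.diag(S) @ frame.U.T
        r = yp - xp @ A.T
        return float(w @ np.einsum("ij,ij->i", r, r))

    q, S = q0.copy(), S0.copy()
    trace = [eval_cost(q, S)]
    converged = False
    sweeps = 0
    for sweeps in range(1, max_iter + 1):
        # (a) rotation step
        xi = xt * S  # ξ_i rows
        _, Pxi = _stacked_quat_matrices(xi)
        Ssum = Qy + Pxi
        B = -np.einsum("i,ijk,ikl->jl", w, Ssum, Ssum)
        q = _rotation_quaternion(B, previous=q)
        # (b) scaling step
        S_new = np.array([q @ Cj[j] @ q / denom[j] for j in range(3)])
        if np.any(S_new <= 0):
            raise IllPosedFitError(
                f"non-positive scaling estimate {S_new}; data do not support a "
                "positive anisotropic similarity in this frame"
            )
        S = S_new
        c = eval_cost(q, S)
        trace.append(c)
        prev = trace[-2]
        # relative-change test with an absolute floor: once the cost is at
        # rounding level w.r.t. the initial cost, further sweeps only churn
        floor = 1e-17 * max(trace[0], 1.0)
        if abs(prev - c) <= tol * max(prev, 1e-300) or c <= floor:
            converged = True
            break
    return q, S, trace, converged, sweeps


def fit_anisotropic_similarity(
    pts: PairedPointSet,
    frame: Union[ScalingFrame, np.ndarray],
    tol: float = 1e-8,
    max_iter: int = 100,
    S_init: Optional[np.ndarray] = None,
) -> FitReport:
    """9-dof fit ``A = R·diag(S)·Uᵀ`` with fixed scaling frame ``U``.

    Alternates exact rotation and scaling updates (module docstring) until the
    relative cost change drops below ``tol`` or ``max_iter`` sweeps.  By
    default two warm starts are tried — identity scaling with the rigid-fit
    rotation, and the similarity fit re-expressed in the frame — and the
    lower-cost run is returned; this keeps the fit at least as good as the
    similarity one (the class is nested) without a global search.  Passing
    ``S_init`` forces a single run from that scaling.
    """
    if not isinstance(frame, ScalingFrame):
        frame = ScalingFrame(frame)
    _require_pairs(pts, 4, "anisotropic similarity fit")

    starts: List[Tuple[np.ndarray, np.ndarray]] = []
    q_rigid = fit_rigid(pts).quaternion.q
    if S_init is not None:
        S0 = np.asarray(S_init, dtype=float).reshape(3)
        if np.any(S0 <= 0):
            raise ValueError("S_init must be positive")
        starts.append((q_rigid, S0))
    else:
        starts.append((q_rigid, np.ones(3)))
        try:
            sim = fit_similarity(pts)
            s = float(np.linalg.norm(sim.transform.matrix[:, 0]))
            # s·R_sim = (R_sim U)·(s I)·Uᵀ — same transform, frame form
            starts.append(
                (rotation_to_quat(quat_to_rotation(sim.quaternion.q) @ frame.U).q,
                 np.full(3, s))
            )
        except (DegeneratePointSetError, IllPosedFitError):
            pass

    best = None
    for q0, S0 in starts:
        q, S, trace, converged, sweeps = _aniso_sweeps(
            pts, frame, q0, S0, tol, max_iter
        )
        if best is None or trace[-1] < best[2][-1]:
            best = (q, S, trace, converged, sweeps)

    q, S, trace, converged, sweeps = best
    R = quat_to_rotation(q)
    A = R @ np.diag(S) @ frame.U.T
    t = optimal_translation(A, pts)
    T = LinearTransform3D(A, t, kind="anisotropic_similarity")
    dec = AnisoSimDecomposition(R=R, S=S, U=frame, t=t)
    return FitReport(
        transform=T,
        final_cost=cost(pts, T),
        n_iterations=sweeps,
        converged=converged,
        decomposition=dec,
        quaternion=UnitQuaternion(q),
        cost_trace=trace,
    )


# ---------------------------------------------------------------------------
# Plain-text point-pair files: "x1 x2 x3 y1 y2 y3 [w]" per row
# ---------------------------------------------------------------------------

def load_paired_points(path) -> PairedPointSet:
    text = Path(path).read_text().replace(",", " ")
    rows = np.loadtxt(io.StringIO(text), ndmin=2)
    if rows.shape[1] == 6:
        return PairedPointSet(rows[:, :3], rows[:, 3:6])
    if rows.shape[1] == 7:
        return PairedPointSet(rows[:, :3], rows[:, 3:6], rows[:, 6])
    raise ValueError("point file rows must be 'x1 x2 x3 y1 y2 y3 [w]'")


def save_paired_points(pts: PairedPointSet, path) -> None:
    np.savetxt(path, np.column_stack([pts.x, pts.y, pts.w]), fmt="%.10g")
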