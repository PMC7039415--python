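"""Linear 3D transforms, constrained scaling decompositions and quaternion algebra.

The central object of the package is the *anisotropic similarity*: an affine
transformation ``y = A x + t`` whose linear part factors as ``A = R S Uᵀ``
where ``U`` is a fixed rotation matrix (its columns are the constrained
scaling directions), ``S`` is a positive diagonal scaling matrix and ``R`` is
a free rotation.  With ``U`` fixed this leaves 9 degrees of freedom (3
rotation, 3 scaling, 3 translation), between the 7-dof similarity
(``S = s·I``) and the 12-dof affine.

All transforms act on world-space coordinates in millimetres and follow the
backward-mapping convention used throughout the package: a transform maps
reference-space coordinates to moving-space coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np

__all__ = [
    "DegenerateTransformError",
    "LinearTransform3D",
    "ScalingFrame",
    "AnisoSimDecomposition",
    "UnitQuaternion",
    "decompose_affine",
    "decompose_with_frame",
    "nearest_similarity",
    "compose",
    "quat_multiply",
    "quat_conjugate",
    "quat_to_rotation",
    "rotation_to_quat",
    "quat_matrices",
    "save_transform",
    "load_transform",
]

_DET_EPS = 1e-12


class DegenerateTransformError(ValueError):
    """Raised when a transform is singular or reflecting where it must not be."""


def _as_matrix(a) -> np.ndarray:
    m = np.asarray(a, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {m.shape}")
    return m


def _as_vector(v) -> np.ndarray:
    t = np.asarray(v, dtype=float).reshape(-1)
    if t.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {t.shape}")
    return t


# ---------------------------------------------------------------------------
# Transform containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearTransform3D:
    """Affine map ``x ↦ matrix @ x + translation`` on world-space mm coordinates."""

    matrix: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    kind: str = "affine"

    def __post_init__(self):
        object.__setattr__(self, "matrix", _as_matrix(self.matrix))
        object.__setattr__(self, "translation", _as_vector(self.translation))

    @classmethod
    def identity(cls, kind: str = "rigid") -> "LinearTransform3D":
        return cls(np.eye(3), np.zeros(3), kind=kind)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) array of points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "LinearTransform3D":
        if abs(np.linalg.det(self.matrix)) <= _DET_EPS:
            raise DegenerateTransformError("transform is singular, cannot invert")
        inv = np.linalg.inv(self.matrix)
        return LinearTransform3D(inv, -inv @ self.translation, kind=self.kind)

    def to_dict(self) -> dict:
        return {
            "matrix": [float(v) for v in self.matrix.ravel()],
            "translation": [float(v) for v in self.translation],
            "frame_U": None,
            "scalings": None,
            "kind": self.kind,
        }


@dataclass(frozen=True)
class ScalingFrame:
    """Rotation matrix whose columns are the three constrained scaling directions."""

    U: np.ndarray

    def __post_init__(self):
        U = _as_matrix(self.U)
        if not np.allclose(U.T @ U, np.eye(3), atol=1e-10):
            raise ValueError("scaling frame must be orthogonal (UᵀU = I)")
        if not np.isclose(np.linalg.det(U), 1.0, atol=1e-10):
            raise ValueError("scaling frame must be a proper rotation (det U = +1)")
        object.__setattr__(self, "U", U)

    @classmethod
    def identity(cls) -> "ScalingFrame":
        return cls(np.eye(3))

    def column(self, j: int) -> np.ndarray:
        return self.U[:, j]


@dataclass(frozen=True)
class AnisoSimDecomposition:
    """Factorization ``A = R·diag(S)·Uᵀ`` plus translation ``t``.

    ``R`` is a free rotation, ``S`` the positive scaling factors along the
    columns of the fixed frame ``U``.
    """

    R: np.ndarray
    S: np.ndarray
    U: ScalingFrame
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = _as_matrix(self.R)
        S = np.asarray(self.S, dtype=float).reshape(-1)
        if S.shape != (3,):
            raise ValueError("S must be a 3-vector of scalings")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-10) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-10
        ):
            raise ValueError("R must be a proper rotation")
        if np.any(S <= 0):
            raise ValueError("scaling factors must be positive")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "t", _as_vector(self.t))

    def to_transform(self) -> LinearTransform3D:
        A = self.R @ np.diag(self.S) @ self.U.U.T
        return LinearTransform3D(A, self.t, kind="anisotropic_similarity")

    def to_dict(self) -> dict:
        d = self.to_transform().to_dict()
        d["frame_U"] = [float(v) for v in self.U.U.ravel()]
        d["scalings"] = [float(v) for v in self.S]
        return d


# ---------------------------------------------------------------------------
# Decompositions and projections
# ---------------------------------------------------------------------------

def decompose_affine(A: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split an invertible matrix into rotation, scalings and scaling frame.

    From the SVD ``A = V D Wᵀ`` the factors ``R = V·det(V)``,
    ``U = W·det(W)`` and ``S = det(V)·det(W)·D`` give ``A = R·diag(S)·Uᵀ``
    with ``R`` and ``U`` proper rotations.  Scalings come out in the SVD's
    descending order; when a caller works in a fixed externally-chosen frame
    it should use :func:`decompose_with_frame` instead, which preserves the
    caller's column order.

    Reflections (``det A ≤ 0``) are rejected: they would force a negative
    scaling factor and never arise in the intended registration setting.
    """
    A = _as_matrix(A)
    det = np.linalg.det(A)
    if abs(det) <= _DET_EPS:
        raise DegenerateTransformError("matrix is singular, cannot decompose")
    if det < 0:
        raise DegenerateTransformError(
            "matrix has negative determinant (reflection); not a valid "
            "anisotropic similarity"
        )
    V, D, Wt = np.linalg.svd(A)
    dV = np.linalg.det(V)
    dW = np.linalg.det(Wt.T)
    R = V * dV
    U = Wt.T * dW
    S = dV * dW * D
    return R, S, U


def decompose_with_frame(
    transform: LinearTransform3D, frame: ScalingFrame, atol: float = 1e-6
) -> AnisoSimDecomposition:
    """Recover ``(R, S)`` of ``A = R·diag(S)·Uᵀ`` for a *given* frame ``U``.

    ``A·U = R·diag(S)`` must have orthogonal columns; the scalings are the
    column norms, reported in the caller's column order.  Raises if ``A`` is
    not an anisotropic similarity w.r.t. ``U`` within ``atol``.
    """
    A = transform.matrix
    if np.linalg.det(A) <= _DET_EPS:
        raise DegenerateTransformError("matrix must have positive determinant")
    M = A @ frame.U  # columns s_j * R e_j
    S = np.linalg.norm(M, axis=0)
    if np.any(S <= 0):
        raise DegenerateTransformError("degenerate scaling along a frame direction")
    R = M / S
    if not np.allclose(R.T @ R, np.eye(3), atol=atol):
        raise DegenerateTransformError(
            "transform is not an anisotropic similarity in the given frame"
        )
    # re-orthonormalize to polish round-off before the strict container checks
    Uq, _, Vtq = np.linalg.svd(R)
    R = Uq @ Vtq
    return AnisoSimDecomposition(R=R, S=S, U=frame, t=transform.translation)


def nearest_similarity(
    A: np.ndarray,
    t: Optional[np.ndarray] = None,
    x_bar: Optional[np.ndarray] = None,
    y_bar: Optional[np.ndarray] = None,
) -> LinearTransform3D:
    """Project an affine onto the similarity group.

    With the SVD ``A = V D Wᵀ``, the nearest similarity has linear part
    ``B = d̄·V·Wᵀ`` where ``d̄`` is the mean singular value, and translation
    ``ȳ − B·x̄`` when point-set barycenters are supplied (otherwise the input
    translation is projected as ``t + (A − B)·x̄`` ≡ ``ȳ − B·x̄``).
    """
    A = _as_matrix(A)
    det = np.linalg.det(A)
    if abs(det) <= _DET_EPS:
        raise DegenerateTransformError("matrix is singular")
    V, D, Wt = np.linalg.svd(A)
    B = D.mean() * (V @ Wt)
    if x_bar is None:
        x_bar = np.zeros(3)
    x_bar = _as_vector(x_bar)
    if y_bar is None:
        t = np.zeros(3) if t is None else _as_vector(t)
        y_bar = A @ x_bar + t
    y_bar = _as_vector(y_bar)
    return LinearTransform3D(B, y_bar - B @ x_bar, kind="similarity")


def compose(outer: LinearTransform3D, inner: LinearTransform3D) -> LinearTransform3D:
    """Composition ``x ↦ A_outer (A_inner x + t_inner) + t_outer``.

    Composing a similarity with an anisotropic similarity of frame ``U``
    yields an anisotropic similarity with the *same* frame:
    ``(s R_B)(R_C S_C Uᵀ) = (R_B R_C)(s S_C) Uᵀ``.
    """
    A = outer.matrix @ inner.matrix
    t = outer.matrix @ inner.translation + outer.translation
    kinds = {outer.kind, inner.kind}
    if kinds == {"rigid"}:
        kind = "rigid"
    elif kinds <= {"rigid", "similarity"}:
        kind = "similarity"
    elif "affine" in kinds:
        kind = "affine"
    else:
        kind = "anisotropic_similarity"
    return LinearTransform3D(A, t, kind=kind)


# ---------------------------------------------------------------------------
# Quaternion algebra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitQuaternion:
    """Unit quaternion ``(q1, q2, q3, q4)``, real part first.

    ``q`` and ``−q`` encode the same rotation; the stored representative is
    canonicalized so that the first component of magnitude > 1e-9 is positive.
    """

    q: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float).reshape(-1)
        if q.shape != (4,):
            raise ValueError("quaternion must have 4 components")
        n = np.linalg.norm(q)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("quaternion must be unit norm")
        object.__setattr__(self, "q", canonical_quat(q / n))

    @classmethod
    def identity(cls) -> "UnitQuaternion":
        return cls(np.array([1.0, 0.0, 0.0, 0.0]))


def canonical_quat(q: np.ndarray) -> np.ndarray:
    """Fix the sign ambiguity: first component with |·| > 1e-9 made positive."""
    q = np.asarray(q, dtype=float).copy()
    for v in q:
        if abs(v) > 1e-9:
            if v < 0:
                q = -q
            break
    return q


def quat_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product ``p ∗ q`` (real part first)."""
    p1, p2, p3, p4 = np.asarray(p, dtype=float)
    q1, q2, q3, q4 = np.asarray(q, dtype=float)
    return np.array(
        [
            p1 * q1 - p2 * q2 - p3 * q3 - p4 * q4,
            p1 * q2 + p2 * q1 + p3 * q4 - p4 * q3,
            p1 * q3 - p2 * q4 + p3 * q1 + p4 * q2,
            p1 * q4 + p2 * q3 - p3 * q2 + p4 * q1,
        ]
    )


def quat_conjugate(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return np.array([p[0], -p[1], -p[2], -p[3]])


def quat_matrices(p: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Matricial representation of a quaternion ``p`` (not necessarily unit).

    Returns ``(Q_p, P_p)`` with ``Q_p · q = p ∗ q`` (left multiplication) and
    ``P_p · q = q ∗ p̄`` (right multiplication by the conjugate), hence
    ``P_pᵀ · q = q ∗ p``.  For a pure quaternion both matrices are
    antisymmetric, which is what makes the registration criterion a quadratic
    form ``qᵀ B q``.
    """
    p1, p2, p3, p4 = np.asarray(p, dtype=float).reshape(4)
    Q = np.array(
        [
            [p1, -p2, -p3, -p4],
            [p2, p1, -p4, p3],
            [p3, p4, p1, -p2],
            [p4, -p3, p2, p1],
        ]
    )
    P = np.array(
        [
            [p1, p2, p3, p4],
            [-p2, p1, -p4, p3],
            [-p3, p4, p1, -p2],
            [-p4, -p3, p2, p1],
        ]
    )
    return Q, P


def quat_to_rotation(q: Union[UnitQuaternion, np.ndarray]) -> np.ndarray:
    """Rotation matrix of a unit quaternion (``x ↦ q ∗ x ∗ q̄``)."""
    if isinstance(q, UnitQuaternion):
        q = q.q
    q = np.asarray(q, dtype=float).reshape(4)
    n = np.linalg.norm(q)
    if not np.isclose(n, 1.0, atol=1e-9):
        raise ValueError("quaternion must be unit norm")
    w, x, y, z = q / n
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def rotation_to_quat(R: np.ndarray) -> UnitQuaternion:
    """Unit quaternion of a proper rotation matrix (Shepperd's method)."""
    R = _as_matrix(R)
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-8) or not np.isclose(
        np.linalg.det(R), 1.0, atol=1e-8
    ):
        raise ValueError("input is not a proper rotation matrix")
    # pick the numerically largest component to divide by
    tr = np.trace(R)
    choices = np.array([tr, R[0, 0], R[1, 1], R[2, 2]])
    i = int(np.argmax(choices))
    if i == 0:
        w = 0.5 * np.sqrt(1.0 + tr)
        q = np.array(
            [
                w,
                (R[2, 1] - R[1, 2]) / (4 * w),
                (R[0, 2] - R[2, 0]) / (4 * w),
                (R[1, 0] - R[0, 1]) / (4 * w),
            ]
        )
    else:
        j, k = {1: (2, 3), 2: (3, 1), 3: (1, 2)}[i]
        a, b, c = i - 1, j - 1, k - 1
        s = np.sqrt(1.0 + R[a, a] - R[b, b] - R[c, c])
        q = np.empty(4)
        q[0] = (R[c, b] - R[b, c]) / (2 * s)
        q[i] = 0.5 * s
        q[j] = (R[b, a] + R[a, b]) / (2 * s)
        q[k] = (R[a, c] + R[c, a]) / (2 * s)
    return UnitQuaternion(q / np.linalg.norm(q))


# ---------------------------------------------------------------------------
# Transform file format (JSON, world-space mm, RAS+)
# ---------------------------------------------------------------------------

def save_transform(
    obj: Union[LinearTransform3D, AnisoSimDecomposition], path: Union[str, Path]
) -> None:
    Path(path).write_text(json.dumps(obj.to_dict(), indent=2) + "\n")


def load_transform(path: Union[str, Path]):
    """Load a transform JSON; returns an :class:`AnisoSimDecomposition` when
    the file carries a frame and scalings, else a :class:`LinearTransform3D`."""
    d = json.loads(Path(path).read_text())
    matrix = np.array(d["matrix"], dtype=float).reshape(3, 3)
    translation = np.array(d["translation"], dtype=float)
    kind = d.get("kind", "affine")
    if d.get("frame_U") is not None and d.get("scalings") is not None:
        frame = ScalingFrame(np.array(d["frame_U"], dtype=float).reshape(3, 3))
        S = np.array(d["scalings"], dtype=float)
        M = matrix @ frame.U
        R = M / np.linalg.norm(M, axis=0)
        Uq, _, Vtq = np.linalg.svd(R)
        return AnisoSimDecomposition(R=Uq @ Vtq, S=S, U=frame, t=translation)
    return LinearTransform3D(matrix, translation, kind=kind)
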