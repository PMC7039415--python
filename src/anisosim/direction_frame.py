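"""Construction of the constrained scaling frame U on a reference image.

The first scaling direction is the normal of the mid-sagittal plane — the
brain's approximate left-right symmetry plane — estimated here by rigidly
registering the image onto its own left-right mirror and extracting the
fixed plane of the resulting symmetry map (a documented substitute for
dedicated mid-sagittal detectors; it falls back to the grid mid-plane when
the symmetry registration is unreliable).  The remaining two directions are
the principal and secondary PCA axes of the nonzero-voxel world coordinates
projected onto that plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .blockmatch_registration import (
    Image3D,
    RegistrationConfig,
    RegistrationFailedError,
    register,
    resample,
)
from .transform_core import LinearTransform3D, ScalingFrame

logger = logging.getLogger(__name__)

__all__ = [
    "AmbiguousFrameError",
    "PlaneSpec",
    "estimate_midsagittal_plane",
    "compute_scaling_frame",
]


class AmbiguousFrameError(ValueError):
    """In-plane covariance is (near) isotropic; the PCA directions are undefined."""


@dataclass(frozen=True)
class PlaneSpec:
    """A plane in world space: unit normal plus a point on the plane (mm)."""

    normal: np.ndarray
    point: np.ndarray

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float).reshape(3)
        if not np.isclose(np.linalg.norm(n), 1.0, atol=1e-9):
            raise ValueError("plane normal must be unit length")
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float).reshape(3))


def _grid_midplane(img: Image3D) -> PlaneSpec:
    """Fallback: the mid-plane of the voxel grid along the first axis."""
    n = img.affine[:3, 0] / np.linalg.norm(img.affine[:3, 0])
    if n[0] < 0:
        n = -n
    center = img.voxel_to_world((np.asarray(img.shape, dtype=float) - 1) / 2.0)
    return PlaneSpec(normal=n, point=center)


def estimate_midsagittal_plane(
    img: Image3D, cfg: Optional[RegistrationConfig] = None
) -> PlaneSpec:
    """Estimate the left-right symmetry plane by mirror registration.

    The image is registered rigidly onto its mirror about the grid mid-plane.
    If ``T`` maps image world coordinates to mirror world coordinates and
    ``F`` is the mirroring map, ``S = F ∘ T`` maps the head onto itself and,
    for a truly symmetric object, is the reflection about the mid-sagittal
    plane: ``S(x) = x − 2((x − p)·n)n``.  The normal is read off the linear
    part (the eigendirection of ``(I − L)/2`` with the largest eigenvalue)
    and the plane point from the midpoint of a point and its image.  When the
    result is far from a reflection the grid mid-plane is returned instead,
    with a logged warning.
    """
    if cfg is None:
        # symmetry registration needs no dense lattice: a coarser block grid
        # and fewer sweeps give the plane to a fraction of a degree
        cfg = RegistrationConfig(kind="rigid", block_spacing=3,
                                 iterations_per_level=6)
    fallback = _grid_midplane(img)

    # initial mirror: flip voxel axis 0, same affine → world-space mirroring F
    mirror = Image3D(np.ascontiguousarray(img.data[::-1]), img.affine)
    n0 = img.shape[0]
    Mvox = np.eye(4)
    Mvox[0, 0] = -1.0
    Mvox[0, 3] = n0 - 1.0
    F4 = img.affine @ Mvox @ np.linalg.inv(img.affine)
    F = LinearTransform3D(F4[:3, :3], F4[:3, 3])

    plane = fallback
    for sweep in range(3):
        try:
            rep = register(img, mirror, replace_kind_rigid(cfg))
        except Exception as exc:  # registration failure of any kind → fallback
            logger.warning("mid-sagittal symmetry registration failed (%s); "
                           "falling back to the grid mid-plane", exc)
            return fallback
        scores = rep.match_set.scores
        if len(scores) == 0 or float(np.mean(scores)) < 0.4:
            logger.warning(
                "symmetry registration matches are unreliable (mean score "
                "%.2f); falling back to the grid mid-plane",
                float(np.mean(scores)) if len(scores) else 0.0,
            )
            return fallback

        S_lin = F.matrix @ rep.transform.matrix
        S_t = F.matrix @ rep.transform.translation + F.translation
        # reflection check: L ≈ I − 2nnᵀ with det ≈ −1
        E = 0.5 * (np.eye(3) - S_lin)
        E = 0.5 * (E + E.T)
        evals, evecs = np.linalg.eigh(E)
        n = evecs[:, np.argmax(evals)]
        residual = np.linalg.norm(S_lin - (np.eye(3) - 2 * np.outer(n, n)))
        if np.linalg.det(S_lin) > -0.5 or residual > 0.3:
            logger.warning(
                "symmetry map is not close to a reflection (residual %.3g); "
                "falling back to the grid mid-plane", residual,
            )
            return fallback
        if n[0] < 0 or (n[0] == 0 and n[np.argmax(np.abs(n))] < 0):
            n = -n
        n = n / np.linalg.norm(n)
        c = img.voxel_to_world((np.asarray(img.shape, dtype=float) - 1) / 2.0)
        s_c = S_lin @ c + S_t
        point = 0.5 * (c + s_c)
        point = point + ((c - point) - ((c - point) @ n) * n)  # drop in-plane part
        plane = PlaneSpec(normal=n, point=point)
        # refine: mirror about the *estimated* plane and register the residual;
        # each sweep halves the rotation the block matcher must capture
        refl = np.eye(3) - 2 * np.outer(n, n)
        F = LinearTransform3D(refl, (np.eye(3) - refl) @ point)
        mirror = resample(img, F, img)
    return plane


def replace_kind_rigid(cfg: RegistrationConfig) -> RegistrationConfig:
    from dataclasses import replace

    return replace(cfg, kind="rigid", frame=None)


def compute_scaling_frame(
    img_or_mask: Image3D, plane: PlaneSpec, rel_gap: float = 1e-9
) -> ScalingFrame:
    """Build the frame: plane normal, then in-plane principal/secondary PCA axes.

    PCA runs on the (unweighted) world coordinates of the nonzero voxels,
    projected onto the mid-sagittal plane.  Column 1 is the plane normal,
    column 2 the leading in-plane eigenvector, column 3 the secondary one
    (flipped if needed so det U = +1).  Sign conventions: column 1 has
    nonnegative dot with world +x, column 2 with world +y.  A (near)
    isotropic in-plane covariance — relative eigenvalue gap below
    ``rel_gap`` — raises :class:`AmbiguousFrameError`.
    """
    data = img_or_mask.data if img_or_mask.mask is None else img_or_mask.mask
    vox = np.argwhere(np.asarray(data) != 0)
    if len(vox) < 2:
        raise ValueError("need at least 2 nonzero voxels")
    pts = img_or_mask.voxel_to_world(vox.astype(float))
    n = plane.normal
    d = (pts - plane.point) @ n
    proj = pts - d[:, None] * n[None, :]
    proj = proj - proj.mean(axis=0)
    cov = proj.T @ proj / len(proj)
    evals, evecs = np.linalg.eigh(cov)
    # the projection leaves rank 2: drop the (near-zero) normal eigenvalue
    order = np.argsort(evals)[::-1]
    l1, l2 = evals[order[0]], evals[order[1]]
    v1, v2 = evecs[:, order[0]], evecs[:, order[1]]
    if l1 <= 0 or (l1 - l2) <= rel_gap * l1:
        raise AmbiguousFrameError(
            "in-plane covariance is isotropic; principal directions are undefined"
        )
    c1 = n if n[0] >= 0 else -n
    c2 = v1 if v1[1] >= 0 else -v1
    c3 = v2
    U = np.column_stack([c1, c2, c3])
    if np.linalg.det(U) < 0:
        U[:, 2] = -U[:, 2]
    # polish: project onto the closest rotation to wash out discretization
    Uq, _, Vt = np.linalg.svd(U)
    return ScalingFrame(Uq @ Vt)
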