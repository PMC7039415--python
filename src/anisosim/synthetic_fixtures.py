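"""Deterministic synthetic data: ellipsoid phantoms, point pairs and cohorts.

Every generator is a pure function of its spec plus a seed, so tests and the
acceptance pipeline run without any external data.  Phantoms are rendered
*analytically* from ellipsoid membership functions; applying a transform
re-renders the geometry instead of resampling, which gives alias-free ground
truth for registration-recovery experiments.

Cohorts emulate the structure of a pediatric growth study: ages 0–19 years
with a neonate cluster (ages ≤ 0.1 y, the normalization baseline, mirroring
a newborn cohort scanned in the first month of life), per-direction growth
following one of the four candidate growth families, multiplicative
lognormal noise on the (positive, ratio-valued) scaling factors, and an
optional multiplicative sex effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .transform_core import LinearTransform3D
from .pointset_estimation import PairedPointSet

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "CohortSpec",
    "make_phantom",
    "transform_phantom",
    "make_paired_points",
    "make_cohort",
    "default_brain_spec",
    "GROWTH_FAMILIES",
]


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    """One soft-edged ellipsoid: center/semi-axes in world mm, optional rotation."""

    center: Tuple[float, float, float]
    semi_axes: Tuple[float, float, float]
    intensity: float
    label: str
    rotation: Optional[np.ndarray] = None  # 3x3, None = axis-aligned

    def quadric(self) -> Tuple[np.ndarray, np.ndarray]:
        """Matrix M and center c with membership boundary {p: (p−c)ᵀM(p−c)=1}."""
        a = np.asarray(self.semi_axes, dtype=float)
        if np.any(a <= 0):
            raise ValueError("semi-axes must be positive")
        D = np.diag(1.0 / a**2)
        R = np.eye(3) if self.rotation is None else np.asarray(self.rotation, float)
        return R @ D @ R.T, np.asarray(self.center, dtype=float)


@dataclass(frozen=True)
class PhantomSpec:
    shape: Tuple[int, int, int] = (64, 64, 64)
    spacing: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    ellipsoids: Tuple[Ellipsoid, ...] = ()
    noise_sigma: float = 0.0
    edge_width: float = 0.08  # soft-edge width in normalized radius units
    # deterministic multi-scale blob texture: tuples (center mm, width mm,
    # relative amplitude); non-periodic, so block matching has unambiguous
    # local structure at every pyramid scale
    texture_blobs: Tuple[Tuple[Tuple[float, float, float], float, float], ...] = ()
    seed: int = 0

    def __post_init__(self):
        labels = [e.label for e in self.ellipsoids]
        if len(set(labels)) != len(labels):
            raise ValueError("ellipsoid labels must be unique")

    @property
    def affine(self) -> np.ndarray:
        """Voxel→world affine putting the world origin at the grid center."""
        A = np.eye(4)
        sp = np.asarray(self.spacing, dtype=float)
        A[:3, :3] = np.diag(sp)
        A[:3, 3] = -(np.asarray(self.shape) - 1) / 2.0 * sp
        return A


def default_brain_spec(noise_sigma: float = 0.0, seed: int = 0) -> PhantomSpec:
    """A left-right symmetric multi-ellipsoid 'brain' on a 64³, 2 mm grid.

    The layout is mirror-symmetric about the world plane x = 0 so the
    mid-sagittal estimator is exercised, and the in-plane extents differ
    (longer along y than z) so the PCA frame is well determined.
    """
    ell = (
        Ellipsoid((0, 0, 0), (42, 54, 46), 100.0, "brain"),
        Ellipsoid((18, 8, 10), (12, 16, 13), 60.0, "deep_r"),
        Ellipsoid((-18, 8, 10), (12, 16, 13), 60.0, "deep_l"),
        Ellipsoid((0, -34, -22), (20, 14, 12), 80.0, "cerebellum"),
        Ellipsoid((7, 6, 6), (5, 12, 6), -60.0, "vent_r"),
        Ellipsoid((-7, 6, 6), (5, 12, 6), -60.0, "vent_l"),
        Ellipsoid((0, 30, 12), (14, 14, 10), 45.0, "frontal"),
    )
    return PhantomSpec(
        ellipsoids=ell,
        noise_sigma=noise_sigma,
        texture_blobs=_symmetric_blob_texture(),
        seed=seed,
    )


def _texture(spec: PhantomSpec, points: np.ndarray) -> np.ndarray:
    """Smooth multiplicative blob texture (clipped to stay positive)."""
    if not spec.texture_blobs:
        return np.ones(points.shape[:-1])
    t = np.zeros(points.shape[:-1])
    for center, width, amp in spec.texture_blobs:
        d = points - np.asarray(center, dtype=float)
        t += amp * np.exp(-np.einsum("...i,...i->...", d, d) / (2.0 * width**2))
    return np.maximum(1.0 + t, 0.2)


def _symmetric_blob_texture(
    n: int = 48, extent: float = 45.0, rng_seed: int = 977
) -> Tuple[Tuple[Tuple[float, float, float], float, float], ...]:
    """Mirror-symmetric (x → −x) set of blobs at mixed spatial scales.

    Amplitudes are a sizeable fraction of the base intensity so interior
    blocks carry local contrast comparable to tissue structure; without it
    the smooth boundary dominates and block matching becomes blind to
    tangential (rotational) motion.
    """
    rng = np.random.default_rng(rng_seed)
    blobs = []
    for _ in range(n):
        c = rng.uniform(-extent, extent, 3)
        width = rng.uniform(4.0, 20.0)
        amp = rng.uniform(0.25, 0.55) * rng.choice([-1.0, 1.0])
        blobs.append(((c[0], c[1], c[2]), width, amp))
        if abs(c[0]) > 1e-9:
            blobs.append(((-c[0], c[1], c[2]), width, amp))
    return tuple(blobs)


def _render(spec: PhantomSpec, points: np.ndarray) -> np.ndarray:
    """Analytic intensity at arbitrary world points (sum of soft memberships)."""
    out = np.zeros(points.shape[:-1])
    w = spec.edge_width
    for e in spec.ellipsoids:
        M, c = e.quadric()
        d = points - c
        q = np.einsum("...i,ij,...j->...", d, M, d)
        r = np.sqrt(np.maximum(q, 0.0))
        out += e.intensity / (1.0 + np.exp(np.clip((r - 1.0) / w, -60, 60)))
    return out * _texture(spec, points)


def _world_grid(spec: PhantomSpec) -> np.ndarray:
    idx = np.indices(spec.shape).reshape(3, -1).T.astype(float)
    A = spec.affine
    return idx @ A[:3, :3].T + A[:3, 3]


def make_phantom(spec: PhantomSpec):
    """Render a phantom image plus one hard binary mask per ellipsoid label.

    Returns ``(image, masks)`` where ``image`` is an
    :class:`~anisosim.blockmatch_registration.Image3D` and ``masks`` maps each
    label to a boolean array on the same grid (membership radius ≤ 1).
    """
    from .blockmatch_registration import Image3D  # local import: avoid cycle

    pts = _world_grid(spec)
    data = _render(spec, pts).reshape(spec.shape)
    masks: Dict[str, np.ndarray] = {}
    for e in spec.ellipsoids:
        M, c = e.quadric()
        d = pts - c
        q = np.einsum("...i,ij,...j->...", d, M, d)
        masks[e.label] = (q <= 1.0).reshape(spec.shape)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)
    return Image3D(data, spec.affine), masks


def transform_phantom(spec: PhantomSpec, T: LinearTransform3D):
    """Analytically re-render the phantom as seen after transform ``T``.

    ``T`` maps reference-space world coordinates to moving-space ones
    (backward convention), so the moving image satisfies
    ``mov(y) = ref(T⁻¹(y))`` and registering ``ref → mov`` recovers ``T``.
    """
    from .blockmatch_registration import Image3D

    Tinv = T.inverse()  # raises on singular T
    pts = Tinv.apply(_world_grid(spec))
    data = _render(spec, pts).reshape(spec.shape)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 1)
        data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)
    return Image3D(data, spec.affine)


# ---------------------------------------------------------------------------
# Paired points
# ---------------------------------------------------------------------------

def make_paired_points(
    M: int,
    transform: LinearTransform3D,
    noise_sigma: float = 0.0,
    seed: int = 0,
    half_extent: float = 50.0,
    coplanar: bool = False,
) -> PairedPointSet:
    """``x`` uniform in a cube of the given half-extent (mm); ``y = T(x) + ε``.

    ``coplanar=True`` flattens the third coordinate to produce a degenerate
    geometry (for exercising degenerate-point-set errors downstream).
    """
    if M < 4:
        raise ValueError("need at least 4 point pairs")
    rng = np.random.default_rng(seed)
    x = rng.uniform(-half_extent, half_extent, size=(M, 3))
    if coplanar:
        x[:, 2] = 0.0
    y = transform.apply(x)
    if noise_sigma > 0:
        y = y + rng.normal(0.0, noise_sigma, size=y.shape)
    return PairedPointSet(x, y)


# ---------------------------------------------------------------------------
# Cohorts of scaling factors
# ---------------------------------------------------------------------------

def _rational(x, a, b, c):
    return (a * x + b) / (x + c)


def _weibull(x, a, b, c, d):
    return a - b * np.exp(-c * np.asarray(x, dtype=float) ** d)


def _gompertz(x, a, b, c):
    return a * np.exp(-b * np.exp(-c * x))


def _exponential(x, a, b, c):
    return a + b * np.exp(-c * x)


GROWTH_FAMILIES = {
    "rational": _rational,
    "weibull": _weibull,
    "gompertz": _gompertz,
    "exponential": _exponential,
}


@dataclass(frozen=True)
class CohortSpec:
    """Generator spec for a synthetic cohort of per-direction scaling factors.

    Defaults mirror the structure of the study cohort: 308 subjects, a
    neonate baseline cluster of roughly 12% (ages ≤ 0.1 y), the remainder
    spread over (0, 6], (6, 12] and (12, 19] in proportions ≈ 0.39/0.39/0.22,
    near-balanced sexes, and saturating growth per direction with
    multiplicative lognormal noise.  The default true curves are rational
    (degree-1 over degree-1) with value 1 at birth and direction-dependent
    asymptotes, rendered *relative* to a reference image via constant
    per-direction reference factors (< 1: the atlas is larger than a neonate).
    """

    n_subjects: int = 308
    neonate_fraction: float = 0.12
    age_bin_weights: Tuple[float, float, float] = (0.39, 0.39, 0.22)
    age_bins: Tuple[Tuple[float, float], ...] = ((0.1, 6.0), (6.0, 12.0), (12.0, 19.0))
    rois: Tuple[str, ...] = ("whole_brain",)
    growth_family: str = "rational"
    # per-direction coefficients, value 1 at age 0 (b = c for the rational)
    growth_coefficients: Tuple[Tuple[float, ...], ...] = (
        (1.35, 1.0, 1.0),
        (1.30, 1.5, 1.5),
        (1.42, 0.8, 0.8),
    )
    reference_factors: Tuple[float, ...] = (0.76, 0.80, 0.72)
    noise_sigma: float = 0.03  # lognormal sigma on scaling factors
    sex_effect: Optional[Dict[int, float]] = None  # direction -> male multiplier
    n_references: int = 1
    reference_jitter_sigma: float = 0.0  # lognormal jitter across references
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 4:
            raise ValueError("cohort needs at least 4 subjects")
        if self.growth_family not in GROWTH_FAMILIES:
            raise ValueError(f"unknown growth family {self.growth_family!r}")
        fam = GROWTH_FAMILIES[self.growth_family]
        ages = np.linspace(0, 19, 50)
        for coefs in self.growth_coefficients:
            if np.any(fam(ages, *coefs) <= 0):
                raise ValueError("growth coefficients must keep s > 0 on [0, 19]")


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Sample a scaling-record table: one row per subject × ROI × direction × reference.

    Columns: ``subject, age, sex, roi, direction, reference, scaling`` —
    ``scaling`` is *relative* to the reference image (true growth curve times
    the per-direction reference factor, times lognormal noise and optional
    sex effect).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    n_neo = max(2, int(round(spec.neonate_fraction * n)))
    ages = np.empty(n)
    ages[:n_neo] = rng.uniform(0.0, 0.1, size=n_neo)
    bins = rng.choice(len(spec.age_bins), size=n - n_neo, p=np.asarray(
        spec.age_bin_weights) / sum(spec.age_bin_weights))
    for i, b in enumerate(bins):
        lo, hi = spec.age_bins[b]
        ages[n_neo + i] = rng.uniform(lo, hi)
    sexes = rng.choice(["male", "female"], size=n)
    fam = GROWTH_FAMILIES[spec.growth_family]

    rows = []
    for k in range(spec.n_references):
        ref_id = f"ref{k + 1}"
        for j, roi in enumerate(spec.rois):
            for d in range(3):
                coefs = spec.growth_coefficients[d]
                true = fam(ages, *coefs) * spec.reference_factors[d]
                s = true.copy()
                if spec.noise_sigma > 0:
                    s = s * np.exp(rng.normal(0, spec.noise_sigma, size=n))
                if spec.sex_effect and (d + 1) in spec.sex_effect:
                    s = np.where(
                        sexes == "male", s * spec.sex_effect[d + 1], s
                    )
                if spec.reference_jitter_sigma > 0 and spec.n_references > 1:
                    s = s * np.exp(
                        rng.normal(0, spec.reference_jitter_sigma, size=n)
                    )
                rows.append(
                    pd.DataFrame(
                        {
                            "subject": [f"sub{i:04d}" for i in range(n)],
                            "age": ages,
                            "sex": sexes,
                            "roi": roi,
                            "direction": d + 1,
                            "reference": ref_id,
                            "scaling": s,
                        }
                    )
                )
    df = pd.concat(rows, ignore_index=True)
    if np.any(df["scaling"] <= 0):
        raise RuntimeError("generator produced a non-positive scaling factor")
    return df
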