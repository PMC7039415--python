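"""Iterative block-matching 3D registration on NIfTI-style images.

The engine alternates two steps per pyramid level:

1. *Matching* — for a lattice of blocks in the reference image, the
   homologous block is searched in the moving image by exhaustive
   integer-voxel offsets around the current transform's prediction; the
   squared Pearson correlation of the block intensity vectors is the match
   score.
2. *Aggregation* — the matched block-center pairs (in world mm, scores as
   weights) are fed to the requested point-set fitter
   (rigid / similarity / affine / anisotropic similarity with a fixed
   scaling frame), which directly yields the updated global transform.

All fitting happens in world millimetres so anisotropic voxel spacing cannot
masquerade as anatomical anisotropy.  Transforms map reference-space world
coordinates to moving-space ones (backward mapping), which is also the
direction used for resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
from scipy import ndimage

from .transform_core import (
    LinearTransform3D,
    ScalingFrame,
    nearest_similarity,
)
from .pointset_estimation import (
    FitReport,
    PairedPointSet,
    fit_affine,
    fit_anisotropic_similarity,
    fit_rigid,
    fit_similarity,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EmptyBlocksError",
    "RegistrationFailedError",
    "Image3D",
    "BlockMatchSet",
    "RegistrationConfig",
    "extract_blocks",
    "match_blocks",
    "register",
    "two_step_roi_registration",
    "resample",
]


class EmptyBlocksError(RuntimeError):
    """No block survived extraction (flat image or empty mask)."""


class RegistrationFailedError(RuntimeError):
    """Fewer than 4 usable block pairs; no transform can be estimated."""


# ---------------------------------------------------------------------------
# Image container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Image3D:
    """A 3D scalar image: voxel array plus voxel-to-world 4×4 affine (mm)."""

    data: np.ndarray
    affine: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError("image data must be 3D")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(np.linalg.norm(aff[:3, :3], axis=0) <= 0):
            raise ValueError("voxel spacing must be positive")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", aff)
        if self.mask is not None:
            mask = np.asarray(self.mask).astype(bool)
            if mask.shape != data.shape:
                raise ValueError("mask must be on the same grid as the image")
            object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, vox: np.ndarray) -> np.ndarray:
        vox = np.asarray(vox, dtype=float)
        return vox @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, world: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        world = np.asarray(world, dtype=float)
        return world @ inv[:3, :3].T + inv[:3, 3]

    @classmethod
    def from_nifti(cls, path: Union[str, Path], mask_path=None) -> "Image3D":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
        mask = None
        if mask_path is not None:
            m = nib.load(str(mask_path))
            mask = np.asanyarray(m.dataobj) > 0
        return cls(data, img.affine, mask=mask)

    def to_nifti(self, path: Union[str, Path]) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))


@dataclass(frozen=True)
class BlockMatchSet:
    """Matched block-center pairs (world mm) with correlation scores as weights."""

    points: PairedPointSet
    scores: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (len(self.points),):
            raise ValueError("one score per pair required")
        if np.any((s < 0) | (s > 1 + 1e-9)):
            raise ValueError("scores must lie in [0, 1]")
        object.__setattr__(self, "scores", np.clip(s, 0.0, 1.0))

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class RegistrationConfig:
    """Block-matching hyperparameters (all overridable; sizes in voxels)."""

    block_size: int = 5
    block_spacing: int = 2
    search_radius: int = 3
    keep_fraction: float = 0.75
    pyramid_levels: int = 3
    iterations_per_level: int = 10
    kind: str = "rigid"
    frame: Optional[ScalingFrame] = None
    score_threshold: float = 0.05
    stop_displacement: float = 0.01  # early stop, in units of min voxel spacing
    seed: int = 0

    def __post_init__(self):
        if self.block_size % 2 != 1 or self.block_size < 3:
            raise ValueError("block size must be odd and ≥ 3")
        if not (0 < self.keep_fraction <= 1):
            raise ValueError("keep fraction must be in (0, 1]")
        if self.kind not in {"rigid", "similarity", "affine", "anisotropic_similarity"}:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "anisotropic_similarity" and self.frame is None:
            raise ValueError("anisotropic similarity registration needs a frame U")


# ---------------------------------------------------------------------------
# Block extraction and matching
# ---------------------------------------------------------------------------

def _block_offsets(block_size: int, shape: Tuple[int, int, int]):
    half = block_size // 2
    rng = np.arange(-half, half + 1)
    offs = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    return offs, offs @ strides


def _gather_blocks(flat: np.ndarray, centers_flat: np.ndarray, off_flat: np.ndarray):
    return flat[centers_flat[:, None] + off_flat[None, :]]


def extract_blocks(ref: Image3D, cfg: RegistrationConfig) -> np.ndarray:
    """Lattice of block centers inside the mask, keeping the most variant ones.

    Blocks are placed on a regular lattice (step ``block_spacing``) strictly
    inside the volume; flat blocks are discarded, the rest ranked by
    intensity variance and the lowest ``1 − keep_fraction`` dropped.
    Returns integer voxel coordinates, shape (N, 3).
    """
    half = cfg.block_size // 2
    shape = ref.shape
    axes = [np.arange(half, s - half, cfg.block_spacing) for s in shape]
    if any(len(a) == 0 for a in axes):
        raise EmptyBlocksError("image too small for the requested block size")
    centers = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    if ref.mask is not None:
        if not ref.mask.any():
            raise EmptyBlocksError("mask is empty")
        keep = ref.mask[centers[:, 0], centers[:, 1], centers[:, 2]]
        centers = centers[keep]
        if len(centers) == 0:
            raise EmptyBlocksError("no block center falls inside the mask")
    _, off_flat = _block_offsets(cfg.block_size, shape)
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    flat = np.ascontiguousarray(ref.data, dtype=np.float32).ravel()
    vecs = _gather_blocks(flat, centers @ strides, off_flat)
    var = vecs.var(axis=1)
    dyn = float(ref.data.max() - ref.data.min())
    live = var > 1e-12 * max(1.0, dyn * dyn)
    centers, var = centers[live], var[live]
    if len(centers) == 0:
        raise EmptyBlocksError("all candidate blocks are flat")
    n_keep = max(1, int(round(cfg.keep_fraction * len(centers))))
    order = np.argsort(var, kind="stable")[::-1]
    kept = centers[np.sort(order[:n_keep])]
    return kept


def match_blocks(
    ref: Image3D,
    mov: Image3D,
    centers: np.ndarray,
    current_T: LinearTransform3D,
    cfg: RegistrationConfig,
) -> BlockMatchSet:
    """Exhaustive integer-offset search for each reference block.

    The search window is centered on the current transform's image of the
    block center (rounded to the nearest moving voxel).  The score is the
    squared correlation coefficient between block intensity vectors; the
    best-scoring moving center becomes ``y``.  Pairs whose best score falls
    below ``cfg.score_threshold`` (or whose candidates are all flat) are
    dropped.
    """
    half = cfg.block_size // 2
    r = cfg.search_radius
    n_vox = cfg.block_size**3
    margin = half + r

    ref_flat = np.ascontiguousarray(ref.data, dtype=np.float32).ravel()
    # zero-pad the moving image so search windows near the border stay valid
    mov_pad = np.pad(np.asarray(mov.data, dtype=np.float32), margin)
    mov_flat = mov_pad.ravel()
    _, off_flat_ref = _block_offsets(cfg.block_size, ref.shape)
    _, off_flat_mov = _block_offsets(cfg.block_size, mov_pad.shape)
    strides_ref = np.array([ref.shape[1] * ref.shape[2], ref.shape[2], 1])
    strides_mov = np.array(
        [mov_pad.shape[1] * mov_pad.shape[2], mov_pad.shape[2], 1]
    )

    x_world = ref.voxel_to_world(centers)
    pred_vox = mov.world_to_voxel(current_T.apply(x_world))
    m0 = np.rint(pred_vox).astype(int)
    inb = np.all((m0 >= 0) & (m0 <= np.array(mov.shape) - 1), axis=1)
    centers, x_world, m0 = centers[inb], x_world[inb], m0[inb]
    if len(centers) == 0:
        return _empty_match()

    A = _gather_blocks(ref_flat, centers @ strides_ref, off_flat_ref)
    An = A - A.mean(axis=1, keepdims=True)
    a_norm = np.linalg.norm(An, axis=1)
    ok_ref = a_norm > 0
    An = np.where(ok_ref[:, None], An / np.where(ok_ref, a_norm, 1.0)[:, None], 0.0)

    base_flat = (m0 + margin) @ strides_mov
    srange = np.arange(-r, r + 1)
    search = np.stack(np.meshgrid(srange, srange, srange, indexing="ij"), axis=-1)
    search = search.reshape(-1, 3)
    best_score = np.full(len(centers), -1.0)
    best_k = np.zeros(len(centers), dtype=int)
    for k, off in enumerate(search):
        off_scalar = int(off @ strides_mov)
        B = _gather_blocks(mov_flat, base_flat + off_scalar, off_flat_mov)
        bs = B.sum(axis=1)
        denom = np.einsum("ij,ij->i", B, B) - bs * bs / n_vox
        dot = np.einsum("ij,ij->i", An, B)
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(denom > 1e-12, dot * dot / denom, -1.0)
        better = score > best_score
        best_score[better] = score[better]
        best_k[better] = k

    usable = ok_ref & (best_score >= max(cfg.score_threshold, 0.0)) & (best_score > 0)
    if not np.any(usable):
        return _empty_match()
    y_vox = m0[usable] + search[best_k[usable]]
    y_world = mov.voxel_to_world(y_vox)
    scores = np.clip(best_score[usable], 0.0, 1.0)
    pts = PairedPointSet(x_world[usable], y_world, scores)
    return BlockMatchSet(points=pts, scores=scores)


def _empty_match() -> BlockMatchSet:
    pts = PairedPointSet.__new__(PairedPointSet)
    object.__setattr__(pts, "x", np.zeros((0, 3)))
    object.__setattr__(pts, "y", np.zeros((0, 3)))
    object.__setattr__(pts, "w", np.zeros(0))
    bm = BlockMatchSet.__new__(BlockMatchSet)
    object.__setattr__(bm, "points", pts)
    object.__setattr__(bm, "scores", np.zeros(0))
    return bm


def fit_pointset(pts: PairedPointSet, kind: str, frame: Optional[ScalingFrame]) -> FitReport:
    """Dispatch to the point-set fitter for a transform kind."""
    if kind == "rigid":
        return fit_rigid(pts)
    if kind == "similarity":
        return fit_similarity(pts)
    if kind == "affine":
        return fit_affine(pts)
    if kind == "anisotropic_similarity":
        return fit_anisotropic_similarity(pts, frame)
    raise ValueError(f"unknown transform kind {kind!r}")


# ---------------------------------------------------------------------------
# Pyramid and main loop
# ---------------------------------------------------------------------------

def _intensity_centroid(img: Image3D) -> np.ndarray:
    w = img.data - img.data.min()
    total = w.sum()
    if total <= 0:
        return img.voxel_to_world((np.asarray(img.shape, dtype=float) - 1) / 2.0)
    idx = np.indices(img.shape).reshape(3, -1)
    vox = (w.ravel() @ idx.T) / total
    return img.voxel_to_world(vox)


def _downsample(img: Image3D, factor: int) -> Image3D:
    if factor == 1:
        return img
    data = ndimage.gaussian_filter(img.data, sigma=factor / 2.0)
    data = data[::factor, ::factor, ::factor]
    aff = img.affine.copy()
    aff[:3, :3] *= factor
    mask = None
    if img.mask is not None:
        mask = img.mask[::factor, ::factor, ::factor]
    return Image3D(data, aff, mask=mask)


def register(
    ref: Image3D,
    mov: Image3D,
    cfg: RegistrationConfig,
    initial_transform: Optional[LinearTransform3D] = None,
) -> FitReport:
    """Multi-resolution block-matching registration of ``mov`` onto ``ref``.

    Per pyramid level (coarse to fine) the match/fit cycle runs for
    ``iterations_per_level`` iterations or until the transform update moves
    block centers by less than ``stop_displacement`` voxels.  Because block
    pairs are expressed in absolute world coordinates, each aggregation
    directly produces the total transform; the returned report's
    ``diagnostics`` carry per-iteration costs, pair counts and the final
    match set.
    """
    if initial_transform is not None:
        T = initial_transform
    else:
        # deterministic barycentric initialization: translate so the
        # intensity centroids coincide, which brings large offsets inside
        # the search range of the coarsest level
        T = LinearTransform3D(
            np.eye(3), _intensity_centroid(mov) - _intensity_centroid(ref)
        )
    diagnostics: List[dict] = []
    last_fit: Optional[FitReport] = None
    last_match: Optional[BlockMatchSet] = None

    factors = [2 ** (cfg.pyramid_levels - 1 - l) for l in range(cfg.pyramid_levels)]
    margin = cfg.block_size // 2 + cfg.search_radius
    for level, f in enumerate(factors):
        if f > 1 and min(min(ref.shape), min(mov.shape)) // f < 2 * margin:
            continue  # level too coarse to host block + search window
        ref_l = _downsample(ref, f)
        mov_l = _downsample(mov, f)
        try:
            centers = extract_blocks(ref_l, cfg)
        except EmptyBlocksError:
            if f > 1:  # level too coarse for the mask; skip it
                continue
            raise
        min_sp = float(ref_l.spacing.min())
        for it in range(cfg.iterations_per_level):
            # match against the moving image resampled through the current
            # estimate: block contents are then scale- and rotation-matched,
            # which removes the bias of comparing fixed-size blocks across a
            # stretch; matched positions are mapped back through T so the
            # fit still estimates the *total* transform (keeping the
            # anisotropic-similarity class closed under aggregation)
            mov_res = resample(mov_l, T, ref_l)
            bm_res = match_blocks(
                ref_l, mov_res, centers, LinearTransform3D.identity(), cfg
            )
            if len(bm_res) < 4:
                raise RegistrationFailedError(
                    f"only {len(bm_res)} usable block pairs at level {level}"
                )
            bm = BlockMatchSet(
                points=PairedPointSet(
                    bm_res.points.x, T.apply(bm_res.points.y), bm_res.points.w
                ),
                scores=bm_res.scores,
            )
            fit = fit_pointset(bm.points, cfg.kind, cfg.frame)
            x_ctr = bm.points.x
            disp = np.linalg.norm(fit.transform.apply(x_ctr) - T.apply(x_ctr), axis=1)
            T = fit.transform
            last_fit, last_match = fit, bm
            diagnostics.append(
                {
                    "level": level,
                    "factor": f,
                    "iteration": it,
                    "cost": fit.final_cost,
                    "n_pairs": len(bm),
                    "max_update_mm": float(disp.max()),
                }
            )
            logger.debug(
                "level %d it %d: %d pairs, cost %.4g, update %.3g mm",
                level, it, len(bm), fit.final_cost, disp.max(),
            )
            if disp.max() < cfg.stop_displacement * min_sp:
                break

    if last_fit is None:
        raise RegistrationFailedError("no pyramid level produced block pairs")
    report = FitReport(
        transform=T,
        final_cost=last_fit.final_cost,
        n_iterations=len(diagnostics),
        converged=last_fit.converged,
        decomposition=last_fit.decomposition,
        quaternion=last_fit.quaternion,
        cost_trace=[d["cost"] for d in diagnostics],
    )
    report.diagnostics = diagnostics  # type: ignore[attr-defined]
    report.match_set = last_match  # type: ignore[attr-defined]
    report.seed = cfg.seed  # type: ignore[attr-defined]
    return report


def two_step_roi_registration(
    subject: Image3D,
    ref: Image3D,
    roi_mask: np.ndarray,
    frame: ScalingFrame,
    cfg: Optional[RegistrationConfig] = None,
) -> Tuple[LinearTransform3D, FitReport, np.ndarray]:
    """The two-step ROI protocol yielding per-direction scaling factors.

    Step 1: whole-image affine registration of the subject onto the
    reference, projected to its nearest similarity ``T_B`` (mean singular
    value, translation from the matched-point barycenters).  Step 2:
    anisotropic-similarity registration restricted to the ROI (the mask only
    limits reference block extraction), initialized at ``T_B``.  Because a
    similarity composed with an anisotropic similarity of frame ``U`` stays
    in the class of ``U``, the step-2 estimate is an anisotropic similarity
    whose scalings are returned in the frame's column order.
    """
    if cfg is None:
        cfg = RegistrationConfig()
    cfg_affine = replace(cfg, kind="affine", frame=None)
    rep_a = register(ref, subject, cfg_affine)
    bm = rep_a.match_set  # type: ignore[attr-defined]
    x_bar, y_bar = bm.points.barycenters
    T_B = nearest_similarity(
        rep_a.transform.matrix, rep_a.transform.translation, x_bar, y_bar
    )
    roi = np.asarray(roi_mask).astype(bool)
    ref_roi = Image3D(ref.data, ref.affine, mask=roi)
    cfg_aniso = replace(cfg, kind="anisotropic_similarity", frame=frame)
    rep_c = register(ref_roi, subject, cfg_aniso, initial_transform=T_B)
    return T_B, rep_c, rep_c.decomposition.S.copy()


# ---------------------------------------------------------------------------
# Resampling (backward mapping)
# ---------------------------------------------------------------------------

def resample(
    mov: Image3D,
    T: LinearTransform3D,
    ref_grid: Union[Image3D, Tuple[Tuple[int, int, int], np.ndarray]],
) -> Image3D:
    """Resample ``mov`` onto a reference grid through the backward map ``T``.

    Each output voxel's world coordinate is sent through ``T`` into moving
    space and the value trilinearly interpolated there; points outside the
    moving field of view get 0.
    """
    if isinstance(ref_grid, Image3D):
        shape, affine = ref_grid.shape, ref_grid.affine
    else:
        shape, affine = ref_grid
        affine = np.asarray(affine, dtype=float)
    T.inverse()  # raises on singular transforms
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    mov_vox = mov.world_to_voxel(T.apply(world))
    vals = ndimage.map_coordinates(
        mov.data, mov_vox.T, order=1, mode="constant", cval=0.0
    )
    return Image3D(vals.reshape(shape), affine)
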