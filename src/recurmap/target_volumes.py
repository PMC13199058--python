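"""Reconstruction of analysis target volumes from a resection-cavity mask.

The analysis clinical target volume (CTV) is the convex hull of the cavity,
rasterized by voxel-center containment; the analysis planning target volume
(PTV) is the CTV expanded concentrically by a physical margin (default 5 mm)
using an anisotropic Euclidean distance transform. Neither is cropped to
anatomical boundaries by default: the hull may extend beyond the brain, and
an optional brain-mask crop is provided but off unless requested.

Rasterization rule: a voxel belongs to the hull iff its *center* (in mm
coordinates, index * spacing) lies inside or on the convex hull of the
cavity voxel centers. The expansion ball is closed (distance <= margin), so
a 0 mm margin is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .volumes_io import GridSpec, LabelVolume, assert_same_grid

__all__ = ["TargetVolumes", "convex_hull_mask", "expand_mask", "build_target_volumes"]

# Absolute tie-break tolerance (mm) on distance thresholds; covers floating
# point noise in the distance transform without admitting any lattice point
# that is not genuinely on the boundary.
EPS_MM = 1e-9


class EmptyMaskError(ValueError):
    """An operation requiring foreground received an empty mask."""


@dataclass
class TargetVolumes:
    """CTV and PTV masks plus the margin that produced the PTV."""

    ctv: LabelVolume
    ptv: LabelVolume
    ptv_margin_mm: float
    grid: GridSpec

    def __post_init__(self) -> None:
        assert_same_grid([self.ctv, self.ptv], names=["ctv", "ptv"])
        if self.ptv_margin_mm < 0:
            raise ValueError("ptv_margin_mm must be non-negative")
        if np.any(self.ctv.foreground & ~self.ptv.foreground):
            raise ValueError("ctv must be a subset of ptv")


def _points_mm(mask: LabelVolume) -> np.ndarray:
    spacing = np.asarray(mask.grid.spacing_mm)
    return np.argwhere(mask.foreground) * spacing


def _candidate_box(points: np.ndarray, grid: GridSpec, pad_mm: float = 0.0):
    """Index slices and voxel centers of the bounding box of ``points``."""
    spacing = np.asarray(grid.spacing_mm)
    lo = np.maximum(np.floor((points.min(axis=0) - pad_mm) / spacing), 0).astype(int)
    hi = np.minimum(
        np.ceil((points.max(axis=0) + pad_mm) / spacing), np.asarray(grid.shape) - 1
    ).astype(int)
    axes = [np.arange(lo[a], hi[a] + 1) for a in range(3)]
    idx = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    return lo, hi, idx, idx * spacing


def _hull_tolerance(points: np.ndarray) -> float:
    return 1e-9 * (1.0 + float(np.max(np.abs(points))))


def _segment_distance(centers: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = b - a
    denom = float(d @ d)
    if denom == 0.0:
        return np.linalg.norm(centers - a, axis=1)
    t = np.clip((centers - a) @ d / denom, 0.0, 1.0)
    proj = a + t[:, None] * d
    return np.linalg.norm(centers - proj, axis=1)


def _degenerate_hull_distance(centers: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Distance from each center to the convex hull of a rank < 3 point set."""
    origin = points.mean(axis=0)
    q = points - origin
    # Full SVD so the basis always spans 3D even with < 3 points.
    _, s, vt = np.linalg.svd(q, full_matrices=True)
    scale = max(float(s[0]) if s.size else 0.0, 1.0)
    rank = int(np.sum(s > 1e-9 * scale))
    if rank == 0:
        return np.linalg.norm(centers - origin, axis=1)
    if rank == 1:
        d = vt[0]
        t = q @ d
        a = origin + t.min() * d
        b = origin + t.max() * d
        return _segment_distance(centers, a, b)
    # rank 2: planar polygon. Out-of-plane component plus in-plane distance
    # to the 2D hull boundary (zero for in-plane points inside the polygon).
    basis = vt[:2]
    p2 = q @ basis.T
    rel = centers - origin
    c2 = rel @ basis.T
    out_of_plane = np.linalg.norm(rel - c2 @ basis, axis=1)
    try:
        hull2 = ConvexHull(p2)
    except QhullError:
        # Numerically collinear after all; fall back to the segment case.
        d = vt[0]
        t = q @ d
        return _segment_distance(centers, origin + t.min() * d, origin + t.max() * d)
    tol2 = _hull_tolerance(p2)
    inside2 = np.all(c2 @ hull2.equations[:, :2].T + hull2.equations[:, 2] <= tol2, axis=1)
    verts = p2[hull2.vertices]
    in_plane = np.full(len(centers), np.inf)
    for i in range(len(verts)):
        a2, b2 = verts[i], verts[(i + 1) % len(verts)]
        d = b2 - a2
        denom = float(d @ d)
        t = np.clip((c2 - a2) @ d / max(denom, 1e-300), 0.0, 1.0)
        proj = a2 + t[:, None] * d
        in_plane = np.minimum(in_plane, np.linalg.norm(c2 - proj, axis=1))
    in_plane[inside2] = 0.0
    return np.hypot(out_of_plane, in_plane)


def convex_hull_mask(cavity: LabelVolume) -> LabelVolume:
    """Rasterize the convex hull of a mask's voxel centers.

    A voxel is included iff its center lies inside or on the hull. Cavities
    whose voxel centers are coplanar/collinear (rank < 3) have no 3D hull;
    they are rasterized by distance-to-hull <= half the smallest voxel edge,
    which on any lattice admits exactly the centers lying on the hull itself.
    """
    points = _points_mm(cavity)
    if len(points) == 0:
        raise EmptyMaskError("convex_hull_mask requires a non-empty cavity")
    grid = cavity.grid
    out = np.zeros(grid.shape, dtype=bool)
    try:
        hull = ConvexHull(points)
        degenerate = False
    except QhullError:
        degenerate = True

    if degenerate:
        tol = 0.5 * min(grid.spacing_mm)
        _, _, idx, centers = _candidate_box(points, grid, pad_mm=tol)
        dist = _degenerate_hull_distance(centers, points)
        keep = dist <= tol
    else:
        _, _, idx, centers = _candidate_box(points, grid)
        tol = _hull_tolerance(points)
        normals = hull.equations[:, :3]
        offsets = hull.equations[:, 3]
        keep = np.all(centers @ normals.T + offsets <= tol, axis=1)

    sel = idx[keep]
    out[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    out |= cavity.foreground  # guard against any facet-tolerance exclusion
    return LabelVolume.from_mask(out, grid, name="ctv")


def expand_mask(mask: LabelVolume, margin_mm: float) -> LabelVolume:
    """All voxels whose center lies within ``margin_mm`` of the mask.

    Distances are Euclidean in millimetres between voxel centers, computed
    with an anisotropic-spacing distance transform; the ball is closed, so a
    zero margin returns the mask unchanged. Monotone in ``margin_mm``.
    """
    if margin_mm < 0:
        raise ValueError(f"margin_mm must be >= 0, got {margin_mm}")
    fg = mask.foreground
    name = next(iter(mask.label_map.values()), "mask")
    if margin_mm == 0 or not fg.any():
        return LabelVolume.from_mask(fg.copy(), mask.grid, name=name)
    dist = ndimage.distance_transform_edt(~fg, sampling=mask.grid.spacing_mm)
    return LabelVolume.from_mask(dist <= margin_mm + EPS_MM, mask.grid, name=name)


def build_target_volumes(
    cavity: LabelVolume,
    ptv_margin_mm: float = 5.0,
    brain_mask: Optional[LabelVolume] = None,
    crop_to_brain_mask: bool = False,
) -> TargetVolumes:
    """CTV = convex hull of the cavity; PTV = CTV expanded by the margin.

    Cropping to a brain mask is available but off by default; uncropped
    volumes may extend beyond any anatomical boundary.
    """
    ctv = convex_hull_mask(cavity)
    ptv = expand_mask(ctv, ptv_margin_mm)
    if crop_to_brain_mask:
        if brain_mask is None:
            raise ValueError("crop_to_brain_mask requires a brain_mask")
        assert_same_grid([cavity, brain_mask], names=["cavity", "brain_mask"])
        bm = brain_mask.foreground
        ctv = LabelVolume.from_mask(ctv.foreground & bm, cavity.grid, name="ctv")
        ptv = LabelVolume.from_mask(ptv.foreground & bm, cavity.grid, name="ptv")
    ptv = LabelVolume.from_mask(ptv.foreground, cavity.grid, name="ptv")
    return TargetVolumes(ctv=ctv, ptv=ptv, ptv_margin_mm=ptv_margin_mm, grid=cavity.grid)
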