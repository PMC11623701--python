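"""Unsigned distance maps to structure boundaries and surface point sampling.

The point-to-distance (PD) penalty needs two geometric primitives:

* ``boundary_distance_map``: for a moving-image structure mask, the unsigned
  Euclidean distance (mm) from every voxel center to the nearest *boundary*
  voxel center. "Boundary" means a mask voxel with at least one 6-neighbor
  outside the mask (voxels beyond the grid edge count as outside). The map
  is zero only on the boundary shell — interior voxels carry positive
  distance — so surface points are attracted onto the surface, not merely
  into the structure interior.
* ``sample_surface_points``: a deterministic, seeded subsample of the
  fixed-image structure's boundary voxel centers (the point set Pi_n).

Off-grid sampling of the distance map goes through an interpolating cubic
B-spline of the EDT values; the sampled value is ``|s(p)|`` (the interpolant
can undershoot zero near the boundary) and the gradient is its analytic
derivative, so analytic cost gradients match finite differences. Outside
the grid's bounding box the value continues as (clamped boundary value +
distance to the box), keeping the PD gradient informative when the
optimizer pushes points outside a short CBCT field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._interp import CubicGridSampler
from .errors import GeometryError, ParameterError
from .volumes import BinaryMask, Grid, LabeledPointSet

__all__ = [
    "DistanceMap",
    "SurfacePointSet",
    "boundary_voxels",
    "boundary_distance_map",
    "sample_surface_points",
]

_SIX_CONN = ndimage.generate_binary_structure(3, 1)


def boundary_voxels(mask: BinaryMask | np.ndarray) -> np.ndarray:
    """Boolean array marking mask voxels with a 6-neighbor outside the mask."""
    m = mask.voxels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(m, structure=_SIX_CONN, border_value=0)
    return m & ~eroded


@dataclass
class DistanceMap:
    """Unsigned Euclidean distance (mm) to a structure's boundary surface."""

    values: np.ndarray
    grid: Grid
    structure_name: str = ""
    _sampler: CubicGridSampler | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != tuple(self.grid.size):
            raise GeometryError("distance map shape does not match its grid")
        if not self.grid.has_identity_direction:
            raise GeometryError("distance maps require identity-direction grids")

    def _ensure_sampler(self) -> CubicGridSampler:
        if self._sampler is None:
            self._sampler = CubicGridSampler(self.values)
        return self._sampler

    def sample(self, points) -> tuple[np.ndarray, np.ndarray]:
        """Distance value (mm) and physical gradient (mm/mm) at point(s).

        Inside the grid box: ``|s(p)|`` for the cubic interpolant ``s`` with
        its analytic gradient. Outside: value at the clamped box position
        plus the Euclidean distance to the box; gradient is the unit
        outward vector plus the in-plane (non-clamped) interpolant gradient.
        """
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = pts.reshape(-1, 3)
        spacing = np.asarray(self.grid.spacing)
        u = self.grid.physical_to_voxel(pts)
        n = np.asarray(self.grid.size)
        uc = np.clip(u, 0.0, n - 1.0)
        overshoot_mm = (u - uc) * spacing
        box_dist = np.linalg.norm(overshoot_mm, axis=1)
        outside = box_dist > 0.0

        sampler = self._ensure_sampler()
        raw, grad_units = sampler.sample(uc, gradient=True)
        sign = np.where(raw >= 0.0, 1.0, -1.0)
        value = np.abs(raw)
        grad = sign[:, None] * grad_units / spacing  # physical mm/mm

        if outside.any():
            value[outside] = value[outside] + box_dist[outside]
            unit_out = overshoot_mm[outside] / box_dist[outside, None]
            g = grad[outside]
            g[overshoot_mm[outside] != 0.0] = 0.0  # drop clamped-axis components
            grad[outside] = g + unit_out
        if single:
            return value[0], grad[0]
        return value, grad

    def to_image(self):
        from .volumes import ImageVolume

        return ImageVolume(self.values.copy(), self.grid)


def boundary_distance_map(mask: BinaryMask, structure_name: str | None = None) -> DistanceMap:
    """Exact unsigned EDT (mm) to the mask's boundary voxel centers.

    Anisotropic spacing is honored (``scipy.ndimage.distance_transform_edt``
    with physical sampling). Raises for an empty mask.
    """
    name = structure_name if structure_name is not None else getattr(mask, "structure_name", "")
    if not mask.voxels.any():
        raise ParameterError(f"empty mask for structure {name!r}: no boundary to map")
    boundary = boundary_voxels(mask)
    dist = ndimage.distance_transform_edt(~boundary, sampling=mask.grid.spacing)
    return DistanceMap(dist, mask.grid, structure_name=name or "")


@dataclass
class SurfacePointSet:
    """Sampled boundary points Pi_n of a fixed-image structure, physical mm."""

    structure_name: str
    points: np.ndarray
    source_seed: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return self.points.shape[0]

    def to_point_set(self) -> LabeledPointSet:
        labels = [f"{self.structure_name}_{i}" for i in range(len(self))]
        return LabeledPointSet(labels, self.points, frame="fixed")


def sample_surface_points(
    mask: BinaryMask, max_points: int, seed: int, structure_name: str = ""
) -> SurfacePointSet:
    """Deterministic seeded subsample of boundary voxel centers.

    Boundary voxels are enumerated in lexicographic (C) index order; if more
    than ``max_points``, a uniform subsample without replacement is drawn
    with ``numpy.random.default_rng(seed)`` and returned in sorted index
    order, so the same (mask, max_points, seed) always yields the same set.
    """
    if max_points < 1:
        raise ParameterError(f"max_points must be >= 1, got {max_points}")
    if not mask.voxels.any():
        raise ParameterError(f"empty mask for structure {structure_name!r}")
    idx = np.argwhere(boundary_voxels(mask))  # lexicographic order
    if idx.shape[0] > max_points:
        rng = np.random.default_rng(seed)
        keep = rng.choice(idx.shape[0], size=max_points, replace=False)
        idx = idx[np.sort(keep)]
    pts = mask.grid.voxel_to_physical(idx.astype(float))
    return SurfacePointSet(structure_name=structure_name, points=pts, source_seed=int(seed))
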