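"""Cubic B-spline free-form deformation (FFD).

The transform maps *fixed*-image physical coordinates into *moving*-image
coordinates (pull-back convention): ``T(p) = p + v(p)`` where the
displacement ``v`` is a tensor-product cubic B-spline over a regular
control-point lattice,

    v(p) = sum_j  c_j  B3(u - j),       u = (p - origin) / spacing,

with ``B3`` the centered cubic B-spline. The control grid always covers the
fixed-image extent plus a one-spacing margin so the 4x4x4 support never
leaves the lattice.

The flat parameter vector ``theta`` is ``coefficients.ravel()`` with
coefficient array shape ``(nx, ny, nz, 3)`` in C order — i.e. ordered
``(x, y, z, component)``. This ordering is part of the public contract:
optimizer traces, gradients and serialized transforms all use it.
"""

from __future__ import annotations

import base64
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, sparse


from ._interp import Stencil
from .errors import DomainError, GeometryError, ParameterError
from .volumes import BinaryMask, Grid, ImageVolume

__all__ = ["BSplineTransform"]

_SUPPORT_TOL = 1e-9


def _as_extent(region) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(region, Grid):
        return region.extent
    if isinstance(region, ImageVolume):
        return region.grid.extent
    pmin, pmax = region
    return np.asarray(pmin, dtype=float), np.asarray(pmax, dtype=float)


@dataclass
class BSplineTransform:
    control_origin: np.ndarray
    control_spacing: np.ndarray
    control_size: tuple[int, int, int]
    coefficients: np.ndarray = field(default=None)  # (nx, ny, nz, 3), mm

    def __post_init__(self) -> None:
        self.control_origin = np.asarray(self.control_origin, dtype=float).reshape(3)
        self.control_spacing = np.asarray(self.control_spacing, dtype=float).reshape(3)
        self.control_size = tuple(int(n) for n in self.control_size)
        if np.any(self.control_spacing <= 0):
            raise ParameterError(f"control_spacing must be positive, got {self.control_spacing}")
        if any(n < 4 for n in self.control_size):
            raise ParameterError(f"control_size must be >= 4 per axis, got {self.control_size}")
        if self.coefficients is None:
            self.coefficients = np.zeros(self.control_size + (3,))
        else:
            self.coefficients = np.asarray(self.coefficients, dtype=float)
            if self.coefficients.shape != self.control_size + (3,):
                raise ParameterError(
                    f"coefficients shape {self.coefficients.shape} != {self.control_size + (3,)}"
                )

    # ------------------------------------------------------------------
    # Construction
    # ------------------------------------------------------------------
    @classmethod
    def for_extent(cls, region, control_spacing) -> "BSplineTransform":
        """Identity transform whose lattice covers ``region`` plus a margin.

        ``region`` is a :class:`Grid`, an :class:`ImageVolume` or an
        ``(pmin, pmax)`` pair of physical corners (mm).
        """
        pmin, pmax = _as_extent(region)
        s = np.asarray(control_spacing, dtype=float).reshape(3)
        if np.any(s <= 0):
            raise ParameterError(f"control_spacing must be positive, got {s}")
        origin = pmin - s  # one-spacing margin; u(pmin) = 1
        size = np.ceil((pmax - origin) / s - _SUPPORT_TOL).astype(int) + 3
        size = np.maximum(size, 4)
        return cls(origin, s, tuple(size))

    @property
    def theta(self) -> np.ndarray:
        """Flat parameter vector, ordering (x, y, z, component)."""
        return self.coefficients.ravel()

    @theta.setter
    def theta(self, value) -> None:
        self.coefficients = np.asarray(value, dtype=float).reshape(self.control_size + (3,))

    def with_theta(self, value) -> "BSplineTransform":
        return BSplineTransform(
            self.control_origin,
            self.control_spacing,
            self.control_size,
            np.asarray(value, dtype=float).reshape(self.control_size + (3,)),
        )

    # ------------------------------------------------------------------
    # Evaluation
    # ------------------------------------------------------------------
    def to_lattice_units(self, points: np.ndarray, check: bool = True) -> np.ndarray:
        u = (np.asarray(points, dtype=float).reshape(-1, 3) - self.control_origin) / self.control_spacing
        if check:
            n = np.asarray(self.control_size)
            bad = (u < 1.0 - _SUPPORT_TOL) | (u > (n - 2) + _SUPPORT_TOL)
            if bad.any():
                p = np.asarray(points, dtype=float).reshape(-1, 3)[bad.any(axis=1)][0]
                raise DomainError(
                    f"point {tuple(p)} lies outside the supported region of the control grid"
                )
        return u

    def stencil(self, points: np.ndarray, orders=(0,)) -> Stencil:
        u = self.to_lattice_units(points)
        return Stencil(u, self.control_size, orders=orders)

    def displacement(self, points) -> np.ndarray:
        """Displacement (mm) at physical point(s); (3,) in, (3,) out."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        st = self.stencil(pts.reshape(-1, 3))
        disp = st.evaluate(self.coefficients.reshape(-1, 3))
        return disp[0] if single else disp

    def transform_point(self, points) -> np.ndarray:
        """Map fixed-space position(s) into moving space: ``p + v(p)``."""
        pts = np.asarray(points, dtype=float)
        return pts + self.displacement(pts)

    # ------------------------------------------------------------------
    # Warping
    # ------------------------------------------------------------------
    def warp_image(
        self,
        moving: ImageVolume,
        reference: Grid,
        interp: str = "linear",
        fill: float = 0.0,
    ) -> ImageVolume | BinaryMask:
        """Pull-back warp: output voxel at p takes ``moving(T(p))``.

        ``reference`` must have an identity direction matrix; samples whose
        transformed position leaves the moving grid take ``fill``.
        """
        if not reference.has_identity_direction:
            raise GeometryError("warp_image requires an identity-direction reference grid")
        if interp not in ("linear", "nearest"):
            raise ParameterError(f"interp must be 'linear' or 'nearest', got {interp!r}")
        is_mask = isinstance(moving, BinaryMask)
        if is_mask and interp != "nearest":
            raise ParameterError("binary masks must be warped with nearest interpolation")
        pts = reference.voxel_centers()
        mapped = self.transform_point(pts)
        idx = moving.grid.physical_to_voxel(mapped)
        n = np.asarray(moving.grid.size)
        inside = np.all((idx >= 0.0) & (idx <= n - 1), axis=1)
        order = 1 if interp == "linear" else 0
        values = ndimage.map_coordinates(
            moving.voxels.astype(np.float64, copy=False), idx.T, order=order, mode="nearest"
        )
        values[~inside] = fill
        out = values.reshape(reference.size)
        if is_mask:
            return BinaryMask(out > 0.5, reference)
        return ImageVolume(out, reference)

    # ------------------------------------------------------------------
    # Refinement between pyramid levels
    # ------------------------------------------------------------------
    def refine(self, new_spacing, fixed_extent) -> "BSplineTransform":
        """Re-express the displacement field on a finer control lattice.

        Exactly-halved spacing uses the dyadic two-scale relation of the
        cubic B-spline (reproduces the field to machine precision);
        otherwise the fine coefficients are fit by linear least squares to
        the coarse displacements sampled on the fine lattice (plus midpoints
        for a well-determined fit). Equal spacing returns a copy.
        """
        new_spacing = np.asarray(new_spacing, dtype=float).reshape(3)
        if np.any(new_spacing > self.control_spacing + _SUPPORT_TOL):
            raise ParameterError(
                f"refine requires new_spacing <= old per axis ({new_spacing} vs {self.control_spacing})"
            )
        if np.allclose(new_spacing, self.control_spacing, rtol=1e-12, atol=1e-12):
            return BSplineTransform(
                self.control_origin, self.control_spacing, self.control_size, self.coefficients.copy()
            )
        if np.allclose(2.0 * new_spacing, self.control_spacing, rtol=1e-12, atol=1e-12):
            return self._refine_dyadic(fixed_extent)
        return self._refine_lsq(new_spacing, fixed_extent)

    def _refine_dyadic(self, fixed_extent) -> "BSplineTransform":
        pmin, pmax = _as_extent(fixed_extent)
        s_f = self.control_spacing / 2.0
        # fine lattice indexed on the coarse half-lattice: position o + j * s_f
        j0 = np.floor((pmin - self.control_origin) / s_f).astype(int) - 1
        m = np.ceil((pmax - (self.control_origin + j0 * s_f)) / s_f - _SUPPORT_TOL).astype(int) + 3
        m = np.maximum(m, 4)
        coef = self.coefficients
        for axis in range(3):
            coef = _dyadic_subdivide_axis(coef, axis, int(j0[axis]), int(m[axis]))
        return BSplineTransform(self.control_origin + j0 * s_f, s_f, tuple(m), coef)

    def _refine_lsq(self, new_spacing, fixed_extent) -> "BSplineTransform":
        fine = BSplineTransform.for_extent(fixed_extent, new_spacing)
        # sample the coarse field on the fine lattice and its midpoints,
        # restricted to where both lattices have full support
        axes = [np.arange(1.0, n - 2 + 0.5, 0.5) for n in fine.control_size]
        uf = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        pts = fine.control_origin + uf * fine.control_spacing
        uc = (pts - self.control_origin) / self.control_spacing
        nc = np.asarray(self.control_size)
        ok = np.all((uc >= 1.0) & (uc <= nc - 2), axis=1)
        pts = pts[ok]
        target = self.displacement(pts)
        st = fine.stencil(pts)
        npts = pts.shape[0]
        ncoef = int(np.prod(fine.control_size))
        rows = np.repeat(np.arange(npts, dtype=np.int64), 64)
        cols = np.empty(npts * 64, dtype=np.int64)
        data = np.empty(npts * 64)
        for tap, (off, w) in enumerate(st._weights((0, 0, 0))):
            cols[tap::64] = st._flat_base + off
            data[tap::64] = w
        a = sparse.csr_matrix((data, (rows, cols)), shape=(npts, ncoef))
        # normal equations with a tiny ridge: columns for margin control
        # points barely touched by the sample set would otherwise make the
        # system singular; the 1e-9 bias is far below displacement accuracy
        ata = (a.T @ a + 1e-9 * sparse.eye(ncoef)).tocsc()
        solve = sparse.linalg.factorized(ata)
        coef = np.column_stack([solve(a.T @ target[:, c]) for c in range(3)])
        fine.coefficients = coef.reshape(fine.control_size + (3,))
        return fine

    # ------------------------------------------------------------------
    # Serialization
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        blob = base64.b64encode(np.ascontiguousarray(self.coefficients, dtype="<f8").tobytes())
        return {
            "format": "hybridir-bspline-transform-v1",
            "control_origin": [float(v) for v in self.control_origin],
            "control_spacing": [float(v) for v in self.control_spacing],
            "control_size": list(self.control_size),
            "coefficients_b64": blob.decode("ascii"),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BSplineTransform":
        if d.get("format") != "hybridir-bspline-transform-v1":
            raise ParameterError("not a hybridir B-spline transform record")
        size = tuple(int(n) for n in d["control_size"])
        coef = np.frombuffer(base64.b64decode(d["coefficients_b64"]), dtype="<f8")
        coef = coef.reshape(size + (3,)).copy()
        return cls(d["control_origin"], d["control_spacing"], size, coef)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "BSplineTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def displacement_field(self, grid: Grid) -> np.ndarray:
        """Dense displacement field sampled at ``grid`` voxel centers: (nx,ny,nz,3)."""
        disp = self.displacement(grid.voxel_centers())
        return disp.reshape(tuple(grid.size) + (3,))

    def export_displacement_field(self, grid: Grid, path) -> None:
        """Write the dense field as a 3-component vector NIfTI/MetaImage."""
        import SimpleITK as sitk

        field_arr = self.displacement_field(grid)
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(field_arr.transpose(2, 1, 0, 3)), isVector=True
        )
        img.SetSpacing(tuple(float(s) for s in grid.spacing))
        img.SetOrigin(tuple(float(o) for o in grid.origin))
        img.SetDirection(tuple(np.asarray(grid.direction, dtype=float).ravel()))
        sitk.WriteImage(img, str(path))


def _take_or_zero(arr: np.ndarray, idx: np.ndarray, axis: int) -> np.ndarray:
    """``np.take`` along ``axis`` with out-of-range indices yielding zeros."""
    n = arr.shape[axis]
    valid = (idx >= 0) & (idx < n)
    out = np.take(arr, np.clip(idx, 0, n - 1), axis=axis)
    if not valid.all():
        shape = [1] * out.ndim
        shape[axis] = len(idx)
        out = out * valid.reshape(shape)
    return out


def _dyadic_subdivide_axis(coef: np.ndarray, axis: int, j0: int, m: int) -> np.ndarray:
    """Two-scale refinement along one axis.

    Coarse coefficients ``c_i`` sit at even fine indices ``2i``; the fine
    coefficients on indices ``j0 .. j0+m-1`` follow the (1,4,6,4,1)/8 mask:
    ``c'_{2i} = (c_{i-1} + 6 c_i + c_{i+1}) / 8``,
    ``c'_{2i+1} = (c_i + c_{i+1}) / 2``, with zero coefficients outside the
    coarse lattice.
    """
    js = np.arange(j0, j0 + m)
    even = js % 2 == 0
    out_shape = list(coef.shape)
    out_shape[axis] = m
    out = np.zeros(out_shape)

    ie = js[even] // 2
    ev = (
        _take_or_zero(coef, ie - 1, axis)
        + 6.0 * _take_or_zero(coef, ie, axis)
        + _take_or_zero(coef, ie + 1, axis)
    ) / 8.0
    io = (js[~even] - 1) // 2
    od = (_take_or_zero(coef, io, axis) + _take_or_zero(coef, io + 1, axis)) / 2.0

    idx_even = np.nonzero(even)[0]
    idx_odd = np.nonzero(~even)[0]
    sl = [slice(None)] * out.ndim
    sl[axis] = idx_even
    out[tuple(sl)] = ev
    sl[axis] = idx_odd
    out[tuple(sl)] = od
    return out
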