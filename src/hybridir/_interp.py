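"""Shared uniform cubic B-spline machinery.

Two consumers: the free-form-deformation transform (coefficients on a coarse
control grid, displacement in mm) and the image/distance-map sampler
(interpolating spline through grid values, prefiltered coefficients). Both
use the same 4-point stencil and basis polynomials, so the gather/scatter
kernels live here. Hot loops are JIT-compiled with numba when available;
the numpy code paths are the reference implementation and the fallback.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

try:
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "bspline_basis",
    "bspline_basis_d1",
    "bspline_basis_d2",
    "Stencil",
    "CubicGridSampler",
]


def bspline_basis(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline weights for local coordinate ``t`` in [0, 1]: (N, 4)."""
    t = np.asarray(t, dtype=float)
    t2 = t * t
    t3 = t2 * t
    return np.stack(
        [
            (1.0 - t) ** 3 / 6.0,
            (3.0 * t3 - 6.0 * t2 + 4.0) / 6.0,
            (-3.0 * t3 + 3.0 * t2 + 3.0 * t + 1.0) / 6.0,
            t3 / 6.0,
        ],
        axis=-1,
    )


def bspline_basis_d1(t: np.ndarray) -> np.ndarray:
    """First derivatives of the cubic basis w.r.t. ``t``: (N, 4)."""
    t = np.asarray(t, dtype=float)
    t2 = t * t
    return np.stack(
        [
            -((1.0 - t) ** 2) / 2.0,
            (3.0 * t2 - 4.0 * t) / 2.0,
            (-3.0 * t2 + 2.0 * t + 1.0) / 2.0,
            t2 / 2.0,
        ],
        axis=-1,
    )


def bspline_basis_d2(t: np.ndarray) -> np.ndarray:
    """Second derivatives of the cubic basis w.r.t. ``t``: (N, 4)."""
    t = np.asarray(t, dtype=float)
    return np.stack([1.0 - t, 3.0 * t - 2.0, 1.0 - 3.0 * t, t], axis=-1)


_BASIS_BY_ORDER = {0: bspline_basis, 1: bspline_basis_d1, 2: bspline_basis_d2}


if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _eval_kernel(cf, flat_base, offsets, tab, om, out):
        # cf (M, C); tab (O, N, 3, 4); om (R, 3) order-slot map; out (R, N, C)
        npts = flat_base.shape[0]
        nr = om.shape[0]
        nc = cf.shape[1]
        for p in range(npts):
            fb = flat_base[p]
            o = 0
            for l in range(4):
                for m in range(4):
                    for k in range(4):
                        idx = fb + offsets[o]
                        for r in range(nr):
                            w = (
                                tab[om[r, 0], p, 0, l]
                                * tab[om[r, 1], p, 1, m]
                                * tab[om[r, 2], p, 2, k]
                            )
                            for c in range(nc):
                                out[r, p, c] += w * cf[idx, c]
                        o += 1

    @numba.njit(cache=True)
    def _scatter_kernel(vals, flat_base, offsets, tab, om, out):
        # vals (R, N, C); out (M, C)
        npts = flat_base.shape[0]
        nr = om.shape[0]
        nc = vals.shape[2]
        for p in range(npts):
            fb = flat_base[p]
            o = 0
            for l in range(4):
                for m in range(4):
                    for k in range(4):
                        idx = fb + offsets[o]
                        for r in range(nr):
                            w = (
                                tab[om[r, 0], p, 0, l]
                                * tab[om[r, 1], p, 1, m]
                                * tab[om[r, 2], p, 2, k]
                            )
                            for c in range(nc):
                                out[idx, c] += w * vals[r, p, c]
                        o += 1

    @numba.njit(cache=True)
    def _sample_grad_kernel(cf, flat_base, offsets, b, d, out):
        # scalar field value + 3 first derivatives; b/d (N, 3, 4); out (N, 4)
        npts = flat_base.shape[0]
        for p in range(npts):
            fb = flat_base[p]
            o = 0
            for l in range(4):
                bx = b[p, 0, l]
                dx = d[p, 0, l]
                for m in range(4):
                    by = b[p, 1, m]
                    dy = d[p, 1, m]
                    pbb = bx * by
                    pdb = dx * by
                    pbd = bx * dy
                    for k in range(4):
                        c = cf[fb + offsets[o]]
                        bz = b[p, 2, k]
                        out[p, 0] += pbb * bz * c
                        out[p, 1] += pdb * bz * c
                        out[p, 2] += pbd * bz * c
                        out[p, 3] += pbb * d[p, 2, k] * c
                        o += 1


class Stencil:
    """Precomputed 4x4x4 stencil data for a batch of points on a lattice.

    ``base`` holds the first stencil index per axis (i-1 of the classic
    i-1..i+2 neighborhood); per-axis basis rows for the requested derivative
    orders are precomputed at construction. The lattice is addressed in
    *grid units* (index coordinates); physical scaling of derivatives is the
    caller's concern.
    """

    def __init__(self, u: np.ndarray, shape: tuple[int, int, int], orders=(0,)):
        u = np.asarray(u, dtype=float).reshape(-1, 3)
        n = np.asarray(shape)
        i = np.floor(u).astype(np.int64)
        # keep t in [0, 1]: points exactly at the top of the valid range get
        # the last full stencil with t = 1
        i = np.minimum(i, n - 3)
        i = np.maximum(i, 1)
        t = u - i
        self.shape = tuple(int(s) for s in shape)
        self.npoints = u.shape[0]
        self.base = i - 1  # (N, 3), first index of the 4-stencil per axis
        self.t = t
        self.orders = tuple(orders)
        self._slot = {order: s for s, order in enumerate(self.orders)}
        tables = [
            np.stack([_BASIS_BY_ORDER[order](t[:, a]) for a in range(3)], axis=1)
            for order in self.orders
        ]
        self.tables = {order: tab for order, tab in zip(self.orders, tables)}
        self._tab = np.ascontiguousarray(np.stack(tables)) if tables else None
        ny, nz = self.shape[1], self.shape[2]
        self._flat_base = (self.base[:, 0] * ny + self.base[:, 1]) * nz + self.base[:, 2]
        self._offsets = np.array(
            [(l * ny + m) * nz + k for l in range(4) for m in range(4) for k in range(4)],
            dtype=np.int64,
        )

    def _order_map(self, orders_list) -> np.ndarray:
        return np.array(
            [[self._slot[o] for o in orders] for orders in orders_list], dtype=np.int64
        )

    def _weights(self, axis_orders: tuple[int, int, int]):
        """Yield (flat offset, per-point weight vector) over the 64 stencil taps."""
        bx = self.tables[axis_orders[0]][:, 0, :]
        by = self.tables[axis_orders[1]][:, 1, :]
        bz = self.tables[axis_orders[2]][:, 2, :]
        o = 0
        for l in range(4):
            wx = bx[:, l]
            for m in range(4):
                wxy = wx * by[:, m]
                for k in range(4):
                    yield self._offsets[o], wxy * bz[:, k]
                    o += 1

    def evaluate(self, coef_flat: np.ndarray, axis_orders=(0, 0, 0)) -> np.ndarray:
        """Tensor-product spline sum: (N, C) for coefficients (M, C) or (N,) for (M,)."""
        return self.evaluate_multi(coef_flat, [axis_orders])[0]

    def evaluate_multi(self, coef_flat: np.ndarray, orders_list) -> list[np.ndarray]:
        """Evaluate several derivative combinations in one coefficient-gather pass."""
        scalar = coef_flat.ndim == 1
        cf = coef_flat[:, None] if scalar else coef_flat
        if _HAVE_NUMBA:
            cf = np.ascontiguousarray(cf, dtype=np.float64)
            out = np.zeros((len(orders_list), self.npoints, cf.shape[1]))
            _eval_kernel(
                cf, self._flat_base, self._offsets, self._tab, self._order_map(orders_list), out
            )
            return [out[r, :, 0] if scalar else out[r] for r in range(len(orders_list))]
        outs = [np.zeros((self.npoints, cf.shape[1])) for _ in orders_list]
        for out, orders in zip(outs, orders_list):
            for off, w in self._weights(orders):
                out += w[:, None] * cf[self._flat_base + off]
        return [out[:, 0] if scalar else out for out in outs]

    def scatter(self, values: np.ndarray, out_flat: np.ndarray, axis_orders=(0, 0, 0)) -> None:
        """Accumulate ``sum_p w_p(tap) * values[p]`` into ``out_flat`` (M, C)."""
        self.scatter_multi([values], [axis_orders], out_flat)

    def scatter_multi(self, values_list, orders_list, out_flat: np.ndarray) -> None:
        """Scatter several weighted point-vector fields in one pass."""
        vals = [v[:, None] if v.ndim == 1 else v for v in values_list]
        if _HAVE_NUMBA:
            stacked = np.ascontiguousarray(np.stack(vals), dtype=np.float64)
            _scatter_kernel(
                stacked,
                self._flat_base,
                self._offsets,
                self._tab,
                self._order_map(orders_list),
                out_flat,
            )
            return
        m = out_flat.shape[0]
        for v, orders in zip(vals, orders_list):
            for off, w in self._weights(orders):
                idx = self._flat_base + off
                for c in range(v.shape[1]):
                    out_flat[:, c] += np.bincount(idx, weights=w * v[:, c], minlength=m)


class CubicGridSampler:
    """Interpolating cubic B-spline sampler over a regular grid of values.

    Prefilters the values once (mirror boundary) so evaluation reproduces
    the grid values exactly at voxel centers, then evaluates value and
    analytic gradient at arbitrary continuous indices in ``[0, n-1]`` per
    axis. Indices are expressed in grid units; gradients are returned in
    grid units too (divide by spacing for physical derivatives).
    """

    PAD = 2

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=np.float64)
        coef = ndimage.spline_filter(values, order=3, mode="mirror")
        self.coef = np.pad(coef, self.PAD, mode="reflect")
        self.shape = values.shape
        self._flat = np.ascontiguousarray(self.coef.reshape(-1))

    def sample(self, u: np.ndarray, gradient: bool = False):
        """Value (and optionally grid-unit gradient) at continuous indices (N, 3).

        Indices must lie in ``[0, n-1]`` per axis (callers clamp first).
        """
        u = np.asarray(u, dtype=float).reshape(-1, 3)
        upad = u + self.PAD
        st = Stencil(upad, self.coef.shape, orders=(0, 1) if gradient else (0,))
        if not gradient:
            return st.evaluate(self._flat)
        if _HAVE_NUMBA:
            out = np.zeros((st.npoints, 4))
            _sample_grad_kernel(
                self._flat, st._flat_base, st._offsets, st.tables[0], st.tables[1], out
            )
            return out[:, 0], out[:, 1:]
        val, gx, gy, gz = st.evaluate_multi(
            self._flat, [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)]
        )
        return val, np.stack([gx, gy, gz], axis=1)
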