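"""The hybrid registration cost and its analytic gradient.

    C(theta) = Psi(f, m ∘ T) + lambda * S(v) + sum_n eta_n sum_{pi in Pi_n} dmap_n(T(pi))

* ``Psi`` — mean squared intensity difference over the fixed voxels (inside
  an optional domain mask) whose transformed position lands inside the
  moving grid, normalized by the amount of contributing volume so the
  weights keep their meaning across resolutions. Contributions are feathered
  to zero over the outermost voxel of the moving grid with a C^2 smoothstep
  window (the window's derivative is part of the analytic gradient):
  a hard in/out cut would make the cost discontinuous in theta whenever
  sample points cross the moving-image border — at matched grids that is
  *every* edge voxel at the identity — and stall the line search.
* ``S(v)`` — bending energy of the displacement field: the mean over sample
  points of the squared Frobenius norm of the displacement Hessian,
  ``sum_c v_c,xx^2 + v_c,yy^2 + v_c,zz^2 + 2(v_c,xy^2 + v_c,xz^2 + v_c,yz^2)``,
  with second derivatives analytic in the cubic basis.
* PD term — for each structure, the sum of the moving image's unsigned
  boundary distance map sampled at the transformed fixed surface points,
  scaled by the per-structure weight ``eta_n``.

All three gradients are exact derivatives of the returned values (the
moving image and the distance maps are sampled with interpolating cubic
splines, so values are C^2 in theta away from the domain edge and the
distance map's zero set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._interp import CubicGridSampler
from .bspline import BSplineTransform
from .distance_fields import DistanceMap, SurfacePointSet
from .errors import ConfigurationError, DegenerateOverlapError, ParameterError
from .volumes import BinaryMask, Grid, ImageVolume

__all__ = [
    "CostWeights",
    "CostBreakdown",
    "HybridCostFunction",
    "intensity_term",
    "curvature_term",
    "pd_term",
    "total_cost",
]

# (axis derivative orders, multiplicity) of the bending-energy quadratic form
_HESSIAN_KINDS = (
    ((2, 0, 0), 1.0),
    ((0, 2, 0), 1.0),
    ((0, 0, 2), 1.0),
    ((1, 1, 0), 2.0),
    ((1, 0, 1), 2.0),
    ((0, 1, 1), 2.0),
)


@dataclass
class CostWeights:
    """lambda (curvature weight) and per-structure eta (PD weights)."""

    lambda_reg: float = 1.0e5
    eta: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lambda_reg = float(self.lambda_reg)
        self.eta = {str(k): float(v) for k, v in self.eta.items()}
        if not np.isfinite(self.lambda_reg) or self.lambda_reg < 0:
            raise ParameterError(f"lambda_reg must be finite and >= 0, got {self.lambda_reg}")
        for name, value in self.eta.items():
            if not np.isfinite(value) or value < 0:
                raise ParameterError(f"eta[{name!r}] must be finite and >= 0, got {value}")


@dataclass
class CostBreakdown:
    """One evaluation of the hybrid cost, term by term.

    ``regularization`` and the ``pd_per_structure`` entries are already
    scaled by lambda and eta respectively; ``total`` is their sum with the
    intensity term. ``gradient`` is flat in theta ordering.
    """

    intensity: float
    regularization: float
    pd_per_structure: dict[str, float]
    total: float
    gradient: np.ndarray | None = None

    @property
    def pd_total(self) -> float:
        return float(sum(self.pd_per_structure.values()))


class HybridCostFunction:
    """Reusable evaluator of the hybrid cost for a fixed problem setup.

    Precomputes everything that does not depend on theta (fixed voxel
    positions and values, transform stencils at fixed voxels / curvature
    sample points / surface points, the moving-image spline) so repeated
    evaluations during optimization only gather, sample and scatter.
    """

    def __init__(
        self,
        fixed: ImageVolume,
        moving: ImageVolume,
        transform: BSplineTransform,
        weights: CostWeights,
        surface_points: dict[str, SurfacePointSet] | None = None,
        distance_maps: dict[str, DistanceMap] | None = None,
        domain: BinaryMask | None = None,
        curvature_step: int = 2,
    ):
        surface_points = surface_points or {}
        distance_maps = distance_maps or {}
        active = {n for n, e in weights.eta.items() if e > 0}
        if active:
            missing = sorted((active - set(surface_points)) | (active - set(distance_maps)))
            if missing:
                raise ConfigurationError(
                    "structures with nonzero eta lack surface points or distance maps: "
                    + ", ".join(missing)
                )
        extra = sorted(set(surface_points) ^ set(distance_maps))
        if extra:
            raise ConfigurationError(
                "surface point sets and distance maps disagree on structures: " + ", ".join(extra)
            )
        if not fixed.grid.has_identity_direction or not moving.grid.has_identity_direction:
            raise ConfigurationError("hybrid cost requires identity direction matrices")
        if domain is not None and not domain.grid.same_as(fixed.grid):
            raise ConfigurationError("domain mask must share the fixed image grid")

        self.transform = transform
        self.weights = weights
        self.ntheta = transform.theta.size

        # --- intensity term precomputation ---
        if domain is not None:
            sel = domain.voxels.reshape(-1)
            all_pts = fixed.grid.voxel_centers()
            self._fixed_pts = all_pts[sel]
            self._fixed_vals = fixed.voxels.reshape(-1)[sel].astype(np.float64)
        else:
            self._fixed_pts = fixed.grid.voxel_centers()
            self._fixed_vals = fixed.voxels.reshape(-1).astype(np.float64)
        self._st_intensity = transform.stencil(self._fixed_pts)
        self._moving_sampler = CubicGridSampler(moving.voxels)
        self._moving_grid = moving.grid
        self._moving_n = np.asarray(moving.grid.size, dtype=float)
        self._moving_spacing = np.asarray(moving.grid.spacing)

        # --- curvature term precomputation ---
        curv_pts = fixed.grid.voxel_centers(step=max(1, int(curvature_step)))
        self._st_curv = transform.stencil(curv_pts, orders=(0, 1, 2))
        self._curv_n = curv_pts.shape[0]
        s = np.asarray(transform.control_spacing)
        self._curv_scales = [
            1.0 / (s[0] ** o[0] * s[1] ** o[1] * s[2] ** o[2]) for o, _ in _HESSIAN_KINDS
        ]

        # --- PD term precomputation ---
        self._pd: dict[str, tuple] = {}
        for name in surface_points:
            sp = surface_points[name]
            if len(sp) == 0:
                raise ParameterError(f"empty surface point set for structure {name!r}")
            st = transform.stencil(sp.points)
            self._pd[name] = (sp.points, st, distance_maps[name])

    # ------------------------------------------------------------------
    def _coef_flat(self, theta) -> np.ndarray:
        return np.asarray(theta, dtype=float).reshape(-1, 3)

    FEATHER_VOXELS = 1.0  # width of the border window, in moving voxels

    def _border_window(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """C^2 smoothstep window over the moving grid and its du-gradient.

        Weight is 1 in the interior, rolls off to 0 across the outermost
        ``FEATHER_VOXELS`` of the grid, and is 0 outside. Returns (w, dw/du)
        with u in moving voxel units.
        """
        f = self.FEATHER_VOXELS
        edge = np.minimum(u, (self._moving_n - 1.0) - u)  # distance to box, voxels
        t = np.clip(edge / f, 0.0, 1.0)
        ramp = t * t * t * (10.0 + t * (-15.0 + 6.0 * t))
        dramp = 30.0 * t * t * (1.0 - t) ** 2 / f
        dramp = dramp * np.where(u < 0.5 * (self._moving_n - 1.0), 1.0, -1.0)
        dramp[edge < 0.0] = 0.0
        ramp[edge < 0.0] = 0.0
        w = ramp[:, 0] * ramp[:, 1] * ramp[:, 2]
        dw = np.empty_like(u)
        dw[:, 0] = dramp[:, 0] * ramp[:, 1] * ramp[:, 2]
        dw[:, 1] = ramp[:, 0] * dramp[:, 1] * ramp[:, 2]
        dw[:, 2] = ramp[:, 0] * ramp[:, 1] * dramp[:, 2]
        return w, dw

    def intensity(self, theta) -> tuple[float, np.ndarray]:
        cf = self._coef_flat(theta)
        disp = self._st_intensity.evaluate(cf)
        mapped = self._fixed_pts + disp
        u = self._moving_grid.physical_to_voxel(mapped)
        w, dw = self._border_window(u)
        wsum = float(w.sum())
        if wsum <= 1e-9:
            raise DegenerateOverlapError("no fixed voxel maps inside the moving image domain")
        uc = np.clip(u, 0.0, self._moving_n - 1.0)
        mvals, mgrad_units = self._moving_sampler.sample(uc, gradient=True)
        residual = np.where(w > 0.0, mvals - self._fixed_vals, 0.0)
        r2 = residual * residual
        s = float(w @ r2)
        value = s / wsum
        # d(value) = sum_p [ 2 w r grad_m + (r^2 - value) dw ] / wsum
        dw_phys = dw / self._moving_spacing
        back = (
            (2.0 / wsum) * (w * residual)[:, None] * (mgrad_units / self._moving_spacing)
            + ((r2 - value) / wsum)[:, None] * dw_phys
        )
        grad = np.zeros((cf.shape[0], 3))
        self._st_intensity.scatter(back, grad)
        return value, grad.ravel()

    def curvature(self, theta) -> tuple[float, np.ndarray]:
        lam = self.weights.lambda_reg
        cf = self._coef_flat(theta)
        orders_list = [o for o, _ in _HESSIAN_KINDS]
        derivs = self._st_curv.evaluate_multi(cf, orders_list)
        value = 0.0
        for (_, mult), scale, v in zip(_HESSIAN_KINDS, self._curv_scales, derivs):
            v *= scale
            value += mult * float(np.sum(v * v))
        value *= lam / self._curv_n
        grad = np.zeros((cf.shape[0], 3))
        if lam > 0.0:
            backs = [
                (2.0 * lam * mult * scale / self._curv_n) * v
                for (_, mult), scale, v in zip(_HESSIAN_KINDS, self._curv_scales, derivs)
            ]
            self._st_curv.scatter_multi(backs, orders_list, grad)
        return value, grad.ravel()

    def pd_structure(self, theta, name: str) -> tuple[float, np.ndarray]:
        eta = self.weights.eta.get(name, 0.0)
        cf = self._coef_flat(theta)
        grad = np.zeros((cf.shape[0], 3))
        if eta == 0.0:
            return 0.0, grad.ravel()
        pts, st, dmap = self._pd[name]
        mapped = pts + st.evaluate(cf)
        values, dgrad = dmap.sample(mapped)
        st.scatter(eta * dgrad, grad)
        return eta * float(values.sum()), grad.ravel()

    def evaluate(self, theta, with_gradient: bool = True) -> CostBreakdown:
        i_val, i_grad = self.intensity(theta)
        r_val, r_grad = self.curvature(theta)
        pd_vals: dict[str, float] = {}
        grad = i_grad + r_grad
        for name in self._pd:
            v, g = self.pd_structure(theta, name)
            pd_vals[name] = v
            grad = grad + g
        total = i_val + r_val + sum(pd_vals.values())
        return CostBreakdown(
            intensity=i_val,
            regularization=r_val,
            pd_per_structure=pd_vals,
            total=total,
            gradient=grad if with_gradient else None,
        )

    def __call__(self, theta) -> tuple[float, np.ndarray]:
        bd = self.evaluate(theta)
        return bd.total, bd.gradient


# ---------------------------------------------------------------------------
# Spec-level single-shot operations (thin wrappers over HybridCostFunction)
# ---------------------------------------------------------------------------

def intensity_term(
    fixed: ImageVolume,
    moving: ImageVolume,
    transform: BSplineTransform,
    domain: BinaryMask | None = None,
) -> tuple[float, np.ndarray]:
    """Mean-squared-difference similarity and its gradient w.r.t. theta."""
    fn = HybridCostFunction(fixed, moving, transform, CostWeights(lambda_reg=0.0), domain=domain)
    return fn.intensity(transform.theta)


def curvature_term(
    transform: BSplineTransform,
    sample_grid: Grid,
    lambda_reg: float,
    curvature_step: int = 1,
) -> tuple[float, np.ndarray]:
    """Bending energy (scaled by lambda) and its gradient w.r.t. theta."""
    pts = sample_grid.voxel_centers(step=max(1, int(curvature_step)))
    st = transform.stencil(pts, orders=(0, 1, 2))
    s = np.asarray(transform.control_spacing)
    cf = transform.coefficients.reshape(-1, 3)
    value = 0.0
    derivs = []
    scales = []
    for orders, mult in _HESSIAN_KINDS:
        scale = 1.0 / (s[0] ** orders[0] * s[1] ** orders[1] * s[2] ** orders[2])
        v = st.evaluate(cf, axis_orders=orders) * scale
        derivs.append(v)
        scales.append(scale)
        value += mult * float(np.sum(v * v))
    n = pts.shape[0]
    value *= lambda_reg / n
    grad = np.zeros_like(cf)
    if lambda_reg > 0:
        for (orders, mult), scale, v in zip(_HESSIAN_KINDS, scales, derivs):
            st.scatter((2.0 * lambda_reg * mult * scale / n) * v, grad, axis_orders=orders)
    return value, grad.ravel()


def pd_term(
    transform: BSplineTransform,
    points: SurfacePointSet,
    dmap: DistanceMap,
    eta_n: float,
) -> tuple[float, np.ndarray]:
    """Point-to-distance penalty for one structure and its gradient."""
    if len(points) == 0:
        raise ParameterError("empty surface point set")
    cf = transform.coefficients.reshape(-1, 3)
    grad = np.zeros_like(cf)
    if eta_n == 0.0:
        return 0.0, grad.ravel()
    st = transform.stencil(points.points)
    mapped = points.points + st.evaluate(cf)
    values, dgrad = dmap.sample(mapped)
    st.scatter(eta_n * dgrad, grad)
    return eta_n * float(values.sum()), grad.ravel()


def total_cost(
    fixed: ImageVolume,
    moving: ImageVolume,
    transform: BSplineTransform,
    structures_fixed: dict[str, SurfacePointSet] | None,
    dmaps_moving: dict[str, DistanceMap] | None,
    weights: CostWeights,
    domain: BinaryMask | None = None,
    curvature_step: int = 2,
) -> CostBreakdown:
    """Full Eq.-style cost breakdown with gradient at ``transform.theta``."""
    fn = HybridCostFunction(
        fixed,
        moving,
        transform,
        weights,
        surface_points=structures_fixed,
        distance_maps=dmaps_moving,
        domain=domain,
        curvature_step=curvature_step,
    )
    return fn.evaluate(transform.theta)
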