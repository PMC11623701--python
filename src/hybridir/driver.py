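"""Multi-resolution quasi-Newton optimization of the hybrid cost.

Per pyramid level the fixed and moving images are Gaussian-smoothed and
subsampled, the moving structures' distance maps and the fixed structures'
surface points are rebuilt from full-resolution masks (nearest-neighbor
resampled to the level grid), and the B-spline coefficients are optimized
with L-BFGS-B (no bounds). Between levels the transform is carried over by
exact dyadic subdivision (or a least-squares fit for non-dyadic spacing
changes). Runs are deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage, optimize

from .bspline import BSplineTransform
from .distance_fields import boundary_distance_map, sample_surface_points
from .errors import ConfigurationError, ParameterError
from .hybrid_cost import CostBreakdown, CostWeights, HybridCostFunction
from .volumes import BinaryMask, Grid, ImageVolume, resample

__all__ = [
    "PyramidLevel",
    "RegistrationConfig",
    "RegistrationResult",
    "build_pyramid",
    "register",
]

WORKFLOWS = ("no_pd", "pd")


@dataclass
class PyramidLevel:
    shrink: int = 1
    control_spacing: tuple[float, float, float] = (10.0, 10.0, 10.0)
    max_iterations: int = 50

    def __post_init__(self) -> None:
        self.shrink = int(self.shrink)
        cs = self.control_spacing
        if np.isscalar(cs):
            cs = (float(cs),) * 3
        self.control_spacing = tuple(float(v) for v in cs)
        self.max_iterations = int(self.max_iterations)
        if self.shrink < 1 or (self.shrink & (self.shrink - 1)) != 0:
            raise ParameterError(f"shrink factor must be a power of 2, got {self.shrink}")
        if any(v <= 0 for v in self.control_spacing):
            raise ParameterError("control_spacing must be positive")
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")


@dataclass
class RegistrationConfig:
    """Everything that defines a registration run.

    Defaults follow a conventional pelvic CT/CBCT schedule: three levels,
    image shrink (4, 2, 1), control spacing (40, 20, 10) mm, with
    conservative convergence tolerances.
    """

    pyramid_levels: list[PyramidLevel] = field(
        default_factory=lambda: [
            PyramidLevel(4, (40.0,) * 3, 50),
            PyramidLevel(2, (20.0,) * 3, 60),
            PyramidLevel(1, (10.0,) * 3, 80),
        ]
    )
    weights: CostWeights = field(default_factory=CostWeights)
    workflow: str = "pd"
    structure_max_points: int = 2000
    grad_tol: float = 1e-5
    rel_cost_tol: float = 1e-7
    seed: int = 0
    background_fill: float = -1000.0
    intensity_clip: tuple[float, float] | None = None
    curvature_step: int = 2

    def __post_init__(self) -> None:
        self.pyramid_levels = [
            lv if isinstance(lv, PyramidLevel) else PyramidLevel(**lv) for lv in self.pyramid_levels
        ]
        if isinstance(self.weights, dict):
            self.weights = CostWeights(**self.weights)
        if not self.pyramid_levels:
            raise ConfigurationError("at least one pyramid level is required")
        shrinks = [lv.shrink for lv in self.pyramid_levels]
        if any(a < b for a, b in zip(shrinks, shrinks[1:])):
            raise ConfigurationError(f"shrink factors must be non-increasing, got {shrinks}")
        spacings = np.array([lv.control_spacing for lv in self.pyramid_levels])
        if np.any(spacings[:-1] < spacings[1:] - 1e-12):
            raise ConfigurationError("control spacings must be non-increasing across levels")
        if self.workflow not in WORKFLOWS:
            raise ConfigurationError(f"workflow must be one of {WORKFLOWS}, got {self.workflow!r}")
        if self.workflow == "no_pd":
            # the No PD workflow is the pure intensity ablation
            self.weights = CostWeights(lambda_reg=self.weights.lambda_reg, eta={})
        if self.intensity_clip is not None:
            lo, hi = self.intensity_clip
            if not lo < hi:
                raise ConfigurationError(f"intensity_clip must be (lo, hi), got {self.intensity_clip}")
            self.intensity_clip = (float(lo), float(hi))

    # -- YAML round trip -------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "RegistrationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        known = {f.name for f in dc_fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {unknown}")
        if "intensity_clip" in raw and raw["intensity_clip"] is not None:
            raw["intensity_clip"] = tuple(raw["intensity_clip"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            "pyramid_levels": [
                {
                    "shrink": lv.shrink,
                    "control_spacing": list(lv.control_spacing),
                    "max_iterations": lv.max_iterations,
                }
                for lv in self.pyramid_levels
            ],
            "weights": {"lambda_reg": self.weights.lambda_reg, "eta": dict(self.weights.eta)},
            "workflow": self.workflow,
            "structure_max_points": self.structure_max_points,
            "grad_tol": self.grad_tol,
            "rel_cost_tol": self.rel_cost_tol,
            "seed": self.seed,
            "background_fill": self.background_fill,
            "intensity_clip": list(self.intensity_clip) if self.intensity_clip else None,
            "curvature_step": self.curvature_step,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class RegistrationResult:
    transform: BSplineTransform
    history: list[list[CostBreakdown]]
    converged_by: list[str]
    level_transforms: list[BSplineTransform] = field(default_factory=list)

    def history_rows(self):
        """Flat (level, iteration, terms...) rows for the CSV/stderr log."""
        rows = []
        for lvl, entries in enumerate(self.history):
            for it, bd in enumerate(entries):
                row = {
                    "level": lvl,
                    "iteration": it,
                    "intensity": bd.intensity,
                    "regularization": bd.regularization,
                    "total": bd.total,
                    "gradient_norm": float(np.linalg.norm(bd.gradient))
                    if bd.gradient is not None
                    else np.nan,
                }
                for name, v in bd.pd_per_structure.items():
                    row[f"pd_{name}"] = v
                rows.append(row)
        return rows

    def write_history_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.history_rows()).to_csv(path, index=False)


def build_pyramid(vol: ImageVolume, shrink: int) -> ImageVolume:
    """Gaussian-smooth (sigma = 0.5 * shrink voxels) and subsample by ``shrink``.

    The coarse grid's voxel centers sit at the centers of the shrink-blocks,
    preserving the physical center of the field of view.
    """
    shrink = int(shrink)
    if shrink < 1 or (shrink & (shrink - 1)) != 0:
        raise ParameterError(f"shrink must be a power of 2 >= 1, got {shrink}")
    smoothed = ndimage.gaussian_filter(
        vol.voxels.astype(np.float64, copy=False), sigma=0.5 * shrink, mode="nearest"
    )
    if shrink == 1:
        return ImageVolume(smoothed, vol.grid)
    size = tuple(int(np.ceil(n / shrink)) for n in vol.grid.size)
    spacing = tuple(s * shrink for s in vol.grid.spacing)
    origin = tuple(
        o + 0.5 * (shrink - 1) * s for o, s in zip(vol.grid.origin, vol.grid.spacing)
    )
    coarse = Grid(size, spacing, origin, vol.grid.direction)
    return resample(ImageVolume(smoothed, vol.grid), coarse, interp="linear", fill=float(smoothed.min()))


def _derive_seed(base: int, level: int, index: int) -> int:
    return (int(base) * 100003 + level * 1009 + index * 101) % (2**31 - 1)


def _converged_reason(result) -> str:
    msg = str(result.message)
    if "NORM_OF_PROJECTED_GRADIENT" in msg or "NORM OF PROJECTED GRADIENT" in msg:
        return "gradient"
    if "REL_REDUCTION_OF_F" in msg or "RELATIVE REDUCTION" in msg:
        return "cost"
    if result.status == 1:
        return "max_iter"
    return "cost" if result.status == 0 else "max_iter"


def register(
    fixed: ImageVolume,
    moving: ImageVolume,
    fixed_masks: dict[str, BinaryMask] | None,
    moving_masks: dict[str, BinaryMask] | None,
    fiducials=None,
    cfg: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Run the configured multi-resolution hybrid registration.

    ``fixed_masks`` carry the fixed-image structure contours (surface point
    sources), ``moving_masks`` the moving-image contours (distance map
    sources). For ``workflow="no_pd"`` both may be empty. ``fiducials`` is
    accepted for interface parity and ignored by the optimizer (fiducials
    are evaluation-only).
    """
    cfg = cfg or RegistrationConfig()
    fixed_masks = fixed_masks or {}
    moving_masks = moving_masks or {}
    if not fixed.grid.has_identity_direction or not moving.grid.has_identity_direction:
        raise ConfigurationError("registration requires identity direction matrices")
    pd_structures = sorted(n for n, e in cfg.weights.eta.items() if e > 0)
    if cfg.workflow == "pd":
        if not pd_structures:
            raise ConfigurationError("pd workflow requires at least one structure with eta > 0")
        missing = [n for n in pd_structures if n not in fixed_masks or n not in moving_masks]
        if missing:
            raise ConfigurationError(
                f"pd workflow: masks missing for weighted structures {missing}"
            )

    if cfg.intensity_clip is not None:
        lo, hi = cfg.intensity_clip
        fixed = ImageVolume(np.clip(fixed.voxels, lo, hi), fixed.grid)
        moving = ImageVolume(np.clip(moving.voxels, lo, hi), moving.grid)

    transform: BSplineTransform | None = None
    history: list[list[CostBreakdown]] = []
    converged: list[str] = []
    level_transforms: list[BSplineTransform] = []
    fixed_extent = fixed.grid.extent

    for lvl, level in enumerate(cfg.pyramid_levels):
        f_l = build_pyramid(fixed, level.shrink)
        m_l = build_pyramid(moving, level.shrink)

        if transform is None:
            transform = BSplineTransform.for_extent(fixed_extent, level.control_spacing)
        else:
            transform = transform.refine(level.control_spacing, fixed_extent)

        surface_points = {}
        distance_maps = {}
        for si, name in enumerate(pd_structures):
            fm = resample(fixed_masks[name], f_l.grid, interp="nearest")
            mm = resample(moving_masks[name], m_l.grid, interp="nearest")
            if not fm.voxels.any() or not mm.voxels.any():
                raise ConfigurationError(
                    f"structure {name!r} is empty after resampling to level {lvl}"
                )
            surface_points[name] = sample_surface_points(
                fm,
                cfg.structure_max_points,
                seed=_derive_seed(cfg.seed, lvl, si),
                structure_name=name,
            )
            distance_maps[name] = boundary_distance_map(mm, structure_name=name)

        objective = HybridCostFunction(
            f_l,
            m_l,
            transform,
            cfg.weights,
            surface_points=surface_points,
            distance_maps=distance_maps,
            curvature_step=cfg.curvature_step,
        )

        level_history: list[CostBreakdown] = []
        cache: dict[bytes, CostBreakdown] = {}

        def fun(theta):
            bd = objective.evaluate(theta)
            if len(cache) > 4:
                cache.clear()
            cache[np.asarray(theta).tobytes()] = bd
            return bd.total, bd.gradient

        def callback(xk):
            key = np.asarray(xk).tobytes()
            bd = cache.get(key)
            if bd is None:
                bd = objective.evaluate(xk)
            level_history.append(bd)

        x0 = transform.theta.copy()
        bd0 = objective.evaluate(x0)
        level_history.append(bd0)
        result = optimize.minimize(
            fun,
            x0,
            jac=True,
            method="L-BFGS-B",
            callback=callback,
            options={
                "maxiter": level.max_iterations,
                "ftol": cfg.rel_cost_tol,
                "gtol": cfg.grad_tol,
                "maxcor": 20,
            },
        )
        transform = transform.with_theta(result.x)
        history.append(level_history)
        converged.append(_converged_reason(result))
        level_transforms.append(transform)

    return RegistrationResult(
        transform=transform,
        history=history,
        converged_by=converged,
        level_transforms=level_transforms,
    )
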