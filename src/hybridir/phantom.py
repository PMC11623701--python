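"""Synthetic pelvic phantom lab.

Emulates the experimental design end-to-end with no external data:

* a CT-like *fixed* volume with a body ellipsoid, a bone rim, and three
  soft-tissue organ analogs (prostate sphere, bladder ellipsoid, rectum
  tube) plus implanted fiducial marker pairs (bright blobs, top/bottom
  points 3 mm apart) inside the prostate analog;
* a known smooth ground-truth B-spline deformation ``T*`` (random
  coefficients rescaled to a prescribed peak displacement magnitude);
* a CBCT-like *moving* volume: the fixed anatomy carried through ``T*`` and
  degraded by soft-tissue contrast compression, additive noise and a
  low-frequency multiplicative bias field (intensity-only — anatomy never
  moves);
* "expert" moving contours exactly consistent with ``T*`` and "auto-seg"
  contours perturbed to a controllable Dice against them.

Because registration and evaluation both use the pull-back convention
(transforms map fixed coordinates into moving space), the moving volume is
generated with the *inverse* of ``T*`` (computed by fixed-point iteration to
below 1e-6 mm in the interior): that makes ``T*`` itself the exact transform
the optimizer should recover, and the truth-mapped fiducials/masks the
evaluation zero point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np
from scipy import ndimage

from .bspline import BSplineTransform
from .errors import ConvergenceError, ParameterError, SpecificationError
from .volumes import BinaryMask, Grid, ImageVolume, LabeledPointSet

__all__ = [
    "OrganGeometry",
    "IntensityLevels",
    "DeformationSpec",
    "DegradationSpec",
    "ContourNoiseSpec",
    "PhantomSpec",
    "SyntheticCase",
    "make_phantom",
    "make_truth_deformation",
    "degrade_to_cbct",
    "perturb_contours",
    "make_case",
]

ORGAN_NAMES = ("prostate", "bladder", "rectum")


@dataclass
class OrganGeometry:
    """Parametric organ-analog geometry, physical mm (grid-size independent)."""

    body_semiaxes: tuple[float, float, float] = (56.0, 46.0, 100.0)
    bone_rim_inner_fraction: float = 0.90
    prostate_radius: float = 12.0
    prostate_center: tuple[float, float, float] = (0.0, 0.0, -8.0)
    bladder_semiaxes: tuple[float, float, float] = (18.0, 15.0, 13.0)
    bladder_center: tuple[float, float, float] = (0.0, 10.0, 20.0)
    rectum_radius: float = 9.0
    rectum_length: float = 80.0
    rectum_center: tuple[float, float, float] = (0.0, -26.0, 0.0)


@dataclass
class IntensityLevels:
    """HU-like intensity levels of the phantom tissues."""

    background: float = -1000.0
    body: float = 30.0
    bone: float = 500.0
    prostate: float = 90.0
    bladder: float = -10.0
    rectum: float = -90.0
    fiducial: float = 900.0

    def organ(self, name: str) -> float:
        return {"prostate": self.prostate, "bladder": self.bladder, "rectum": self.rectum}[name]

    @property
    def soft_tissue_range(self) -> tuple[float, float]:
        levels = [self.body, self.prostate, self.bladder, self.rectum]
        return min(levels), max(levels)


@dataclass
class DeformationSpec:
    """Ground-truth deformation parameters.

    The random coefficient field is attenuated by a Gaussian envelope
    (sigma ``envelope_sigma_mm`` around the organ region) before rescaling:
    inter-fraction pelvic deformation is soft-tissue dominated (bladder and
    rectal filling displace the organs) while the bony frame stays put, so
    the phantom concentrates its deformation there too.
    """

    control_spacing: float = 40.0
    peak_magnitude: float = 14.0
    envelope_sigma_mm: float = 50.0
    envelope_center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.peak_magnitude < 0:
            raise ParameterError("peak_magnitude must be >= 0")
        if self.envelope_sigma_mm <= 0:
            raise ParameterError("envelope_sigma_mm must be > 0")


@dataclass
class DegradationSpec:
    """CBCT-like intensity degradation (never moves anatomy).

    ``blur_sigma_mm`` is an effective point-spread width: scatter, residual
    motion and reconstruction artifacts wash out fine detail on CBCT —
    implanted seeds bloom and smear, soft-tissue edges lose definition —
    even though the underlying anatomy is unmoved.
    """

    contrast_compression: float = 0.7
    noise_sd: float = 20.0
    bias_amplitude: float = 0.06
    bias_wavelength: float = 90.0
    blur_sigma_mm: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.contrast_compression <= 1.0:
            raise ParameterError("contrast_compression must lie in [0, 1]")
        if self.blur_sigma_mm < 0:
            raise ParameterError("blur_sigma_mm must be >= 0")


@dataclass
class ContourNoiseSpec:
    """Auto-segmentation quality emulation, calibrated in Dice."""

    target_dice: float = 0.80
    boundary_sd: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_dice <= 1.0:
            raise ParameterError("target_dice must lie in (0, 1]")


@dataclass
class PhantomSpec:
    grid_size: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    organs: OrganGeometry = field(default_factory=OrganGeometry)
    intensities: IntensityLevels = field(default_factory=IntensityLevels)
    n_fiducials: int = 3
    fiducial_jitter_mm: float = 6.0
    fiducial_pair_gap_mm: float = 3.0
    fiducial_marker_radius_mm: float = 1.5
    deformation: DeformationSpec = field(default_factory=DeformationSpec)
    degradation: DegradationSpec = field(default_factory=DegradationSpec)
    contour_noise: ContourNoiseSpec = field(default_factory=ContourNoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_size = tuple(int(v) for v in self.grid_size)
        sp = self.spacing
        if np.isscalar(sp):
            sp = (float(sp),) * 3
        self.spacing = tuple(float(v) for v in sp)
        if isinstance(self.organs, dict):
            self.organs = OrganGeometry(**self.organs)
        if isinstance(self.intensities, dict):
            self.intensities = IntensityLevels(**self.intensities)
        if isinstance(self.deformation, dict):
            self.deformation = DeformationSpec(**self.deformation)
        if isinstance(self.degradation, dict):
            self.degradation = DegradationSpec(**self.degradation)
        if isinstance(self.contour_noise, dict):
            self.contour_noise = ContourNoiseSpec(**self.contour_noise)
        if self.n_fiducials < 1:
            raise ParameterError("n_fiducials must be >= 1")

    @property
    def grid(self) -> Grid:
        n = np.asarray(self.grid_size)
        s = np.asarray(self.spacing)
        origin = -(n - 1) * s / 2.0  # centered field of view
        return Grid(tuple(n), tuple(s), tuple(origin))

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        import yaml
        from dataclasses import fields as dc_fields

        raw = yaml.safe_load(open(path)) or {}
        if not isinstance(raw, dict):
            raise ParameterError(f"{path}: phantom spec must be a mapping")
        known = {f.name for f in dc_fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ParameterError(f"{path}: unknown phantom spec keys {unknown}")
        return cls(**raw)


@dataclass
class SyntheticCase:
    """One phantom registration case with ground truth."""

    spec: PhantomSpec
    fixed: ImageVolume
    fixed_masks: Dict[str, BinaryMask]
    fixed_fiducials: LabeledPointSet
    truth: BSplineTransform
    moving: ImageVolume
    moving_masks_exact: Dict[str, BinaryMask]
    moving_masks_noisy: Dict[str, BinaryMask]
    moving_fiducials: LabeledPointSet


def _rng(spec_seed: int, tag: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(spec_seed) & 0x7FFFFFFF, tag, extra])


def _physical_coords(grid: Grid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [
        grid.origin[a] + np.arange(grid.size[a]) * grid.spacing[a] for a in range(3)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _dice_arrays(a: np.ndarray, b: np.ndarray) -> float:
    inter = float(np.logical_and(a, b).sum())
    denom = float(a.sum() + b.sum())
    return 1.0 if denom == 0 else 2.0 * inter / denom


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

def make_phantom(spec: PhantomSpec):
    """Build the CT-like fixed volume, organ masks and fiducial points.

    Deterministic given ``spec.seed``. Raises
    :class:`~hybridir.errors.SpecificationError` if the parametric organs
    overlap or leave the body.
    """
    grid = spec.grid
    x, y, z = _physical_coords(grid)
    og = spec.organs
    hu = spec.intensities

    ax, ay, az = og.body_semiaxes
    rho2 = (x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2
    body = rho2 <= 1.0
    bone = (rho2 <= 1.0) & (rho2 >= og.bone_rim_inner_fraction**2)

    cx, cy, cz = og.prostate_center
    prostate = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= og.prostate_radius**2
    bx_, by_, bz_ = og.bladder_center
    sa, sb, sc = og.bladder_semiaxes
    bladder = ((x - bx_) / sa) ** 2 + ((y - by_) / sb) ** 2 + ((z - bz_) / sc) ** 2 <= 1.0
    rx, ry, rz = og.rectum_center
    rectum = (
        ((x - rx) ** 2 + (y - ry) ** 2 <= og.rectum_radius**2)
        & (np.abs(z - rz) <= og.rectum_length / 2.0)
    )

    masks = {"prostate": prostate, "bladder": bladder, "rectum": rectum}
    soft_interior = body & ~bone
    for name, m in masks.items():
        if not m.any():
            raise SpecificationError(f"{name} analog is empty on this grid")
        if (m & ~soft_interior).any():
            raise SpecificationError(f"{name} analog leaves the soft-tissue body region")
    for a, b in (("prostate", "bladder"), ("prostate", "rectum"), ("bladder", "rectum")):
        if (masks[a] & masks[b]).any():
            raise SpecificationError(f"{a} and {b} analogs overlap")

    voxels = np.full(grid.size, hu.background, dtype=np.float64)
    voxels[body] = hu.body
    voxels[bone] = hu.bone
    for name, m in masks.items():
        voxels[m] = hu.organ(name)

    # fiducial marker pairs inside the prostate analog
    rng = _rng(spec.seed, 2)
    labels: list[str] = []
    points: list[np.ndarray] = []
    center = np.asarray(og.prostate_center)
    max_jitter = min(
        spec.fiducial_jitter_mm,
        og.prostate_radius - spec.fiducial_marker_radius_mm - spec.fiducial_pair_gap_mm,
    )
    if max_jitter <= 0:
        raise SpecificationError("prostate analog too small for the requested fiducials")
    half_gap = spec.fiducial_pair_gap_mm / 2.0
    for k in range(spec.n_fiducials):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = max_jitter * rng.uniform() ** (1.0 / 3.0)
        c = center + radius * direction
        top = c + np.array([0.0, 0.0, half_gap])
        bottom = c - np.array([0.0, 0.0, half_gap])
        labels += [f"fid{k + 1}_top", f"fid{k + 1}_bottom"]
        points += [top, bottom]
        for p in (top, bottom):
            blob = (x - p[0]) ** 2 + (y - p[1]) ** 2 + (z - p[2]) ** 2 <= (
                spec.fiducial_marker_radius_mm**2
            )
            voxels[blob] = hu.fiducial

    fixed = ImageVolume(voxels, grid)
    mask_objs = {name: BinaryMask(m, grid) for name, m in masks.items()}
    fiducials = LabeledPointSet(labels, np.asarray(points), frame="fixed")
    return fixed, mask_objs, fiducials


def make_truth_deformation(spec: PhantomSpec, fixed_grid: Grid | None = None) -> BSplineTransform:
    """Seeded smooth ground-truth deformation with exact peak magnitude.

    Coefficients are i.i.d. normal draws rescaled so the maximum
    displacement magnitude over the fixed grid equals
    ``spec.deformation.peak_magnitude`` (zero peak gives the identity).
    The lattice extends one peak-magnitude beyond the image so the inverse
    mapping stays inside its support.
    """
    grid = fixed_grid if fixed_grid is not None else spec.grid
    pmin, pmax = grid.extent
    pad = spec.deformation.peak_magnitude + max(grid.spacing)
    cs = (spec.deformation.control_spacing,) * 3
    t = BSplineTransform.for_extent((pmin - pad, pmax + pad), cs)
    if spec.deformation.peak_magnitude == 0:
        return t
    rng = _rng(spec.seed, 1)
    coef = rng.standard_normal(t.coefficients.shape)
    # soft-tissue envelope: deformation concentrates around the organs
    axes = [
        t.control_origin[a] + np.arange(t.control_size[a]) * t.control_spacing[a]
        for a in range(3)
    ]
    cx, cy, cz = np.meshgrid(*axes, indexing="ij")
    center = np.asarray(spec.deformation.envelope_center)
    r2 = (cx - center[0]) ** 2 + (cy - center[1]) ** 2 + (cz - center[2]) ** 2
    envelope = np.exp(-r2 / (2.0 * spec.deformation.envelope_sigma_mm**2))
    coef = coef * envelope[..., None]
    t.coefficients = coef
    mags = np.linalg.norm(t.displacement(grid.voxel_centers()), axis=1)
    peak = mags.max()
    if peak == 0:
        raise ParameterError("degenerate random deformation draw")
    t.coefficients = coef * (spec.deformation.peak_magnitude / peak)
    return t


# ---------------------------------------------------------------------------
# Degradation
# ---------------------------------------------------------------------------

def degrade_to_cbct(vol: ImageVolume, spec: PhantomSpec) -> ImageVolume:
    """Apply CBCT-like intensity degradation (contrast, bias, noise).

    Intensities within the soft-tissue range are compressed toward the body
    level; a seeded low-frequency multiplicative bias and additive Gaussian
    noise follow. With all degradation parameters zero the input is
    returned unchanged, bit for bit.
    """
    deg = spec.degradation
    hu = spec.intensities
    out = vol.voxels.copy()

    if deg.contrast_compression > 0:
        lo, hi = hu.soft_tissue_range
        soft = (out >= lo) & (out <= hi)
        out[soft] = hu.body + (1.0 - deg.contrast_compression) * (out[soft] - hu.body)

    if deg.blur_sigma_mm > 0:
        sigma_vox = deg.blur_sigma_mm / np.asarray(vol.grid.spacing)
        out = ndimage.gaussian_filter(out, sigma=sigma_vox, mode="nearest")

    if deg.bias_amplitude > 0:
        rng = _rng(spec.seed, 3)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
        x, y, z = _physical_coords(vol.grid)
        w = 2.0 * np.pi / deg.bias_wavelength
        bias = 1.0 + deg.bias_amplitude * (
            np.sin(w * x + phases[0]) * np.sin(w * y + phases[1]) * np.sin(w * z + phases[2])
        )
        out = hu.background + (out - hu.background) * bias

    if deg.noise_sd > 0:
        rng = _rng(spec.seed, 4)
        out = out + rng.normal(0.0, deg.noise_sd, size=out.shape)

    return ImageVolume(out, vol.grid)


# ---------------------------------------------------------------------------
# Contour perturbation ("auto-seg" emulation)
# ---------------------------------------------------------------------------

def perturb_contours(
    mask: BinaryMask, target_dice: float, boundary_sd: float, seed: int
) -> BinaryMask:
    """Degrade a contour to a target Dice against the original.

    A seeded random direction field — a smooth B-spline component
    (systematic contouring error) plus boundary roughening (high-frequency
    jitter, relative weight ``boundary_sd / 4`` mm-for-mm) — is scaled by
    bisection until ``Dice(perturbed, original)`` falls within +/-0.02 of
    ``target_dice``. Deterministic given ``seed``.
    """
    if not 0.0 < target_dice <= 1.0:
        raise ParameterError("target_dice must lie in (0, 1]")
    if target_dice == 1.0:
        return BinaryMask(mask.voxels.copy(), mask.grid)
    if not mask.voxels.any():
        raise ParameterError("cannot perturb an empty mask")

    rng = np.random.default_rng(seed)
    grid = mask.grid
    spacing = np.asarray(grid.spacing)

    # smooth systematic component: B-spline field, unit peak magnitude
    smooth_t = BSplineTransform.for_extent(grid, (25.0, 25.0, 25.0))
    smooth_t.coefficients = rng.standard_normal(smooth_t.coefficients.shape)
    centers = grid.voxel_centers()
    us = smooth_t.displacement(centers).reshape(tuple(grid.size) + (3,))
    us /= np.linalg.norm(us, axis=-1).max()

    # rough random component: smoothed white noise, unit RMS magnitude
    ur = rng.standard_normal(tuple(grid.size) + (3,))
    for c in range(3):
        ur[..., c] = ndimage.gaussian_filter(ur[..., c], sigma=1.0, mode="nearest")
    ur /= np.sqrt(np.mean(np.sum(ur**2, axis=-1)))

    direction = us + (boundary_sd / 4.0) * ur  # mm per unit scale
    base_idx = np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in grid.size], indexing="ij"), axis=-1
    )

    src = mask.voxels.astype(np.float64)

    def perturbed_at(scale: float) -> np.ndarray:
        idx = base_idx + scale * direction / spacing
        vals = ndimage.map_coordinates(src, [idx[..., a] for a in range(3)], order=0, mode="constant", cval=0.0)
        return vals > 0.5

    def dice_at(scale: float) -> tuple[float, np.ndarray]:
        p = perturbed_at(scale)
        return _dice_arrays(p, mask.voxels), p

    # bracket, then bisect the scale
    s_lo, s_hi = 0.0, float(max(spacing))
    d_hi, p_hi = dice_at(s_hi)
    doublings = 0
    while d_hi > target_dice and doublings < 12:
        s_lo = s_hi
        s_hi *= 2.0
        d_hi, p_hi = dice_at(s_hi)
        doublings += 1
    if d_hi > target_dice:
        raise ConvergenceError(
            f"could not reach Dice {target_dice:.2f}; achieved {d_hi:.3f} at scale {s_hi:.1f} mm"
        )
    achieved, result = d_hi, p_hi
    for _ in range(50):
        if abs(achieved - target_dice) <= 0.02:
            return BinaryMask(result, mask.grid)
        mid = 0.5 * (s_lo + s_hi)
        d_mid, p_mid = dice_at(mid)
        achieved, result = d_mid, p_mid
        if d_mid > target_dice:
            s_lo = mid
        else:
            s_hi = mid
    if abs(achieved - target_dice) <= 0.02:
        return BinaryMask(result, mask.grid)
    raise ConvergenceError(
        f"bisection did not reach Dice {target_dice:.2f} +/- 0.02; achieved {achieved:.3f}"
    )


# ---------------------------------------------------------------------------
# Inverse mapping and full case composition
# ---------------------------------------------------------------------------

def _invert_truth_on_grid(truth: BSplineTransform, grid: Grid) -> np.ndarray:
    """Preimages under ``T*`` of every voxel center: solve p + v(p) = q.

    Fixed-point iteration ``p <- q - v(p)`` with the displacement field
    linearly interpolated from a dense sampling (contractive for the smooth
    truth fields the lab generates). Returns (N, 3) physical positions.
    """
    pad = 3.0 * max(grid.spacing)
    pmin, pmax = grid.extent
    lo_support = truth.control_origin + truth.control_spacing
    hi_support = truth.control_origin + (np.asarray(truth.control_size) - 2) * truth.control_spacing
    lo = np.maximum(pmin - pad, lo_support)
    hi = np.minimum(pmax + pad, hi_support)
    spacing = np.asarray(grid.spacing)
    n_ext = np.ceil((hi - lo) / spacing).astype(int) + 1
    ext = Grid(tuple(n_ext), tuple(spacing), tuple(lo))
    disp = truth.displacement(ext.voxel_centers()).reshape(tuple(n_ext) + (3,))

    q = grid.voxel_centers()
    p = q.copy()
    for _ in range(60):
        idx = ((np.clip(p, lo, hi) - lo) / spacing).T
        u = np.stack(
            [ndimage.map_coordinates(disp[..., c], idx, order=1, mode="nearest") for c in range(3)],
            axis=1,
        )
        p_new = q - u
        step = np.abs(p_new - p).max()
        p = p_new
        if step < 1e-9:
            break
    return p


def make_case(spec: PhantomSpec) -> SyntheticCase:
    """Compose phantom, truth deformation, degradation and contour noise."""
    fixed, fixed_masks, fixed_fids = make_phantom(spec)
    truth = make_truth_deformation(spec, fixed.grid)
    grid = fixed.grid

    if spec.deformation.peak_magnitude == 0:
        moving_clean = fixed.copy()
        moving_masks_exact = {n: BinaryMask(m.voxels.copy(), grid) for n, m in fixed_masks.items()}
    else:
        preimages = _invert_truth_on_grid(truth, grid)
        idx = grid.physical_to_voxel(preimages)
        n = np.asarray(grid.size)
        inside = np.all((idx >= 0.0) & (idx <= n - 1), axis=1)
        vals = ndimage.map_coordinates(fixed.voxels, idx.T, order=1, mode="nearest")
        vals[~inside] = spec.intensities.background
        moving_clean = ImageVolume(vals.reshape(grid.size), grid)
        moving_masks_exact = {}
        for name, m in fixed_masks.items():
            mv = ndimage.map_coordinates(m.voxels.astype(np.float64), idx.T, order=0, mode="constant", cval=0.0)
            mv[~inside] = 0.0
            moving_masks_exact[name] = BinaryMask(mv.reshape(grid.size) > 0.5, grid)

    moving = degrade_to_cbct(moving_clean, spec)
    moving_fids = LabeledPointSet(
        list(fixed_fids.labels), truth.transform_point(fixed_fids.points), frame="moving"
    )

    moving_masks_noisy = {}
    for si, name in enumerate(ORGAN_NAMES):
        if spec.contour_noise.target_dice == 1.0:
            moving_masks_noisy[name] = BinaryMask(moving_masks_exact[name].voxels.copy(), grid)
        else:
            moving_masks_noisy[name] = perturb_contours(
                moving_masks_exact[name],
                spec.contour_noise.target_dice,
                spec.contour_noise.boundary_sd,
                seed=int(_rng(spec.seed, 5, si).integers(2**31 - 1)),
            )

    # constructor contract checks
    assert np.abs(truth.transform_point(fixed_fids.points) - moving_fids.points).max() < 1e-9
    for name in ORGAN_NAMES:
        if not moving_masks_exact[name].voxels.any():
            raise SpecificationError(f"exact moving mask for {name} is empty")
        d = _dice_arrays(moving_masks_noisy[name].voxels, moving_masks_exact[name].voxels)
        if abs(d - spec.contour_noise.target_dice) > 0.05:
            raise ConvergenceError(
                f"noisy contour for {name} missed target Dice: {d:.3f} vs {spec.contour_noise.target_dice}"
            )

    return SyntheticCase(
        spec=spec,
        fixed=fixed,
        fixed_masks=fixed_masks,
        fixed_fiducials=fixed_fids,
        truth=truth,
        moving=moving,
        moving_masks_exact=moving_masks_exact,
        moving_masks_noisy=moving_masks_noisy,
        moving_fiducials=moving_fids,
    )
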