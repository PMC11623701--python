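import numpy as np
import pytest

from conftest import sphere_mask
from hybridir import (
    BinaryMask,
    BSplineTransform,
    ConfigurationError,
    CostWeights,
    Grid,
    HybridCostFunction,
    ImageVolume,
    ParameterError,
    boundary_distance_map,
    curvature_term,
    intensity_term,
    pd_term,
    sample_surface_points,
    total_cost,
)


def small_problem(n=12, seed=42, coef_scale=0.3):
    """Random fixed/moving pair + transform + one spherical structure."""
    rng = np.random.default_rng(seed)
    grid = Grid((n,) * 3, (1.0,) * 3, (0.0,) * 3)
    fixed = ImageVolume(rng.standard_normal((n,) * 3) * 50 + 100, grid)
    moving = ImageVolume(rng.standard_normal((n,) * 3) * 50 + 100, grid)
    t = BSplineTransform.for_extent(grid, (4.0,) * 3)
    t.coefficients = t.coefficients + rng.standard_normal(t.coefficients.shape) * coef_scale
    dom = np.zeros((n,) * 3, bool)
    dom[2:-2, 2:-2, 2:-2] = True  # interior domain: no in/out border crossings
    domain = BinaryMask(dom, grid)
    x, y, z = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    sph = (x - n / 2 + 0.5) ** 2 + (y - n / 2 + 0.5) ** 2 + (z - n / 2 + 0.5) ** 2 <= 16
    mask_f = BinaryMask(sph, grid)
    mask_m = BinaryMask(np.roll(sph, 1, axis=0), grid)
    sp = sample_surface_points(mask_f, 200, seed=1, structure_name="s")
    dm = boundary_distance_map(mask_m, "s")
    return fixed, moving, t, domain, sp, dm


def directional_fd_errors(f, grad, theta, n_dirs=20, h=1e-3, seed=0):
    rng = np.random.default_rng(seed)
    errs = []
    for _ in range(n_dirs):
        d = rng.standard_normal(theta.size)
        d /= np.linalg.norm(d)
        fd = (f(theta + h * d) - f(theta - h * d)) / (2 * h)
        an = float(grad @ d)
        errs.append(abs(fd - an) / max(abs(fd), abs(an), 1e-12))
    return max(errs)


class TestIntensityTerm:
    def test_perfect_match_is_zero(self):
        rng = np.random.default_rng(0)
        grid = Grid((8, 8, 8), (2.0,) * 3, (0.0,) * 3)
        vol = ImageVolume(rng.standard_normal((8, 8, 8)), grid)
        t = BSplineTransform.for_extent(grid, (8.0,) * 3)
        v, g = intensity_term(vol, vol, t)
        assert abs(v) < 1e-18
        assert np.abs(g).max() < 1e-9

    def test_constant_difference_closed_form(self):
        grid = Grid((8, 8, 8), (2.0,) * 3, (0.0,) * 3)
        fixed = ImageVolume(np.zeros((8, 8, 8)), grid)
        moving = ImageVolume(np.full((8, 8, 8), 3.0), grid)
        t = BSplineTransform.for_extent(grid, (8.0,) * 3)
        v, _ = intensity_term(fixed, moving, t)
        assert abs(v - 9.0) < 1e-9

    def test_gradient_matches_finite_differences(self):
        fixed, moving, t, domain, _, _ = small_problem()
        fn = HybridCostFunction(fixed, moving, t, CostWeights(lambda_reg=0.0), domain=domain)
        theta = t.theta
        v, g = fn.intensity(theta)
        assert directional_fd_errors(lambda th: fn.intensity(th)[0], g, theta) < 1e-4

    def test_symmetric_under_swap_at_identity(self):
        rng = np.random.default_rng(1)
        grid = Grid((8, 8, 8), (2.0,) * 3, (0.0,) * 3)
        a = ImageVolume(rng.standard_normal((8, 8, 8)), grid)
        b = ImageVolume(rng.standard_normal((8, 8, 8)), grid)
        t = BSplineTransform.for_extent(grid, (8.0,) * 3)
        va, _ = intensity_term(a, b, t)
        vb, _ = intensity_term(b, a, t)
        assert abs(va - vb) < 1e-9


class TestCurvatureTerm:
    def test_constant_displacement_has_zero_bending(self):
        grid = Grid((8, 8, 8), (2.0,) * 3, (0.0,) * 3)
        t = BSplineTransform.for_extent(grid, (6.0,) * 3)
        t.coefficients[...] = [4.0, -1.0, 2.5]
        v, g = curvature_term(t, grid, lambda_reg=1.0)
        assert abs(v) < 1e-18
        assert np.abs(g).max() < 1e-12

    def test_globally_linear_field_has_zero_bending(self):
        grid = Grid((8, 8, 8), (2.0,) * 3, (0.0,) * 3)
        t = BSplineTransform.for_extent(grid, (6.0,) * 3)
        # coefficients of a linear spline field are the field at control points
        for a, n in enumerate(t.control_size):
            coords = t.control_origin[a] + np.arange(n) * t.control_spacing[a]
            shape = [1, 1, 1]
            shape[a] = n
            t.coefficients[..., 0] += 0.05 * coords.reshape(shape)
            t.coefficients[..., 2] += -0.02 * coords.reshape(shape)
        v, _ = curvature_term(t, grid, lambda_reg=1.0)
        assert abs(v) < 1e-9

    def test_gradient_matches_finite_differences(self):
        fixed, moving, t, domain, _, _ = small_problem(seed=5)
        fn = HybridCostFunction(fixed, moving, t, CostWeights(lambda_reg=0.7), curvature_step=1)
        theta = t.theta
        _, g = fn.curvature(theta)
        assert directional_fd_errors(lambda th: fn.curvature(th)[0], g, theta) < 1e-4

    def test_scales_linearly_in_lambda(self):
        fixed, _, t, _, _, _ = small_problem(seed=6)
        v1, g1 = curvature_term(t, fixed.grid, lambda_reg=1.0)
        v2, g2 = curvature_term(t, fixed.grid, lambda_reg=2.5)
        assert abs(v2 - 2.5 * v1) < 1e-12
        assert np.abs(g2 - 2.5 * g1).max() < 1e-12


class TestPDTerm:
    def test_lattice_translation_gives_exact_zero(self):
        # moving structure is the fixed structure shifted by exactly one
        # voxel; the matching translation lands every surface point on a
        # boundary voxel center where the distance map is exactly zero
        grid = Grid((14, 14, 14), (1.0,) * 3, (0.0,) * 3)
        x, y, z = np.meshgrid(*[np.arange(14)] * 3, indexing="ij")
        sph = (x - 7) ** 2 + (y - 7) ** 2 + (z - 7) ** 2 <= 9
        mask_f = BinaryMask(sph, grid)
        mask_m = BinaryMask(np.roll(sph, 1, axis=0), grid)
        sp = sample_surface_points(mask_f, 500, seed=0, structure_name="s")
        dm = boundary_distance_map(mask_m, "s")
        t = BSplineTransform.for_extent(grid, (6.0,) * 3)
        t.coefficients[..., 0] = 1.0  # translation by +1 voxel in x
        v, _ = pd_term(t, sp, dm, eta_n=1.0)
        assert abs(v) < 1e-9

    def test_eta_zero_annihilates(self):
        _, _, t, _, sp, dm = small_problem(seed=7)
        v, g = pd_term(t, sp, dm, eta_n=0.0)
        assert v == 0.0
        assert np.abs(g).max() == 0.0

    def test_linear_in_eta_and_order_invariant(self):
        _, _, t, _, sp, dm = small_problem(seed=8)
        v1, g1 = pd_term(t, sp, dm, eta_n=0.3)
        v2, g2 = pd_term(t, sp, dm, eta_n=0.6)
        assert abs(v2 - 2.0 * v1) < 1e-9
        assert np.abs(g2 - 2.0 * g1).max() < 1e-9
        perm = np.random.default_rng(0).permutation(len(sp))
        sp_shuffled = type(sp)(sp.structure_name, sp.points[perm], sp.source_seed)
        v3, _ = pd_term(t, sp_shuffled, dm, eta_n=0.3)
        assert abs(v3 - v1) < 1e-9

    def test_gradient_matches_finite_differences(self):
        fixed, moving, t, _, sp, dm = small_problem(seed=9)
        fn = HybridCostFunction(
            fixed, moving, t, CostWeights(lambda_reg=0.0, eta={"s": 0.3}),
            surface_points={"s": sp}, distance_maps={"s": dm},
        )
        theta = t.theta
        _, g = fn.pd_structure(theta, "s")
        assert directional_fd_errors(lambda th: fn.pd_structure(th, "s")[0], g, theta) < 1e-4

    def test_empty_point_set_rejected(self):
        _, _, t, _, sp, dm = small_problem(seed=10)
        empty = type(sp)(sp.structure_name, np.empty((0, 3)), 0)
        with pytest.raises(ParameterError):
            pd_term(t, empty, dm, eta_n=1.0)


class TestTotalCost:
    def test_breakdown_additivity(self):
        fixed, moving, t, domain, sp, dm = small_problem(seed=11)
        bd = total_cost(
            fixed, moving, t, {"s": sp}, {"s": dm},
            CostWeights(lambda_reg=0.7, eta={"s": 0.3}), domain=domain,
        )
        parts = bd.intensity + bd.regularization + sum(bd.pd_per_structure.values())
        assert abs(bd.total - parts) < 1e-9
        assert bd.regularization >= 0.0
        assert all(v >= 0.0 for v in bd.pd_per_structure.values())

    def test_reduces_to_intensity_when_weights_vanish(self):
        fixed, moving, t, domain, sp, dm = small_problem(seed=12)
        bd = total_cost(
            fixed, moving, t, {"s": sp}, {"s": dm},
            CostWeights(lambda_reg=0.0, eta={"s": 0.0}), domain=domain,
        )
        v, _ = intensity_term(fixed, moving, t, domain=domain)
        assert bd.total == v

    def test_total_gradient_matches_finite_differences(self):
        fixed, moving, t, domain, sp, dm = small_problem(seed=13)
        fn = HybridCostFunction(
            fixed, moving, t, CostWeights(lambda_reg=0.7, eta={"s": 0.3}),
            surface_points={"s": sp}, distance_maps={"s": dm}, domain=domain,
            curvature_step=1,
        )
        theta = t.theta
        bd = fn.evaluate(theta)
        err = directional_fd_errors(lambda th: fn.evaluate(th).total, bd.gradient, theta)
        assert err < 1e-4

    def test_structure_name_mismatch_is_configuration_error(self):
        fixed, moving, t, _, sp, dm = small_problem(seed=14)
        with pytest.raises(ConfigurationError, match="s"):
            total_cost(fixed, moving, t, {"s": sp}, {}, CostWeights(eta={"s": 0.1}))

    def test_weight_validation(self):
        with pytest.raises(ParameterError):
            CostWeights(lambda_reg=-1.0)
        with pytest.raises(ParameterError):
            CostWeights(eta={"s": float("nan")})
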