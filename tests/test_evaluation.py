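import numpy as np
import pandas as pd
import pytest

from conftest import sphere_mask
from hybridir import (
    BinaryMask,
    BSplineTransform,
    GeometryError,
    Grid,
    LabeledPointSet,
    ParameterError,
    WorkflowReport,
    boundary_voxels,
    default_experiment_configs,
    dice,
    fiducial_separation,
    hausdorff95,
    holm_correction,
    paired_compare,
    run_experiment,
)
from hybridir.phantom import (
    ContourNoiseSpec,
    DeformationSpec,
    DegradationSpec,
    PhantomSpec,
    make_case,
)


def cube_mask(n, lo, hi):
    grid = Grid((n,) * 3, (1.0,) * 3, (0.0,) * 3)
    vox = np.zeros((n,) * 3, bool)
    vox[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return BinaryMask(vox, grid)


class TestDice:
    def test_identical_and_disjoint(self):
        a = cube_mask(10, (1, 1, 1), (4, 4, 4))
        b = cube_mask(10, (6, 6, 6), (9, 9, 9))
        assert dice(a, a) == 1.0
        assert dice(a, b) == 0.0

    def test_offset_cubes_voxel_counting(self):
        # 3^3 cubes offset by one voxel in x: 2*18/54
        a = cube_mask(10, (2, 2, 2), (5, 5, 5))
        b = cube_mask(10, (3, 2, 2), (6, 5, 5))
        assert abs(dice(a, b) - 2.0 * 18.0 / 54.0) < 1e-12

    def test_symmetry_exact(self):
        rng = np.random.default_rng(0)
        grid = Grid((8, 8, 8), (1.0,) * 3, (0.0,) * 3)
        a = BinaryMask(rng.uniform(size=(8, 8, 8)) > 0.5, grid)
        b = BinaryMask(rng.uniform(size=(8, 8, 8)) > 0.5, grid)
        assert dice(a, b) == dice(b, a)

    def test_geometry_mismatch_rejected(self):
        a = cube_mask(10, (1, 1, 1), (4, 4, 4))
        b = BinaryMask(a.voxels.copy(), Grid((10,) * 3, (2.0,) * 3, (0.0,) * 3))
        with pytest.raises(GeometryError):
            dice(a, b)

    def test_both_empty_is_one_with_warning(self):
        grid = Grid((4,) * 3, (1.0,) * 3, (0.0,) * 3)
        empty = BinaryMask(np.zeros((4, 4, 4), bool), grid)
        with pytest.warns(UserWarning):
            assert dice(empty, empty) == 1.0


def brute_force_hd95(a, b):
    sp = np.asarray(a.grid.spacing)
    pa = np.argwhere(boundary_voxels(a)) * sp
    pb = np.argwhere(boundary_voxels(b)) * sp
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return max(np.percentile(d.min(1), 95), np.percentile(d.min(0), 95))


class TestHausdorff95:
    def test_identical_masks_give_zero(self):
        m = sphere_mask(12, 1.0, (0, 0, 0), 4.0)
        assert hausdorff95(m, m) == 0.0

    def test_single_voxel_pair_distance(self):
        grid = Grid((8,) * 3, (1.0,) * 3, (0.0,) * 3)
        a = np.zeros((8,) * 3, bool)
        b = np.zeros((8,) * 3, bool)
        a[2, 4, 4] = True
        b[5, 4, 4] = True
        assert abs(hausdorff95(BinaryMask(a, grid), BinaryMask(b, grid)) - 3.0) < 1e-12

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        grid = Grid((11, 12, 9), (1.0, 1.5, 2.0), (0.0,) * 3)
        a = BinaryMask(rng.uniform(size=(11, 12, 9)) > 0.7, grid)
        b = BinaryMask(rng.uniform(size=(11, 12, 9)) > 0.7, grid)
        if not a.voxels.any() or not b.voxels.any():
            pytest.skip("degenerate draw")
        assert abs(hausdorff95(a, b) - brute_force_hd95(a, b)) < 1e-9

    def test_dice_one_implies_hd95_zero(self):
        m = sphere_mask(10, 1.0, (0, 0, 0), 3.0)
        assert dice(m, m) == 1.0 and hausdorff95(m, m) == 0.0

    def test_empty_mask_error_names_which(self):
        grid = Grid((4,) * 3, (1.0,) * 3, (0.0,) * 3)
        empty = BinaryMask(np.zeros((4, 4, 4), bool), grid)
        full = BinaryMask(np.ones((4, 4, 4), bool), grid)
        with pytest.raises(ParameterError, match="second"):
            hausdorff95(full, empty)


class TestFiducialSeparation:
    def test_plain_euclidean_distance_at_identity(self):
        t = BSplineTransform((-50.0,) * 3, (20.0,) * 3, (7, 7, 7))
        fixed = LabeledPointSet(["a_top"], [[0.0, 0.0, 0.0]])
        moving = LabeledPointSet(["a_top"], [[3.0, 4.0, 0.0]])
        seps = fiducial_separation(fixed, moving, t)
        assert abs(seps["a_top"] - 5.0) < 1e-12

    def test_label_mismatch_lists_offenders(self):
        t = BSplineTransform((-50.0,) * 3, (20.0,) * 3, (7, 7, 7))
        fixed = LabeledPointSet(["a_top"], [[0.0, 0.0, 0.0]])
        moving = LabeledPointSet(["b_top"], [[0.0, 0.0, 0.0]])
        with pytest.raises(ParameterError, match="a_top"):
            fiducial_separation(fixed, moving, t)


def test_separation_consistent_with_exported_displacement_field():
    # recompute separations from the dense displacement-field export
    # (linear interpolation at the marker positions) as an independent route
    case = make_case(PhantomSpec(grid_size=(32, 32, 32), spacing=(4.0,) * 3, seed=6))
    t = case.truth
    seps = fiducial_separation(case.fixed_fiducials, case.moving_fiducials, t)
    # export on a 1 mm grid so linear interpolation of the dense field is
    # accurate enough for a 0.01 mm comparison
    pmin, pmax = case.fixed.grid.extent
    n = tuple(int(np.ceil(hi - lo)) + 1 for lo, hi in zip(pmin, pmax))
    export_grid = Grid(n, (1.0, 1.0, 1.0), tuple(pmin))
    field = t.displacement_field(export_grid)
    from scipy.ndimage import map_coordinates

    idx = export_grid.physical_to_voxel(case.fixed_fiducials.points)
    disp = np.stack(
        [map_coordinates(field[..., c], idx.T, order=1, mode="nearest") for c in range(3)],
        axis=1,
    )
    mapped = case.fixed_fiducials.points + disp
    recomputed = np.linalg.norm(mapped - case.moving_fiducials.points, axis=1)
    reference = np.array([seps[l] for l in case.fixed_fiducials.labels])
    assert np.abs(recomputed - reference).max() < 0.01


class TestPairedCompare:
    def test_zero_differences_flagged_degenerate(self):
        x = np.arange(10.0)
        p, test = paired_compare(x, x)
        assert np.isnan(p) and test == "degenerate"

    def test_large_shift_detected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.0, 1.0, size=10)
        y = x + 3.0 + rng.normal(0.0, 0.3, size=10)
        p, _ = paired_compare(x, y)
        assert p < 0.01

    def test_non_normal_differences_use_wilcoxon(self):
        rng = np.random.default_rng(1)
        x = np.zeros(25)
        y = rng.exponential(1.0, size=25) ** 3  # heavily skewed differences
        _, test = paired_compare(x, y)
        assert test == "wilcoxon"

    def test_normal_differences_use_t_test(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = x + rng.normal(0.1, 1.0, size=30)
        _, test = paired_compare(x, y)
        assert test == "paired t-test"


def test_holm_correction_known_example():
    adj = holm_correction([0.01, 0.04, 0.03])
    assert adj[0] == pytest.approx(0.03)
    assert adj[1] == pytest.approx(0.06)
    assert adj[2] == pytest.approx(0.06)
    with_nan = holm_correction([0.01, float("nan")])
    assert with_nan[0] == pytest.approx(0.01)
    assert np.isnan(with_nan[1])


def test_workflow_report_csv_round_trip(tmp_path):
    report = WorkflowReport(
        metrics=pd.DataFrame(
            dict(case=[0, 0], workflow=["no_pd", "exact_pd"], structure=["prostate"] * 2,
                 dsc=[0.61, 0.89], hd95=[11.75, 3.27], failed=["", ""])
        ),
        fiducials=pd.DataFrame(
            dict(case=[0], workflow=["no_pd"], label=["fid1_top"], separation_mm=[8.95])
        ),
        summary=pd.DataFrame(dict(workflow=["no_pd"], structure=["prostate"],
                                  dsc_mean=[0.61], dsc_sd=[0.18], hd95_mean=[11.75], hd95_sd=[5.3])),
        comparisons=pd.DataFrame(dict(structure=["prostate"], metric=["dsc"],
                                      pair=["no_pd_vs_exact_pd"], p=[0.002], p_holm=[0.006],
                                      test=["paired t-test"])),
    )
    report.to_csv(tmp_path / "report")
    back = WorkflowReport.from_csv(tmp_path / "report")
    pd.testing.assert_frame_equal(back.metrics.fillna(""), report.metrics)
    pd.testing.assert_frame_equal(back.summary, report.summary)


def test_identity_problem_reaches_high_dice_under_all_workflows():
    # zero deformation, no degradation: every workflow must solve it
    cases = [
        make_case(
            PhantomSpec(
                grid_size=(32, 32, 32), spacing=(4.0,) * 3, seed=s,
                deformation=DeformationSpec(peak_magnitude=0.0),
                degradation=DegradationSpec(0.0, 0.0, 0.0, 90.0, 0.0),
                contour_noise=ContourNoiseSpec(target_dice=1.0),
            )
        )
        for s in (0, 1)
    ]
    cfgs = default_experiment_configs(structure_max_points=400)
    report = run_experiment(cases, cfgs)
    assert (report.metrics.failed == "").all()
    assert report.metrics.dsc.min() > 0.99
    assert report.fiducials.separation_mm.max() < 0.5
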