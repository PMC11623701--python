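import numpy as np
import pytest

from hybridir import (
    ConvergenceError,
    PhantomSpec,
    SpecificationError,
    degrade_to_cbct,
    dice,
    fiducial_separation,
    make_case,
    make_phantom,
    make_truth_deformation,
    perturb_contours,
)
from hybridir.phantom import (
    ContourNoiseSpec,
    DeformationSpec,
    DegradationSpec,
    ORGAN_NAMES,
    OrganGeometry,
)

QUIET = DegradationSpec(0.0, 0.0, 0.0, 90.0, 0.0)  # no degradation at all


class TestMakePhantom:
    def test_construction_invariants(self):
        fixed, masks, fids = make_phantom(PhantomSpec(seed=0))
        assert set(masks) == set(ORGAN_NAMES)
        names = list(masks)
        for i, a in enumerate(names):
            assert masks[a].voxels.any()
            for b in names[i + 1 :]:
                assert not (masks[a].voxels & masks[b].voxels).any()
        body = fixed.voxels > -500  # anything above background is body/bone/organ
        for m in masks.values():
            assert not (m.voxels & ~body).any()

    def test_fiducial_labeling_contract(self):
        _, _, fids = make_phantom(PhantomSpec(seed=1, n_fiducials=3))
        assert len(fids) == 6
        stems = {l.rsplit("_", 1)[0] for l in fids.labels}
        assert len(stems) == 3
        for stem in stems:
            assert f"{stem}_top" in fids.labels and f"{stem}_bottom" in fids.labels
            gap = fids.position(f"{stem}_top") - fids.position(f"{stem}_bottom")
            assert np.allclose(gap, [0.0, 0.0, 3.0])

    def test_determinism_bit_for_bit(self):
        a = make_phantom(PhantomSpec(seed=5))
        b = make_phantom(PhantomSpec(seed=5))
        assert np.array_equal(a[0].voxels, b[0].voxels)
        assert np.array_equal(a[2].points, b[2].points)
        c = make_phantom(PhantomSpec(seed=6))
        assert not np.array_equal(a[2].points, c[2].points)

    def test_impossible_geometry_rejected(self):
        organs = OrganGeometry(prostate_center=(0.0, 8.0, 10.0))  # collides with bladder
        with pytest.raises(SpecificationError):
            make_phantom(PhantomSpec(seed=0, organs=organs))


class TestTruthDeformation:
    def test_zero_peak_is_identity(self):
        spec = PhantomSpec(seed=0, deformation=DeformationSpec(peak_magnitude=0.0))
        t = make_truth_deformation(spec)
        assert np.abs(t.coefficients).max() == 0.0

    def test_peak_magnitude_rescaling_is_exact(self):
        spec = PhantomSpec(seed=3, deformation=DeformationSpec(peak_magnitude=10.0))
        t = make_truth_deformation(spec)
        mags = np.linalg.norm(t.displacement(spec.grid.voxel_centers()), axis=1)
        assert abs(mags.max() - 10.0) < 1e-6

    def test_determinism(self):
        spec = PhantomSpec(seed=4)
        a = make_truth_deformation(spec)
        b = make_truth_deformation(spec)
        assert np.array_equal(a.coefficients, b.coefficients)


class TestDegradation:
    def test_no_degradation_is_identity(self):
        spec = PhantomSpec(seed=0, degradation=QUIET)
        fixed, _, _ = make_phantom(spec)
        out = degrade_to_cbct(fixed, spec)
        assert np.array_equal(out.voxels, fixed.voxels)

    def test_full_compression_hides_organs(self):
        spec = PhantomSpec(seed=0, degradation=DegradationSpec(1.0, 0.0, 0.0, 90.0, 0.0))
        fixed, masks, _ = make_phantom(spec)
        out = degrade_to_cbct(fixed, spec)
        body_level = spec.intensities.body
        for name in ORGAN_NAMES:
            # implanted markers (metal) keep their contrast; soft tissue does not
            soft = masks[name].voxels & (fixed.voxels == spec.intensities.organ(name))
            assert np.abs(out.voxels[soft] - body_level).max() < 1e-6

    def test_noise_statistics_match_requested_sd(self):
        base = PhantomSpec(seed=9, degradation=DegradationSpec(0.0, 0.0, 0.0, 90.0, 0.0))
        noisy_spec = PhantomSpec(seed=9, degradation=DegradationSpec(0.0, 20.0, 0.0, 90.0, 0.0))
        fixed, _, _ = make_phantom(base)
        clean = degrade_to_cbct(fixed, base)
        noisy = degrade_to_cbct(fixed, noisy_spec)
        body = fixed.voxels > -500
        sd = np.std(noisy.voxels[body] - clean.voxels[body])
        assert abs(sd - 20.0) / 20.0 < 0.05

    def test_degradation_never_moves_anatomy(self):
        # exact moving masks are identical whether or not the moving image
        # is degraded: degradation touches intensities only
        quiet = PhantomSpec(seed=2, degradation=QUIET)
        loud = PhantomSpec(seed=2)  # default (strong) degradation
        a = make_case(quiet)
        b = make_case(loud)
        for name in ORGAN_NAMES:
            assert np.array_equal(
                a.moving_masks_exact[name].voxels, b.moving_masks_exact[name].voxels
            )


class TestPerturbContours:
    def test_target_one_returns_unchanged_mask(self):
        _, masks, _ = make_phantom(PhantomSpec(seed=0))
        out = perturb_contours(masks["prostate"], 1.0, 2.0, seed=1)
        assert np.array_equal(out.voxels, masks["prostate"].voxels)

    def test_default_prostate_hits_dice_080(self):
        _, masks, _ = make_phantom(PhantomSpec(seed=0))
        out = perturb_contours(masks["prostate"], 0.80, 2.0, seed=2)
        d = dice(out, masks["prostate"])
        assert 0.78 <= d <= 0.82

    def test_deterministic_given_seed(self):
        _, masks, _ = make_phantom(PhantomSpec(seed=0))
        a = perturb_contours(masks["bladder"], 0.85, 2.0, seed=3)
        b = perturb_contours(masks["bladder"], 0.85, 2.0, seed=3)
        assert np.array_equal(a.voxels, b.voxels)

    def test_invalid_targets_rejected(self):
        _, masks, _ = make_phantom(PhantomSpec(seed=0))
        from hybridir import ParameterError

        with pytest.raises(ParameterError):
            perturb_contours(masks["prostate"], 0.0, 2.0, seed=4)
        with pytest.raises(ParameterError):
            perturb_contours(masks["prostate"], 1.2, 2.0, seed=4)


class TestMakeCase:
    def test_identity_case_moving_equals_fixed(self):
        spec = PhantomSpec(
            seed=1, deformation=DeformationSpec(peak_magnitude=0.0), degradation=QUIET,
            contour_noise=ContourNoiseSpec(target_dice=1.0),
        )
        case = make_case(spec)
        assert np.array_equal(case.moving.voxels, case.fixed.voxels)
        for name in ORGAN_NAMES:
            assert np.array_equal(
                case.moving_masks_exact[name].voxels, case.fixed_masks[name].voxels
            )

    def test_truth_maps_fixed_fiducials_onto_moving_fiducials(self):
        case = make_case(PhantomSpec(seed=2))
        mapped = case.truth.transform_point(case.fixed_fiducials.points)
        assert np.abs(mapped - case.moving_fiducials.points).max() < 1e-9
        seps = fiducial_separation(case.fixed_fiducials, case.moving_fiducials, case.truth)
        assert max(seps.values()) < 1e-9

    def test_truth_transform_is_evaluation_zero_point(self):
        case = make_case(PhantomSpec(seed=2))
        for name in ORGAN_NAMES:
            warped = case.truth.warp_image(
                case.moving_masks_exact[name], case.fixed.grid, interp="nearest"
            )
            assert dice(case.fixed_masks[name], warped) > 0.95

    def test_noisy_contour_quality_within_tolerance(self):
        for seed in (2, 8, 15):
            case = make_case(PhantomSpec(grid_size=(48, 48, 48), spacing=(2.5,) * 3, seed=seed))
            for name in ORGAN_NAMES:
                d = dice(case.moving_masks_noisy[name], case.moving_masks_exact[name])
                assert abs(d - case.spec.contour_noise.target_dice) <= 0.05
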