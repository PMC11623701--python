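# hybridir

Hybrid intensity + structure-guided deformable image registration for
adaptive radiotherapy workflows, with a synthetic pelvic phantom lab for
controlled evaluation.

## The problem

Adaptive radiation therapy re-plans treatment from on-couch cone-beam CT
(CBCT), which must be deformably registered to the planning CT. Pelvic
soft tissue (prostate, bladder, rectum) has poor contrast on CBCT — noise,
scatter and intensity non-uniformity blur exactly the boundaries the
registration must align — so purely intensity-driven deformable image
registration (DIR) often fails there. A hybrid similarity metric fixes this
by adding a structural term: known organ contours pull the deformation onto
the right anatomy where the intensities are uninformative.

`hybridir` implements this hybrid DIR end to end: a cubic B-spline
free-form deformation `T(θ)` optimized (L-BFGS-B, multi-resolution) under
the cost

```
C(θ) = Ψ(f, m∘T)  +  λ S(v)  +  Σₙ ηₙ Σ_{π∈Πₙ} dmapₙ(T(π))
```

* `Ψ` — mean squared intensity difference between the fixed image `f` and
  the warped moving image `m∘T`;
* `S(v)` — bending energy (curvature) of the displacement field `v`, weight `λ`;
* the point-to-distance (PD) term — for each structure `n`, the unsigned
  Euclidean distance map of the *moving*-image structure boundary, sampled
  at the transformed fixed-image surface points `Πₙ`, weight `ηₙ`.

All three terms carry analytic gradients with respect to the B-spline
coefficients (verified against finite differences to ~1e-7 relative error).

Because clinical CT/CBCT pairs with expert contours cannot ship with a
library, the package includes a **phantom lab**: a parametric pelvic
phantom (organ analogs, implanted fiducial pairs, known smooth ground-truth
deformation, CBCT-like degradation, and contour noise calibrated in Dice to
emulate auto-segmentation quality). On these cases the three clinical
workflows are compared:

| workflow   | PD contours                                   |
|------------|-----------------------------------------------|
| `no_pd`    | none — traditional intensity-only DIR          |
| `noisy_pd` | degraded contours (auto-segmentation quality)  |
| `exact_pd` | exact contours (expert-segmentation benchmark) |

scored with DSC, 95% Hausdorff distance and fiducial separation.

## Worked example

```python
import numpy as np
from hybridir import (PhantomSpec, make_case, register, dice,
                      fiducial_separation, default_experiment_configs)

case = make_case(PhantomSpec(grid_size=(48, 48, 48), spacing=(2.5,)*3, seed=11))
cfgs = default_experiment_configs(final_shrink=2)

for workflow, masks in (("no_pd", {}), ("exact_pd", case.moving_masks_exact)):
    res = register(case.fixed, case.moving, case.fixed_masks, masks, cfg=cfgs[workflow])
    w = res.transform.warp_image(case.moving_masks_exact["prostate"],
                                 case.fixed.grid, interp="nearest")
    seps = fiducial_separation(case.fixed_fiducials, case.moving_fiducials, res.transform)
    print(workflow, "prostate DSC %.3f" % dice(case.fixed_masks["prostate"], w),
          "fiducial sep %.2f mm" % np.mean(list(seps.values())))
```

prints

```
no_pd prostate DSC 0.768 fiducial sep 2.40 mm
exact_pd prostate DSC 0.931 fiducial sep 0.53 mm
```

The degraded CBCT-like contrast leaves intensity-only registration stuck
near its starting overlap, while the contour-guided hybrid recovers the
ground-truth deformation: higher overlap (DSC) and sub-voxel residual at
the implanted markers. The `examples/` scripts walk through each
capability (phantom generation, registration, metrics, the ablation study)
and print what the numbers mean; the `hybridir` command exposes the same
steps as a CLI (`hybridir phantom|register|evaluate|experiment --help`).

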