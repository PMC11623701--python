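"""Register one degraded phantom case with and without the PD term.

Compares the traditional intensity-only workflow against the hybrid cost
driven by exact (expert-like) moving contours, scoring organ overlap (DSC)
and fiducial separation against the known ground truth.
"""

import numpy as np

from hybridir import (
    PhantomSpec,
    default_experiment_configs,
    dice,
    fiducial_separation,
    make_case,
    register,
)

case = make_case(PhantomSpec(grid_size=(48, 48, 48), spacing=(2.5,) * 3, seed=11))
cfgs = default_experiment_configs(final_shrink=2)

for workflow, moving_masks in (("no_pd", {}), ("exact_pd", case.moving_masks_exact)):
    result = register(case.fixed, case.moving, case.fixed_masks, moving_masks,
                      cfg=cfgs[workflow])
    seps = fiducial_separation(case.fixed_fiducials, case.moving_fiducials, result.transform)
    print(f"\n{workflow}:")
    for name in case.fixed_masks:
        warped = result.transform.warp_image(
            case.moving_masks_exact[name], case.fixed.grid, interp="nearest"
        )
        print(f"  {name:9s} DSC {dice(case.fixed_masks[name], warped):.3f}")
    print(f"  fiducial separation {np.mean(list(seps.values())):.2f} mm (mean over markers)")

# Higher DSC and lower fiducial separation for exact_pd show the structural
# guidance compensating for the CBCT-like loss of soft-tissue contrast.
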