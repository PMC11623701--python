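"""Build one synthetic CT/CBCT registration case and look inside it.

The phantom lab generates a CT-like fixed volume (body, bone rim, prostate /
bladder / rectum analogs, implanted fiducial pairs), a known smooth
deformation, and a CBCT-like moving volume with exact and degraded contours.
"""

import numpy as np

from hybridir import PhantomSpec, dice, make_case

case = make_case(PhantomSpec(seed=7))

print("fixed volume:", case.fixed.size, "voxels at", case.fixed.spacing, "mm")
print("intensity range: %.0f .. %.0f HU-like" % (case.fixed.voxels.min(), case.fixed.voxels.max()))

for name, mask in case.fixed_masks.items():
    print(f"  {name:9s} {int(mask.voxels.sum()):5d} voxels")

print("\nfiducials:", ", ".join(case.fixed_fiducials.labels))

disp = case.truth.displacement(case.fixed.grid.voxel_centers())
mags = np.linalg.norm(disp, axis=1)
print("\nground-truth deformation: peak %.1f mm over the grid" % mags.max())
pros = case.fixed_masks["prostate"].voxels.reshape(-1)
print("   mean displacement at the prostate analog: %.1f mm" % mags[pros].mean())

print("\ncontour quality of the auto-seg-like noisy masks (Dice vs exact):")
for name in case.fixed_masks:
    d = dice(case.moving_masks_noisy[name], case.moving_masks_exact[name])
    print(f"  {name:9s} {d:.3f}   (target {case.spec.contour_noise.target_dice})")

# The numbers above describe the *problem*: how far anatomy moved and how
# trustworthy the moving-image contours are before any registration runs.
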