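# Methods

## Model

The deformation is a free-form deformation: a displacement field
`v(p) = Σⱼ cⱼ B₃((p − o)/s − j)` on a regular control lattice (uniform
cubic B-splines, knot spacing = control spacing), mapping fixed-image
physical coordinates into moving-image coordinates, `T(p) = p + v(p)`
(pull-back convention: the warped moving image samples `m(T(p))` at fixed
voxel centers). The lattice always covers the fixed-image extent plus a
one-spacing margin, so every point of interest has a full 4×4×4 stencil.
The optimized parameter vector θ is the coefficient array, shape
`(nx, ny, nz, 3)`, flattened in C order — ordering `(x, y, z, component)`.
This ordering is a public contract: serialized transforms, gradients and
optimizer traces all use it.

The cost is

C(θ) = Ψ(f, m∘T) + λ·S(v) + Σₙ ηₙ Σ_{π∈Πₙ} dmapₙ(T(π))

### Intensity term Ψ

Mean squared difference over fixed voxels (optionally restricted to a
domain mask), normalized by the amount of contributing volume, so λ and η
keep their meaning across pyramid levels and image sizes. The moving image
is sampled with an *interpolating cubic B-spline* (prefiltered
coefficients, mirror boundary): the sampled value is C², its analytic
spatial gradient is exact, and therefore the analytic θ-gradient of Ψ
agrees with finite differences to near machine precision. Mean squared
difference fits the mono-modal CT-vs-degraded-CT setting; mutual
information is an extension point, not implemented.

Contributions are feathered to zero across the outermost voxel of the
moving grid with a C² smoothstep window whose derivative is part of the
gradient. Rationale: with a hard inside/outside cut the cost is
discontinuous in θ whenever a sample point crosses the moving-image
border. On matched grids *every* border voxel sits exactly on that edge at
the identity, so the very first line search stalls on a spurious jump.
The feathered window makes the cost C¹ everywhere while still giving
out-of-field samples zero weight.

### Curvature term S(v)

Bending energy: the mean over sample points (every 2nd fixed voxel per
axis by default) of the squared Frobenius norm of the displacement
Hessian, `Σ_c v_c,xx² + v_c,yy² + v_c,zz² + 2(v_c,xy² + v_c,xz² + v_c,yz²)`,
with second derivatives analytic in the cubic basis. Affine fields have
exactly zero energy.

### Point-to-distance (PD) term

For each structure: the moving-image mask's boundary voxels (mask voxels
with a 6-neighbor outside the mask; the grid edge counts as outside) define
an unsigned Euclidean distance map (exact EDT between voxel centers,
anisotropic spacing respected). "Unsigned" means distance to the boundary
*surface* — zero only on the boundary shell, positive in the interior —
so fixed-surface points are attracted onto the moving surface rather than
merely into the structure. The fixed-image structure's boundary voxel
centers are subsampled (seeded, deterministic, default cap 2000 per
structure) into the point set Πₙ.

Off-grid the map is sampled as `|s(p)|` where `s` is the interpolating
cubic spline of the EDT values: the absolute value implements the metric
literally, guarantees nonnegativity (the spline can undershoot zero near
the boundary), and is differentiable away from the measure-zero zero set.
Outside the grid's bounding box the value continues as (value at the
clamped position + distance to the box) — continuous across the faces —
so the term keeps pulling points back when the optimizer pushes them
outside a short CBCT field of view. Distance maps and their spline
coefficients are built once per structure per pyramid level.

## Optimization

L-BFGS-B (scipy, no bounds — the quasi-Newton path with memory 20) over a
Gaussian pyramid. Default schedule: image shrink (4, 2, 1) with control
spacing (40, 20, 10) mm and iteration caps (50, 60, 80); pyramid levels use
σ = 0.5·shrink voxels of smoothing and block-centered resampling (physical
center preserved). Between levels the transform is carried by the exact
dyadic two-scale relation (the (1,4,6,4,1)/8 mask per axis; reproduces the
coarse field to machine precision) or, for non-dyadic spacing changes, by
a ridge-stabilized least-squares fit to the coarse displacements on the
fine lattice and its midpoints. θ starts at zero (identity); there is no
rigid pre-alignment stage (phantom cases are generated pre-aligned; a
rigid initializer is an extension point). `grad_tol` maps to the
optimizer's projected-gradient tolerance (max-norm), `rel_cost_tol` to its
relative-reduction tolerance. Runs are deterministic given the
configuration seed; the per-level history records every accepted iterate's
cost breakdown.

## Weights

Ψ is in squared HU (typically 10²–10⁴ on the phantom), S(v) in mm⁻²
(~3×10⁻⁴ for the ground-truth fields, ~10⁻¹ for folded ones), and the PD
term in η·mm summed over ≲2000 points. The defaults were calibrated once
on the default phantom and then frozen:

* `λ = 1×10⁵` — large only because of the unit gap: it prices a folded
  field at ~10³–10⁴ (prohibitive next to the intensity scale) while the
  true deformation costs ~30. Calibration observation: with negligible λ
  the optimizer matches all sampled surface points yet folds the space
  between them — surface residuals near zero, organ overlap poor.
* `η = 0.2` per point for every structure — puts the PD term for a
  misaligned organ (≈10³) on par with the intensity term, so contours
  dominate where CBCT-like contrast is gone but intensity still matters
  where they are silent.

## The phantom lab

The generator defines the study conditions; its defaults are fixed.

* **Anatomy** (physical mm, grid-size independent): body ellipsoid
  (56, 46, 100) mm semi-axes with a bone rim (outer 10% shell); prostate
  analog sphere r = 12 mm; bladder analog ellipsoid (18, 15, 13) mm
  antero-superior; rectum analog tube r = 9 mm, 80 mm long, posterior.
  Intensities (HU-like): background −1000, body 30, bone 500, prostate 90,
  bladder −10, rectum −90. Three fiducial markers (gold-seed analogs,
  r = 1.5 mm blobs at 900) at seeded positions inside the prostate, each
  marked by a top/bottom point pair 3 mm apart.
* **Ground-truth deformation**: seeded i.i.d. normal B-spline coefficients
  (40 mm control spacing) attenuated by a Gaussian envelope (σ = 50 mm
  around the organ region — inter-fraction pelvic deformation is
  soft-tissue dominated while the bony frame stays put), then rescaled so
  the maximum displacement over the grid is exactly `peak_magnitude`.
  Default peak 14 mm, which moves the prostate analog by ~3–7 mm —
  the scale of reported clinical prostate misalignment between planning CT
  and CBCT.
* **CBCT-like degradation** (intensity-only; anatomy never moves):
  soft-tissue intensities compressed toward the body level (default 0.7),
  an effective point-spread blur (σ = 1.5 mm; scatter and reconstruction
  artifacts wash out seeds and soft edges), a multiplicative low-frequency
  bias field (±6%, 90 mm wavelength), and additive Gaussian noise
  (SD 20). All seeded; all-zero parameters return the input bit-for-bit.
* **Moving-image composition.** Registration uses the pull-back
  convention, so the transform the optimizer should recover must satisfy
  `m(T*(p)) = f(p)`. The lab therefore resamples the fixed anatomy through
  the *inverse* of T\* (vectorized fixed-point iteration on a densely
  sampled displacement field, interior residual < 1e-6 mm). T\* itself is
  then the exact optimum, truth-mapped fiducials coincide with the moving
  fiducials to 1e-9 mm, and warping the exact moving masks back through
  T\* reproduces the fixed masks (up to double nearest-neighbor
  resampling, DSC ≈ 0.98) — the evaluation zero point.
* **Contour noise**: a seeded direction field (smooth B-spline component
  for systematic contouring error + smoothed white noise for boundary
  roughening, relative weight `boundary_sd/4`) scaled by bisection until
  Dice against the exact mask lands in `target_dice ± 0.02`. Default
  target 0.80 — the auto-segmentation quality level the noisy workflow
  emulates.

What the phantom does *not* emulate: real CBCT physics (scatter/beam
hardening streaks), anatomically shaped organs, FOV truncation,
multi-patient anatomical variability, observer variability in "expert"
contours. Passing phantom tests shows the method recovers known smooth
deformations under controlled contrast loss with known contour quality —
not clinical performance.

## Evaluation conventions

* **DSC** `2|A∩B|/(|A|+|B|)`; masks must share a grid (no silent
  resampling); two empty masks score 1.0 with a warning.
* **HD95**: boundary voxel centers (6-connectivity), directed distances in
  physical mm, 95th percentile by linear interpolation on each directed
  set, symmetrized by the maximum of the two. This is the dominant
  radiotherapy auto-segmentation convention, stated explicitly because
  percentile/pooling conventions differ across tools.
* **Fiducial separation**: Euclidean distance between the
  transform-mapped fixed marker point and its moving counterpart —
  measured in moving space, so no transform inversion is ever needed.
* **Registration scoring**: the exact moving structures are warped into
  the fixed frame through the recovered transform (nearest neighbor,
  pull-back) and compared with the fixed masks. The noisy contours only
  ever *drive* registration; scoring always uses the exact ones.
* **Statistics**: pairwise paired comparisons with Shapiro–Wilk (α = 0.05)
  gating between the paired t-test and the Wilcoxon signed-rank test,
  Holm-corrected within each (structure, metric) family. A constant
  difference vector is flagged degenerate rather than tested. Omnibus
  ANOVA/Tukey machinery is out of scope: in a paired synthetic design the
  pairwise tests carry the information.

## Study configurations and problem sizes

`default_experiment_configs()` defines the package's standard runs: the
three-workflow ablation uses 48³ phantoms at 2.5 mm and a two-level
pyramid (shrink 4, 2) — about 7 s per registration, so the 10-case,
30-registration study completes in minutes; single-case accuracy runs
(e.g. the 8 mm recovery check) append the full-resolution level on 64³ at
2.0 mm (~1 min per registration). Metrics are always computed on the
full-resolution masks; only the optimization pyramid is truncated.

## Known limitations

* The noisy-PD vs no-PD margin for the *rectum* analog is small and can
  invert on individual seeds: the rectum keeps the best residual contrast
  after degradation, so intensity-only registration already handles it
  well. The prostate and bladder margins are large and stable.
* The feathered-border intensity term assumes the moving field of view
  roughly covers the fixed anatomy; gross FOV mismatch should be handled
  by cropping, not by the window.
* Registration requires identity direction matrices (oblique acquisitions
  must be resampled first); the phantom lab only emits identity grids.
* `|s(p)|` sampling makes the PD gradient noisy exactly on the boundary
  zero set; quasi-Newton line searches tolerate this, but gradient checks
  should probe away from the boundary.
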