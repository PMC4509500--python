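# Methods

This note documents the models, numerical choices and limitations of
`aaaseg`: a two-boundary (thrombus / outer wall) delineation pipeline
for abdominal aortic aneurysms in multispectral MR, built around a
point-distribution shape model and explicit texture statistics.

## Shape model

**Representation.** A shape is 19 transversal slices of 20 landmarks.
Landmarks are placed by casting rays from a per-slice origin at angles
90°, 108°, … (counter-clockwise, anterior = +y of the in-plane axes);
the first landmark is therefore the boundary point anterior of the
origin at its sagittal coordinate. When a ray crosses the boundary more
than once the farthest crossing is used (deterministic tie-break);
contours that are not star-shaped about the origin raise a
degenerate-contour error rather than being silently approximated. A
contour stack spanning the aneurysm is first resampled to 19 evenly
spaced slices by linear interpolation of per-slice radial profiles and
centroids; a target slice coinciding with an input slice passes through
unchanged.

**Straightening.** Each slice is translated so its landmark centre of
mass is the origin (the removed centroids are recorded, making the
operation exactly invertible). This removes centreline/axis variation
on purpose: in segmentation, slice positions are anchored by the lumen
centroids, so only cross-sectional variability needs modelling.

**PCA.** Covariance uses the 1/(n−1) convention. Because n ≪ 1140, the
eigenproblem is solved in the dual (n × n Gram) form, which yields the
identical nonzero spectrum; numerically-zero modes (below 10⁻¹⁰ of the
leading eigenvalue) are discarded. The retained count c is the smallest
prefix reaching the configured fraction (default 0.95) of total
variance. With the default phantom cohort this gives c ≈ 4–5 modes; the
count is a property of the training cohort, not a constant of the
method.

**Plausibility constraint.** If coefficients bᵢ are Gaussian, the
squared Mahalanobis distance D_m = Σ bᵢ²/λᵢ is χ²(c)-distributed, so
the bound M_t is the χ² quantile at probability t (default 0.90) with c
degrees of freedom. Applying the constraint means straighten → project
(b = Φᵀ(x − x̄)) → rescale all bᵢ by α = √(M_t/D_m) if D_m > M_t →
reconstruct x̄ + Φb → unstraighten. Two consequences are intentional:
the output always lies in the retained-mode subspace (this is what
repairs isolated landmark misestimates), and per-slice centroids are
preserved exactly (re-pinned after reconstruction, so the constraint
never moves a slice as a whole). The rescaling is applied
multiplicatively to every coefficient — reading the published
constraint as (αbᵢ)², consistent with the accompanying description of α
reducing all components equally. A stack with k ≠ 19 slices is linearly
resampled in normalized z to 19 virtual slices before the constraint
and back after.

## Appearance model

No grey-profile statistics are learned (too few studies in the
motivating setting); instead five explicit statistics compare the
interior and exterior of each candidate boundary position inside an
11 × 3 mm search region centred on the landmark, long axis along the
lumen-centroid → landmark ray, sampled bilinearly at half the in-plane
voxel spacing:

| statistic | definition | cue |
|---|---|---|
| ΔI | mean(in) − mean(out) | thrombus brighter than wall+surroundings |
| Δm | min(in) − min(out) | dark wall pixels appear outside |
| LmO | I(candidate) − min(out) | boundary pixel still bright |
| std_out | σ(out) | heterogeneous surroundings |
| Δstd | σ(out) − σ(in) | interior more homogeneous |

Samples strictly inside the candidate's radial coordinate are interior,
strictly outside exterior; the candidate's own radial row belongs to
neither. Candidates with fewer than two finite samples on either side
are invalid (σ is undefined); regions with fewer than three valid
candidates fail and leave the landmark in place, flagged.

Each included statistic is min–max normalized to [0, 1] across the
region's valid candidates before summing. This normalization is
training-free and makes the summed metric invariant to any increasing
affine intensity transform; the alternative z-scoring is available in
config. A constant statistic contributes zero. Score ties are broken
toward the smallest |offset| (the landmark stays put), outward on exact
magnitude ties. The default combination is ΔI + Δm + LmO (the
standard-deviation statistics degrade ranking on heterogeneous
surroundings); it is configurable, and `select_statistic_combination` ranks
any requested set of combinations by mean thrombus Dice over a study
set; because normalization is training-free, the leave-one-out
"appearance training" stores only the combination itself.

## Segmentation pipeline

**Lumen (3D).** A morphological Chan–Vese (two-phase region) level set
grows from a ball of radius 3 mm around the user seed on the contrast
channel; the connected component containing the seed is kept and must
be brighter than its complement, otherwise a lumen-failure is raised.
The curvature-smoothing weight defaults to 0: at angiographic lumen
contrast the region term is decisive, and nonzero smoothing measurably
erodes a thin tube on strongly anisotropic grids (6 mm slices). The
weight stays configurable for noisier data.

**Channel registration.** The two channels are related by their world
geometry only; the lumen mask is resampled into the segmentation
channel by nearest-neighbour lookup through world coordinates, and
in-plane lumen centroids are taken per slice. Slices without lumen are
excluded; the longest contiguous run of slices with centroids is
segmented.

**Thrombus initialization (2D).** A circle of radius 5 mm at the lumen
centroid initializes a 2D Chan–Vese level set per slice. The resulting
front (marching-squares contour of the component containing the
centroid) is landmarked with rays from the lumen centroid. Fronts that
collapse, touch the image border, or are not star-shaped fall back to
the initial circle, flagged. There is no robust stop criterion for
inhomogeneous thrombi: on a two-component thrombus the front stops at
the inner component — a documented failure mode reproduced by the
`two_component` phantom confounder.

**Iteration.** Texture proposal (per landmark, along its current ray)
and shape restriction alternate until the maximum landmark displacement
falls below 0.5 × in-plane spacing (strict "no modification" never
triggers in floating point), or 50 iterations. On clean data the loop
converges in 2 iterations.

**Outer wall.** From each (fixed) thrombus landmark the radial
intensity profile is sampled outward over 3 mm, averaged over a 3 mm
tangential window — reading the 3 × 3 mm search area as 3 mm radial
extent × 3 mm tangential support. The offset with the largest strictly
positive central-difference derivative (the dark-wall →
brighter-surroundings transition) is proposed; profiles with no
positive derivative keep the minimum wall offset (one sampling step)
and are flagged. After the shape restriction, radii are clamped into
[thrombus + 1 step, thrombus + 3 mm + 1 step] landmark by landmark, so
the outward-only and thickness invariants hold unconditionally. The
same 19-slice 3D shape model restricts both boundaries.

**Determinism.** The pipeline contains no randomness; phantom
generation derives every stream from one integer seed via
`SeedSequence`. Identical config + seed reproduce results bit for bit.

## Phantom generator

The generator stands in for the unavailable patient cohorts and defines
the study conditions of every quantitative claim in the test suite.

Geometry per study: a circular lumen (radius ≤ 7 mm) nested in a
Fourier-perturbed thrombus cross-section (orders 2–3, amplitudes
N(0, 0.04) clipped at ±0.12, phases drifting slowly along z), scaled
globally by U(0.85, 1.15), with a Gaussian fusiform bulge (amplitude
4–8 mm, centre 0.35–0.65, width 0.25–0.45 in normalized z) and a wall
of uniform thickness U(1.5, 2.5) mm — inside the 3 mm search limit, so
the limit binds only in failure-mode scenarios. A ±2 mm sinusoidal
centreline wobble exercises straightening. Default grid: 19 slices of
80 × 80 pixels at 1 × 1 × 6 mm (a ~108 mm infrarenal section at MR-like
slice thickness); a 30-slice variant exercises the z-resampling path.
This family is low-dimensional by design: a 95%-variance PCA keeps
essentially all systematic variation, matching the modelling premise
that discarded modes are negligible.

Appearance: channel 1 renders lumen/thrombus/wall/background at
160/150/60/100 with a smooth heterogeneity field (σ = 8) and Gaussian
noise σ = 2.5, i.e. 5% of the 50-unit thrombus/background contrast;
channel 2 renders lumen 200 on background 50 with noise σ = 5.
Confounders never alter pixels inside the true thrombus, so ground
truth remains valid: `hyper_adjacent`/`hypo_adjacent` place a 14 mm
sphere centred on the outer boundary (masking the dark wall ring
locally — bright as thrombus, or dark as the wall, respectively), and
`two_component` draws a wall-dark ring inside the thrombus that splits
it in two.

What the phantoms do *not* emulate: MR bias fields, flow and motion
artefacts, partial-volume fading at oblique boundaries, anatomically
realistic centreline curvature, calcifications, and inter-expert
ground-truth variability. Passing the phantom benchmarks therefore
demonstrates correctness of the machinery and the qualitative behaviour
of the shape restriction, not clinical-grade accuracy on patient data.

## Evaluation

Dice is computed on voxel masks rasterized from contours by even–odd
point-in-polygon at pixel centres; both-empty masks score 1, one-empty
scores 0. The modified Hausdorff distance (the larger of the two mean
directed nearest-neighbour distances, outlier-robust and monotone in
mismatch) is computed in world mm on boundary points densified to
≤ 0.5 mm arc spacing, over the full 3D point clouds by default with a
slice-wise 2D option in config. Predictions are scored on the slice
range the pipeline actually segmented. The leave-one-out harness trains
the shape model once, fixes the statistic combination, segments each
study and reports per-study rows plus per-structure mean ± SD; failed
studies appear as flagged rows excluded from the summary.

Typical numbers under the default conditions (8-study batch, seed-
derived): mean thrombus Dice ≈ 0.93 / MHD ≈ 1.0 mm, outer Dice ≈ 0.96 /
MHD ≈ 0.6–0.8 mm; on confounder batches the shape restriction lowers
mean MHD for both boundaries (e.g. 1.10 vs 1.55 mm thrombus, 0.83 vs
1.03 mm outer on seed 7). These are recomputed, not stored, by
`scripts/acceptance.py` and the test suite.

## Numerical choices and edge cases

- Landmark radial bias: the texture metric anchors on the last interior
  pixel, so proposals sit up to one pixel inside the geometric
  boundary; MHD at the default grid reflects this ~0.5 mm floor.
- Bilinear sampling outside the image yields NaN; statistics are
  NaN-aware and clipped regions are flagged.
- Gradient search uses `np.gradient` (central differences, one-sided at
  the ends) on the oversampled profile; argmax takes the first (i.e.
  innermost) of exactly tied maxima.
- Polygon rasterization uses pixel-centre containment (half-open
  convention); contours are matched to the nearest slice within half a
  slice spacing.
- The dual-form PCA and the direct covariance eigensolver agree to
  10⁻⁸ on the retained subspace (tested).
- Problem sizes in the shipped experiments (80 × 80 × 19 grids, 8-study
  batches, 75 training geometries) were chosen as the smallest cohort
  at which the batch statistics are stable; larger grids only sharpen
  the same comparisons.

## Known limitations

- The thrombus-initialization level set has no inhomogeneity-robust
  stop criterion; split thrombi are initialized on the inner component
  and the texture stage does not recover (reproduced in tests).
- Walls thicker than the 3 mm search limit cannot be delineated
  correctly; the search flags and caps instead.
- Only axis-aligned volume geometry is supported (oblique acquisitions
  must be resampled upstream).
- The shape restriction projects onto the retained-mode subspace, so
  genuinely novel anatomy (outside the training family) is
  over-restricted toward plausible shapes — visible as a small accuracy
  cost on clean data that buys robustness under confounders.
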