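# Methods

This note records the models, conventions and numerical choices behind the
package, and what the phantom-based validation does and does not show.

## Coordinate and voxel conventions

Volumes are `(z, y, x)` arrays with axis 0 the stack axis, which is taken
to be the bone's long axis. World coordinates are `(x, y, z)` in μm from
the volume corner; voxel `(iz, iy, ix)` has its centre at
`((ix+0.5)h, (iy+0.5)h, (iz+0.5)h)` for voxel size `h`. Voxelisation is by
centre-of-voxel inclusion. Component volumes are voxel count × h³ with no
partial-volume correction.

## Segmentation

* **Threshold.** The minimum cross-entropy criterion is minimised
  exhaustively over the observed grey levels (vectorised cumulative sums;
  candidates are all levels with both classes non-empty). Foreground is
  *strictly above* the threshold; ties break toward the lowest threshold;
  the chosen level is logged. Continuous-valued images with more than 2¹⁶
  distinct values are binned to 1024 histogram bins first. Grey levels are
  shifted to be positive before taking logs, applied uniformly to all
  candidates.
* **Cortex closing.** Closing with a discrete Euclidean ball of radius
  `closing_radius` voxels (default 8, i.e. comfortably above the canal
  radii the phantom generates, 2–4 voxels), implemented exactly via two
  distance transforms. The volume is edge-replicate padded by the closing
  radius first: without padding, the truncated dilation leaves a one-voxel
  rind along faces where the structure is cut by the volume border
  (quadrant crops). Cavities fully enclosed after closing are filled by 3D
  hole filling; the medullary lumen stays open because it meets the stack
  ends. The number/size of closing iterations is a free parameter of the
  original workflow; here it is a single radius, configurable.
* **Connectivity.** Pores are labelled with 26-connectivity; the
  complementary 6-connectivity is used for hole filling. Components
  touching the volume border are retained (quadrant crops cut canals at
  every border).
* **Canal/lacuna partition.** "Larger than 1000 μm³" is read as strictly
  greater; a component of exactly 1000 μm³ is a lacuna. The exclusion mask
  (manually delineated medullary bone in real material) is subtracted
  before labelling.

## Morphometry

* **Porosity** = canal voxels / solid-cortex voxels; the denominator is the
  filled cortex (pore space included).
* **Local thickness** follows the sphere-fitting (model-independent)
  definition: thickness at p = 2·max{ρ(c) : sphere at c covers p}. The
  sphere-radius field is ρ = EDT − 0.5 voxels (an isolated voxel is one
  voxel thick), and a sphere centred at c covers the voxels whose centres
  lie within EDT(c) = ρ + 0.5 — this half-voxel pairing keeps digital balls
  and slabs at their nominal thickness. The map is computed by sweeping
  radii and marking coverage with one distance transform per radius. For
  masks with ≤256 distinct radii in a ≤2-Mvoxel bounding box the sweep uses
  the exact radius set (the result then *equals* the brute-force
  inscribed-sphere definition); otherwise a radius grid of 0.5 voxels,
  coarsened to rho_max/40 on very thick structures, bounds the work at ~40
  distance transforms. Diameters are exact to one radius step, so thick
  cortices are measured with a granularity of a few μm (e.g. 287 μm
  recovered for a 300 μm wall at 2 μm voxels); the ±1-voxel agreement with
  the brute-force oracle is asserted on small instances.
* **Second moment of area** uses the circular-annulus closed form
  I = π/4(r₂⁴ − r₁⁴) with r₁ = r₂ − cortical thickness. r₂ comes from
  calliper/config input, or from the helper that estimates the mean
  periosteal radius of the mid-slice; porosity is deliberately not
  corrected for, so I overestimates on porous bone.

## Orientation

* **Skeleton.** 3D thinning (`skimage.morphology.skeletonize`). Branch
  decomposition is done on the 26-connected skeleton graph: branches run
  between nodes of degree ≠ 2; pure cycles are split into two chords at
  their two most (Euclidean) distant nodes. Thinning retracts branch ends
  by roughly (tube radius − 2) voxels, which shortens chords of isolated
  tubes accordingly; at the canal radii generated here (2–4 voxels) the
  effect is ≤2 voxels per end.
* **Chords.** Each branch is reduced to the straight chord between its
  terminal voxels; chord length (not path length) is used for weighting,
  matching the straight-segment abstraction — path length is recorded for
  diagnostics. Chords shorter than `min_segment_length` (default 3 voxels)
  are dropped as thinning spurs.
* **Angles.** Directions are sign-free (all formulas use |dot products|).
  θL = arcsin|v_z|. θR = arcsin|v·r̂| with r̂ the in-plane unit vector from
  the bone axis to the chord midpoint; the "nearest tangent plane" is that
  of the circular cylinder fitted to the periosteal surface, exact for a
  circular cross-section. The two angles satisfy sin²θL + sin²θR ≤ 1, so
  the radial category (θR ≥ 67.5°) can only occur with θL ≤ 22.5°.
* **Classification.** Box bounds are inclusive; longitudinal is tested
  first (its box spans any radial angle), then radial, then laminar; the
  remainder is oblique. The truth table is verified exhaustively on a 0.1°
  grid.
* **Centre estimation.** Seeded RANSAC over 3-point circle fits on the
  mid-slice boundary, refined by algebraic (Kåsa) least squares on the
  consensus set. Degeneracy guards: fitted radius ≤5× the boundary extent,
  consensus arc ≥30°, and a straight-line fit must *not* explain the
  consensus set (max perpendicular residual > 3× the inlier tolerance) —
  otherwise the geometry has no measurable curvature and the fit fails.
  The centre may lie outside a quadrant crop; a config override is
  available.

## Phantom generator

The phantom emulates a mid-diaphyseal cortex quadrant: a shell of outer
radius 600 μm, wall 300 μm, height 400 μm at 2 μm voxels (full ring or
sector), grey levels 200 (bone) over 50 (background/pores) with additive
Gaussian noise sd 10 (~7% of contrast). Canals are tubes with radii
uniform in 4–8 μm and target lengths 100–200 μm: laminar canals are
circumferential/helical arcs at fixed radius (the chord of such an arc is
exactly perpendicular to the radial direction at its midpoint, so the
chord-based true radial angle is 0 and the pitch sets θL); longitudinal,
radial and oblique canals are straight tubes whose (θL, θR) are drawn
uniformly from the feasible part of the category box (rejection sampling
under sin²θL + sin²θR ≤ 1). Category counts are a multinomial draw from the
requested mixture. Canals are trimmed to the shell with a tube-radius
margin and re-drawn if the trimmed chord leaves the category box or falls
below 60 μm; unplaceable canals are skipped with a warning. Lacunae are
axis-aligned ellipsoids (semi-axes 2.5–7 μm, volume capped at 1000 μm³);
lacunae that would touch a canal are dropped so the two pore classes stay
disjoint by construction. Ground-truth masks are noise-free; rendering is
bit-reproducible for a fixed seed, which is stored in the manifest.

What the phantom does *not* emulate: reconstruction artefacts (rings,
phase fringes), grey-level gradients, medullary-bone texture, osteonal
structure, or realistic canal branching trees (canals intersect only by
chance). Passing the recovery tests therefore demonstrates correctness of
the measurement chain on geometrically ideal data, not robustness to
scanner artefacts. Canal radius and length distributions are free
parameters, not calibrated to any particular specimen series.

The phantom study conditions used by the analysis drivers: 200 canals,
mixture (0.4, 0.3, 0.2, 0.1), 150 lacunae, quadrant sector 0–90°, seed 11 —
about 18 Mvoxels, which keeps a full pipeline run around 1–2 minutes on
one CPU.

## Growth statistics

* **Gompertz.** y(t) = A·exp(−b·e^(−kt)), A, b, k > 0. Start values: A at
  1.05×max(y), k from a log-linearised regression of log log(A/y) on t, b
  from the earliest observation; 10 log-normally jittered restarts
  (sd 0.4 in log-space) guard against local minima and the lowest-RSS
  solution is kept, so multi-start refinement never increases the RSS.
  Parameters are bounded positive (trust-region least squares). Constant
  responses and k → 0 are reported as degenerate rather than fitted.
  Confidence bands are first-order delta-method with a t quantile on
  n − 3 df. Inflection age ln(b)/k and maximum rate A·k/e are exposed in
  closed form and verified against a grid argmax of the rate curve.
* **Age interpolation** is a linear map from body mass to age between two
  anchors (defaults: day 1 and day 42); masses outside the anchor range
  are rejected rather than extrapolated. Age classes: juvenile ≤42 d,
  sub-adult ≤6 months, adult older.
* **Beta regression.** Maximum likelihood for y ~ Beta(μφ, (1−μ)φ) with
  logit(μ) = Xβ and constant precision (no precision covariates), via
  statsmodels' beta-regression model behind the package surface.
  Responses exactly 0 or 1 trigger the standard (y(n−1)+0.5)/n shrinkage
  (interior data pass through untouched). pseudo-R² = corr(η, logit y)²,
  defined as 0 for an intercept-only model. The LR test uses
  2Δℓ ~ χ²(Δparams); tiny negative statistics from optimiser noise are
  clipped to 0. Type-I calibration is checked at n = 100 per dataset over
  1000 null simulations — the χ² reference is asymptotic and visibly
  liberal below n ≈ 50.
* **Cohort driver.** Per species/bone: Gompertz fits for length and for
  the radius curve (diameter/2); beta regressions of porosity and each
  orientation index on age and on the fitted radial growth rate at each
  specimen's age; Pearson correlations for unbounded responses. Raw
  p-values are reported and the number of tests is recorded; no
  multiplicity correction is applied.
* **Synthetic cohorts** are sampled from known per-bone Gompertz curves
  whose maximum rates and inflection ages follow the duck series
  (tibiotarsus fastest in length at ~2.4 mm/day around day 11, humerus
  peaking latest around day 24); asymptotic sizes are plausible adult bone
  sizes. The laminar index increases with age on the logit scale and
  porosity tracks the radial growth rate, so the sign-recovery and power
  checks exercise the same couplings the statistics layer is meant to
  detect.

## Known limitations

* Thickness granularity on very thick structures is rho_max/40 radius
  steps (see above); use `step_voxels=0.5` for full resolution at higher
  cost.
* The radial angle assumes a circular cross-section; strongly elliptical
  cortices bias θR near the extremes of the ellipse.
* Chord shortening from skeleton end-retraction biases recovered lengths
  of isolated tubes low by up to ~2×(radius−2) voxels.
* The annulus second moment of area ignores porosity and non-circularity
  by construction.
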