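# osteovasc

3D histomorphometry and vascular-canal orientation analysis of cortical
bone, for researchers quantifying how the intracortical blood-vessel
network changes through growth — e.g. across an ontogenetic series of avian
long bones imaged by synchrotron CT. The package covers the whole chain
from a grey-value image stack to growth statistics, and ships a
ground-truthed phantom generator so every stage can be validated without
any scan data.

## What it computes

**Segmentation.** A mid-diaphyseal cortex volume is binarised with the
minimum cross-entropy (Li) threshold, the canals are closed with a
Euclidean-ball morphological closing (dilations then erosions, plus hole
filling) to form the solid cortex mask, and the pores — cortex minus
mineralised tissue, minus an optional manual exclusion mask — are labelled
with 26-connectivity and partitioned by component volume: vascular canals
are pores **> 1000 μm³**, osteocyte lacunae everything smaller.

**Morphometry.** Porosity = canal volume / (filled) cortex volume. Mean
canal and cortical thickness follow the sphere-fitting (model-independent)
definition: the thickness at a point is the diameter of the largest
inscribed sphere containing it, averaged over the structure. Bending
stiffness is summarised by the second moment of area of a circular annulus,

  I = π/4 · (r₂⁴ − r₁⁴),  r₁ = r₂ − cortical thickness,

an overestimate on porous bone since intracortical porosity is ignored.

**Orientation.** The canal mask is skeletonised (3D thinning), the skeleton
is split into branches at branch points, and each branch is reduced to its
straight chord. Each chord gets a longitudinal angle θL (90° = parallel to
the bone's long axis) and a radial angle θR (angle out of the local
surface-tangent plane; 90° = a radial spoke), measured about a bone centre
estimated by a robust circle fit to the periosteal boundary. Chords are
classified as

| category | θL (°) | θR (°) |
|---|---|---|
| longitudinal | 67.5–90 | any |
| radial | 0–67.5 | 67.5–90 |
| laminar | 0–67.5 | 0–22.5 |
| oblique | everything else | |

and the four **orientation indices** (laminarity etc.) are the
chord-length-weighted proportions of each class; they sum to 1.

**Growth statistics.** Gompertz curves y(t) = A·exp(−b·e^(−kt)) fitted by
multi-start nonlinear least squares; growth rate as the first derivative,
peaking at t\* = ln(b)/k with maximum A·k/e; linear mass→age interpolation
between anchor individuals; logit-link beta regression for proportion
outcomes (porosity, orientation indices) with likelihood-ratio tests and a
pseudo-R² (squared correlation of linear predictor and logit response);
Pearson correlation for unbounded measures.

**Phantom generator.** A hollow-cylinder (or quadrant-sector) cortex with
tubular canals of controllable orientation mixture and radii, sub-1000-μm³
ellipsoidal lacunae, two-level contrast and Gaussian noise. Every canal
carries analytically computed true angles and lengths, so recovered indices
can be scored against exact ground truth.

## Worked example

```python
from osteovasc import phantom as ph, segmentation as seg, \
    morphometry as mm, orientation as ori

vols = ph.build_phantom(200, (0.4, 0.3, 0.2, 0.1), n_lacunae=150,
                        seed=11, sector=(0, 90))
mineral = seg.threshold_min_cross_entropy(vols.grayscale)
cortex  = seg.close_cortex(mineral, closing_radius=8)
canals, lacunae, table = seg.partition_pores(seg.extract_pores(cortex, mineral))
frame = ori.estimate_center(cortex)
segs  = ori.extract_segments(ori.skeletonize(canals), frame)
idx   = ori.orientation_indices(segs)
print(mm.porosity(canals, cortex), idx.laminar_index)
```

Running the numbered drivers under `analysis/` on this phantom prints:

```
porosity 0.0411 (truth 0.0411, rel err 0.01%); canal thickness 10.0 um;
cortical thickness 287.3 um; r2 0.599 mm -> I 0.0937 mm^4
558 chords, total weighted length 26465 um
  laminar_index       recovered 0.398  truth 0.378  |err| 0.020
  longitudinal_index  recovered 0.281  truth 0.320  |err| 0.039
  radial_index        recovered 0.190  truth 0.205  |err| 0.016
  oblique_index       recovered 0.131  truth 0.096  |err| 0.034
```

i.e. porosity is recovered essentially exactly, and each length-weighted
orientation index lands within ±0.04 of the generator's ground truth.
`analysis/04_growth_curves.py` and `05_regressions.py` fit Gompertz curves
and beta regressions on a synthetic duck-like growth series (tibiotarsus
fastest in length, humerus peaking latest) and recover the generating
maximum rates and inflection ages to a few percent.

A command-line interface mirrors the stages
(`osteovasc phantom | segment | measure | orient | run | cohort`).

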