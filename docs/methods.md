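# Methods

## The quantification problem

In dense 3D tissue (retinal organoids being the motivating case), gene
delivery with a cytoplasmic fluorescent reporter cannot be quantified
per-cell by segmenting the reporter channel into cells: cytoplasm in packed
neuro-epithelium has no resolvable cell boundaries, and expression levels
vary over orders of magnitude between cells, so a bulk-fluorescence readout
confounds "many dim transduced cells" with "few bright ones".  The approach
implemented here sidesteps both problems:

1. Nuclei — which *are* segmentable in dense tissue — are instance-segmented
   (externally, e.g. with Cellpose; this package consumes the label volume).
2. The *overall* transduced volume is segmented semantically, without
   separating cells, by a supervised pixel classifier that is robust to
   intensity variation.
3. Each cell is classified by how much of a thin **virtual shell** around its
   nucleus — the rind `dilate(nucleus) \ (all nuclei)` that samples the
   perinuclear cytoplasm — lies inside the transduced volume.

The transduction efficiency is `E = N_Td / N_Tot`: the number of cells whose
shell overlap fraction reaches the threshold, over the number of cells that
survive all size filters.

## Pipeline stages and parameters

All physical thresholds are in µm³ and converted to voxel counts through the
stack's voxel geometry; "larger than T" is strict everywhere.

| stage | parameter | default | rationale |
|---|---|---|---|
| intensity preprocessing | 50% binning | 2×2×2 block mean | halves each axis, reduces shot noise before segmentation |
| denoising | Gaussian diameter | 0.829 µm | physical kernel; per-axis σ = (d/2)/spacing |
| transduced segmentation | probability threshold | 0.5 | voxels with probability *lower* than 50% are excluded, so exactly 0.5 is kept |
| transduced segmentation | minimum object | 10 µm³ | removes speckle; 26-connected components, strict > |
| nuclei ingest | volume band | (10 µm³, ∞) | segmenter-level debris filter; the nominal upper bound is unbounded |
| nuclei filter | minimum volume | 100 µm³ | excludes fragments and partial nuclei before shell construction |
| shell construction | dilation radius | 2 voxels | ≈ 0.82 µm lateral thickness on the 0.412 µm binned grid |
| shell filter | minimum volume | 50 µm³ human / 30 µm³ mouse | removes artifact shells; shells with volume ≥ the bound are kept |
| classification | overlap threshold | 0.4 | calibrated against manual counting; fraction ≥ 0.4 ⇒ transduced |
| depth profile | bin width | 10 µm | half-open bins [10k, 10(k+1)), labelled by centre |
| inference | α | 0.05 | Brown–Forsythe check, then pooled-variance t-test |

### Shell construction details

Dilation uses a discrete Euclidean ball in **voxel units** (the upstream
convention is pixel-based); anisotropy is deliberately not corrected, though
a physical-radius mode (`dilation_um`) exists as an extension.  In dense
packing the dilations of neighbouring nuclei collide; shell ownership of a
contested voxel goes to the nucleus with the nearest surface voxel, exact
ties to the smaller label id.  This makes shells pairwise disjoint and
disjoint from every nucleus voxel, so the per-cell overlap fraction
(`|shell ∩ mask| / |shell|`, exact integer counting) is well defined.  The
implementation enumerates the ball's integer offsets and keeps a running
nearest-nucleus assignment per voxel; it is verified exactly against an
exhaustive per-voxel brute-force oracle in the test suite.

The overlap denominator is the shell's own voxel count — the only reading
under which a dimensionless 0.4 threshold makes sense per cell.

### Pixel classifier

The transduced volume is segmented by a bagged-decision-tree ensemble
(a random forest, 25 trees, depth ≤ 14, seeded) over multiscale per-voxel
features: Gaussian-smoothed intensity, gradient magnitude and Laplacian at
0.5 and 1.0 µm physical scales (three features per scale).  Training data is
a sparse set of annotated voxels drawn on a few planes spanning the depth
range (by default ¼, ½ and ¾ of stack depth) in both dim and bright regions,
which is what makes the classifier robust to per-cell brightness variation
and to residual depth-dependent gain; no explicit depth-gain correction is
applied.  Probabilities are thresholded at 0.5 and components not strictly
larger than 10 µm³ are removed.

### Aggregation hierarchy

Efficiency is computed per imaged area; an organoid's efficiency is the
unweighted mean of its areas; a condition/timepoint efficiency is the
unweighted mean over organoids.  The pooled cell ratio is *not* used:
organoids with more cells must not dominate.  Dispersion is the unbiased
(N−1) SD over organoids and SEM = SD/√N; SEM is reported as missing (never
zero) for a single organoid.  Depth profiles apply the same hierarchy within
each 10 µm bin, excluding empty bins from every mean rather than imputing
zero.  Within one area the count-weighted bin efficiencies recompose the
area's overall efficiency exactly (a test asserts this identity).

Profile normalization (for comparing depth penetration across conditions) is
exposed as a mode — whole-stack pooled efficiency (default), peak bin,
explicit reference, or none — and the applied mode and reference are recorded
in the output, since no single convention is canonical.

### Threshold calibration

The overlap threshold is the pipeline's one free parameter.  Calibration
compares, per candidate threshold, a 2D surrogate efficiency — the
transduced fraction among shells intersecting the upper (¼ depth) and centre
(½ depth) planes — with the annotator-mean manual efficiency on those
planes, and minimizes the mean absolute deviation, ties resolved toward the
larger (more conservative) threshold.  Two ambiguities were decided here and
recorded in the calibration report: (a) a 2D plane's "cells" are defined as
the shells intersecting that z-plane, the closest 3D analogue of counting in
an extracted image; (b) the deviation is minimized over the *mean* of the
two planes rather than matched per plane.  The lowest plane is excluded from
the reference because manual counting deep in the stack is unreliable.

### Statistics

Equality of variances uses Levene's test with the group median
(Brown–Forsythe); if it passes at α = 0.05, a two-sided pooled-variance
unpaired t-test follows (both via `scipy.stats`, with explicit handling of
the zero-variance degenerate cases).  Significance stars: `**` for p ≤ 0.01
and `******` for p ≤ 10⁻⁶, plus the conventional `*` tier for p ≤ 0.05,
which is included by convention.  No multiple-testing correction is applied.

## The phantom generator

The phantom emulates the standard acquisition this pipeline targets — a
(1024 × 1024 × 400)-voxel confocal stack of (211 × 211 × 100) µm³, analysed
at 50% binning (0.412 × 0.412 × 0.5 µm voxels):

- **Nuclei**: axis-aligned prolate ellipsoids, equatorial diameter
  5 ± 1 µm (clipped to 3–8 µm), elongated 1.3–1.8× along the optical axis
  (photoreceptor-like radial orientation; the elongation also puts typical
  nuclear volumes near the 100 µm³ filter, exercising it realistically).
  Placement is dart-throwing with an ellipsoidal exclusion test plus a
  0.2 µm gap; rasterization is first-come, so labels are always disjoint.
- **Layering**: a nuclear-density gap (±2 µm) at 40 µm depth separates an
  outer from an inner layer; transduction probability can be set per layer.
- **Reporter**: each transduced cell gets a cytoplasmic rind (voxels within
  1.5 µm of its nucleus, excluding all nuclei) at a per-cell brightness
  drawn from a bimodal model — 50% dim (mean 600 counts) and 50% bright
  (mean 6000), each with lognormal spread σ = 0.4 — over a 100-count
  background.
- **Acquisition**: residual linear depth gain (±15% across the stack, the
  remnant after hardware illumination ramping), Gaussian PSF blur
  (σ = 0.3 µm), Poisson noise (gain 5) and Gaussian read noise (σ = 20).
  Truth outputs (labels, transduced mask, per-cell table) are noise-free.
- **Determinism**: one `numpy` PCG64 generator seeded from the config; the
  same config and seed reproduce every output bit-for-bit.

`degrade_labels` perturbs a truth segmentation (seeded merges of touching
instances, centroid-plane splits, per-instance erosion) for robustness tests
against imperfect upstream segmentation.

### What the phantom does not model

No optics-accurate PSF (a single Gaussian, no axial asymmetry or spherical
aberration), no spectral crosstalk between channels, no autofluorescence
texture, no nucleus-shape irregularity beyond ellipsoids, no spatial
correlation of transduction with vessel/surface distance, and cytoplasm is a
uniform rind rather than a full cell body.  Passing phantom tests therefore
demonstrates the correctness of the *quantification logic* (shell geometry,
counting, filters, aggregation) and the classifier's robustness to brightness
bimodality and depth gain — not segmentation performance on real confocal
texture, which depends on the external nuclei segmenter and on annotation
quality.

## Problem sizes and numerical choices

Desk-scale validation uses (100 × 256 × 256)-voxel phantoms — a
(50 × 105 × 105) µm³ sub-volume preserving both nuclear layers — with
200–700 nuclei; these sizes keep the full suite comfortably reproducible on
a single CPU while leaving a few hundred cells after the size filters, so
binomial counting error stays well under the tolerances being asserted.
Parameter recovery runs the *entire* pipeline (annotation → training →
probability prediction → mask → shells → classification) at true fractions
0.2/0.5/0.8 over 10 seeds each and requires ≤ 0.05 mean absolute error; the
residual positive bias at low fractions (~0.03) is real and comes from
non-transduced cells whose shells abut a transduced neighbour's cytoplasm —
exactly the false-positive mode the 0.4 threshold is calibrated to control.

Other numerical conventions: coordinates are 0-based voxel centres in
(z, y, x) order with depth = centroid-z × dz from the shallowest plane;
moment ellipsoids use semi-axis `√(5 λᵢ)` of the voxel-coordinate covariance
(exact for a uniform solid ellipsoid), with coplanar voxel sets flagged and
floored at one voxel spacing; `um3_to_voxels` rounds up (`ceil`) so that the
strict "larger than" comparison is preserved after unit conversion; empty
efficiency denominators raise rather than returning 0.

## Known limitations

- Shell ownership of contested voxels is a modelling choice (nearest surface,
  ties to smaller id); other conventions would shift overlap fractions of
  tightly packed cells slightly.
- The voxel-unit dilation makes physical shell thickness anisotropic
  (0.82 µm laterally vs 1.0 µm axially on the binned grid); the `dilation_um`
  mode trades fidelity to the pixel-based convention for isotropy.
- The classifier is a generic ilastik-style pixel classifier; parity with any
  specific commercial trainer can only be asserted behaviourally (controls,
  recovery), not feature-by-feature.
- 2D plane efficiencies for calibration depend on the shell-intersection
  definition of "cells in a plane"; annotators see membrane outlines instead,
  so a residual systematic offset between the two readouts is expected.
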