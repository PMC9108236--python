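# Methods

## Coordinate conventions

All volumes live on axis-aligned grids in the DICOM LPS patient frame:
array axis 0 is x (+x = Left), axis 1 is y (+y = Posterior), axis 2 is z
(+z = Superior); voxel `(i, j, k)` sits at `origin + spacing·(i, j, k)` mm.
Masks are compared only on a shared grid — comparing structures from
different grids raises, preventing silent misregistration; resampling must
be explicit.

A `RigidTransform` follows the resampling convention: it maps a point in
the primary (fixed) frame to the location of the same anatomy in the
secondary series, `p_moving = R(p_fixed − c) + c + t`, with intrinsic
Z-Y-X Euler angles and rotation centre `c` at the registration ROI
centroid. Under this convention the recorded translation `t` *is* the
anatomy's displacement in the secondary series relative to the primary —
the number a planning system displays after registration — so the
deformation vector `d = t_ref − t_marker` directly equals the target
surrogate's displacement relative to the marker, the quantity the margin
must cover. (With the opposite mapping direction the recorded translations
negate, and the margin would be built on the wrong side of the target.)
Shifting the moving series by `v` shifts the recovered translation by
`+v`, which is asserted on the phantom.

## Registration chain

* **Spine, 6-DOF.** Mean-squared intensity difference restricted to the
  spine ROI (both series are same-modality CT-like), multi-resolution
  (shrink 4×/2×/1×, smoothing 2/1/0 mm) with a gradient-free Powell
  optimiser; the fixed image is cropped to the ROI bounding box (4-voxel
  pad) since metric cost scales with fixed-sample count. Capture range
  ±10° / ±40 mm; a result outside it is flagged, not discarded. Rotations
  are estimated here once and frozen for the rest of the chain, mirroring
  translation-only single-marker tracking.
* **Marker, translation-only.** Closed form: the moving series is
  resampled under the spine transform, the marker is detected in both
  series as the intensity-weighted centroid of the largest connected
  component above 1500 HU (metal vs bone; configurable) inside the marker
  ROI, and the translation is updated by the centroid difference. Closed-
  form matching is robust to streak artefacts and bit-reproducible.
* **Reference structure, translation-only.** Normalised cross-correlation
  of intensities inside the reference ROI, maximised over a deterministic
  three-stage search: all whole-voxel offsets within ±10 mm, a 0.25 mm
  grid spanning ±1 voxel around the coarse optimum, then one per-axis
  parabolic refinement on the 0.25 mm step (applied only when it strictly
  improves the score, so exact optima stay exact). Equivalent in capture
  range to a dense 0.5 mm exhaustive scan but ~100× cheaper, with a finer
  final step; no random restarts, so repeated runs are identical and
  observer-style variability can only enter through ROI choice. A
  zero-variance ROI raises "reference structure not discriminable".

On the default phantom (1.5 mm voxels, 20 HU noise) the chain recovers
programmed deformation vectors to ≲0.45 mm per component, well under the
1-voxel requirement; with noise removed the error falls below 0.25 mm.

## Margin construction

`gdm_margin` takes per-direction maxima of the deformation-vector
components, clamping negative maxima to zero: the margin guards against
underdose only and never shrinks the target. `expand_anisotropic` realises
the Minkowski sum with the `[−R,+L]×[−A,+P]×[−I,+S]` box as three
separable 1-D dilations. Directed extents are voxelised by rounding **up**
(`ceil(margin/spacing − 1e-6)`): upward rounding never clips the margin,
keeps every nearest-voxel-shifted CTV copy contained even when the margin
estimate carries sub-voxel registration error (to-nearest rounding fails
exactly at half-voxel knife-edges), and the 1e-6-voxel tolerance keeps an
exactly-zero margin the identity expansion. The union alternative
`itv_gdm_sum` always includes the untranslated copy (the CTV is defined on
the expiration series) and raises if a translated copy would lose voxels
off the grid. `expand_isotropic` thresholds the Euclidean distance
transform of the complement at the margin radius, respecting anisotropic
spacing. An octant-wise quasi-ellipsoid kernel is available behind
`kernel="ellipsoid"` for comparison with planning systems that round their
expansions; it does not guarantee containment of the shifted copies and is
never the default.

Containment `CTV ⊆ ITV_GDM-SUM ⊆ ITV_GDM ⊆ PTV_GDM` follows from the box
construction (upward-rounded extents dominate every rounded shift) and is
asserted voxelwise on every build.

## Metrics

DICE is computed on voxel counts. H-AVE is the symmetrised mean
nearest-neighbour distance between boundary voxels (mean of the two
directed means — the one-line textbook definition is direction-ambiguous,
and the symmetric mean is the convention of the cited literature), with
boundaries defined by 6-connectivity (grid exterior counts as background)
and distances taken between boundary-voxel centres via a Euclidean
distance transform. Surface-mesh distances are out of scope; the choice is
stated so results are bit-reproducible. Both metrics are verified against
O(n²) brute-force boundary scans on randomized masks to 1e-9.

## Observer-variability statistics

Pairing schemes: 3 unordered repeat pairs per observer per patient
(intra), all 3×3 cross-observer pairs (inter). Summaries use the
arithmetic mean and the n−1 sample SD — this convention reproduces the
shipped table's printed SDs (0.083, 0.036, 0.063) from its raw values —
with display rounding of 2 decimals for DICE and 1 for H-AVE, as in the
tables; unrounded values are retained. Pooled statistics pool individual
values, never row means. Group tests are two-sided t-tests: Welch for
unequal-size groups (the headline 12-vs-60-value comparison cannot be
paired), paired for matched designs. The "margin covering the observed
variability" readout is an explicit inclusive empirical quantile with
default coverage 0.95 rather than a hard-coded 2 mm, because the pooled
H-AVE maximum in the shipped tables is 3.1 mm (95 % coverage gives
2.2 mm; 2 mm covers 89 % of the pooled values). Histograms use 0.05 DICE
bins and 0.25 mm H-AVE bins.

The fixture tables follow the published per-patient values verbatim; their
recomputed grand means are intra 0.89 / 1.1 mm and inter 0.88 / 1.2 mm.
(The source's prose quotes the two DICE means swapped relative to its own
tables; the fixtures follow the tables and the discrepancy is left as is.)

## Synthetic phantom

The phantom emulates the planning study's geometry, not CT physics: a
soft-tissue body ellipsoid (40 HU) in air (−1000), a rigid posterior spine
cylinder (700), a heart blood-pool ellipsoid (300, contrast analogue), a
2.5 mm-radius metal marker (3000), a 4.5 mm contrast heterogeneity (+150
over heart) as reference structure, and a 9 mm spherical CTV, on a 96³
grid at 1.5 mm — small enough to render a five-series study in under a
second while leaving headroom for ±10 mm motion. Surfaces get a ~1-voxel
linear edge so sub-voxel translations shift intensities smoothly, and
Gaussian noise (default sd 20 HU) is added per phase from the study seed.

Motion is hierarchical: a body shift (optionally a rotation) carries
everything including the spine; a heart shift carries marker, reference
structure and target; independent per-phase offsets δ_m(φ) and δ_r(φ) add
marker- and reference-relative motion, so the marker–target deformation
`δ_r − δ_m` is a first-class programmed quantity with exact ground truth.
The default breathing profile is superior–inferior dominant with smaller
A-P/L-R components; the inspiration phase sits deterministically at the
amplitude extreme (instructed inspiration exaggerates the free-breathing
range) while free-breathing phases are drawn uniformly within ±amplitude
(±0.3·amplitude off-axis), reproducibly under the seed. Default amplitude
8 mm heart excursion with reference-structure offsets up to ~0.35 of it,
giving deformations of a few millimetres — the scale at which an
anisotropic margin visibly differs from an isotropic one.

What the phantom does not emulate: beam hardening, scatter and streak
artefacts (an optional artefact stressor exists only for marker-detection
tests), cardiac-cycle ECG-phase structure, intensity texture, and
non-rigid organ deformation beyond the piecewise-rigid hierarchy. Passing
recovery tests therefore demonstrates correctness of the registration and
margin machinery under controlled deformation, not clinical registration
accuracy on artefact-laden CT.

## Numerical choices and degenerate inputs

* Whole-voxel mask shifts round half away from zero (platform-independent
  tie-break); voxels shifted off-grid are dropped with a warning in
  `translate_structure` but are an error inside `itv_gdm_sum`.
* Masks resample with nearest-neighbour, scalar images trilinearly; the
  identity transform on an identical grid is a bit-exact no-op.
* Two empty masks make DICE undefined (error); H-AVE requires two
  non-empty masks.
* Expansions that would leave the grid raise and advise padding, before
  any computation.
* The pipeline report rounds floats to 6 decimals and serialises with
  sorted keys, so identical config + seed reproduce byte-identical JSON;
  the manifest hash covers only numerically relevant configuration.

## Problem sizes

Default study: 1 primary + 4 secondary series at 96³/1.5 mm. The test
suite uses ≤48³ grids for oracle comparisons, 50 randomized pairs for the
metric oracles, and 20 seeded phantom studies (80 full registration
chains) for the recovery and containment suites; the acceptance script
runs 5 phantom studies per invocation. These sizes were chosen so the
whole suite completes in minutes on one CPU while every oracle check stays
exhaustive at full precision.

## Known limitations

* Rotations are never re-estimated after the spine step; real intra-heart
  rotation appears as translation error in the deformation vectors.
* The clinical workflow's registrations are manual; this implementation is
  deterministic, so observer variability must be injected via ROI or
  repeat-level perturbations rather than arising naturally.
* DICOM / RT-STRUCT I/O, deformable registration, dose calculation and
  couch-frame conventions are out of scope; images travel as NRRD/NIfTI
  with identity direction matrices only.
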