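# Methods

## Problem and model

The pipeline decides whether two 3D surface models of a maxillary sinus
air space belong to the same person. The decision statistic is the RMS
point-to-surface distance after rigid superimposition: with AM reference
vertices `p_i` and registered PM surface `S`,
`RMS = sqrt(mean_i d(p_i, S)^2)` in mm, and the call is *match* iff
`RMS < 1.00 mm` (boundary → mismatch, the conservative direction for an
identification claim). The distance is asymmetric — AM vertices against
the PM surface, the AM model being the reference — with the symmetric mean
available but not the headline statistic, and the average is uniform over
vertices (area weighting is offered as an option but "each point of the
model" is the defining convention).

## Synthetic cohort

Real repeat-segmentation CT data cannot be redistributed, so the cohort
module generates stand-ins with the two properties the analysis actually
depends on: smooth inter-individual shape variation that dominates a small
intra-individual repeat noise.

Each subject/side shape is a star-shaped surface: an ellipsoid with
half-extents `base_semi_axes = (17, 12, 16) mm` (typical adult maxillary
sinus extent) displaced radially by a smooth random field — a mixture of
real spherical harmonics of degrees 1..`harmonic_order = 4` with i.i.d.
normal coefficients, analytically normalized (by basis orthonormality) so
the field's standard deviation over the sphere is `shape_amplitude_sd =
2.0 mm`. Degree 0 is excluded so the deformation is not a pure inflation.
Male geometry is the female geometry scaled by `male_scale = 1.05`
(sinuses are larger in males; the factor multiplies the whole shape so sex
acts purely as a size effect). The left side is the x-mirror of the
subject's base geometry with an independent deformation draw: sides are
treated as distinct anatomical traits, and the experiment never compares
across sides, so no left/right correlation is needed.

Repeat acquisition, mesh path: a second spherical-harmonic field with sd
`repeat_noise_sd = 0.15 mm`, independent per acquisition, displaces the
vertices radially. Spatially correlated jitter (same low-order basis as
the shape field) was chosen over per-vertex white noise because
re-segmentation errors are spatially coherent boundary shifts; 0.15 mm
puts the post-registration match RMS at the few-tenths-of-a-millimetre
scale seen in repeat human segmentations. Volume path: the shape's exact
implicit form (star-shaped radius function) is voxelized at
`voxel_spacing = 1 mm` (matching a 1 mm reconstruction thickness) into
air (−1000) inside and bone (700) outside with additive N(0, 30) intensity
noise, then re-segmented, so AM/PM differences arise from thresholding and
surface extraction themselves. Spacing coarser than 8 voxels across the
smallest semi-axis is rejected.

Every draw comes from a dedicated RNG stream keyed by
`(seed, sex, subject index, side, acquisition)`, so the cohort is a pure
function of its config and adding subjects never perturbs existing draws.

What the generator does **not** emulate: real sinus morphology (septa,
ostium, recesses, dental-root protrusion), pathology (sinusitis
opacification), age- or edentulism-related change, and inter-population
shape variation. Passing tests therefore demonstrate that the *pipeline*
behaves correctly in the stated noise regime, not that real sinuses are
unique; that claim belongs to the underlying clinical literature.

## Segmentation

Seeded region growing: the mask is the union, over seeds, of the
6-connected components of the thresholded set `{low ≤ value ≤ high}`
containing each seed. 6-connectivity (faces only) prevents leakage through
diagonal voxel contacts. A seed outside the grid is an index error; a seed
whose intensity falls outside the window is rejected by name. The default
window for synthetic volumes is `[-1100, -200]` (air-like); real gray
ranges are operator-chosen and always overridable — the module deliberately
exposes the range, the seeds and any post-editing rather than hard-coding
values that are not published. No morphological post-processing is applied.

Surfaces are extracted by marching cubes at iso-level 0.5 of the binary
mask, with vertices mapped to world mm (`origin + index · spacing`,
0-based indices) and faces oriented outward (positive enclosed volume).
The mask must not touch the grid boundary, or the surface could not close.

## Registration

ICP with exact point-to-surface correspondences: each moving vertex is
paired with its true nearest point on the reference surface
(point-to-triangle, not nearest vertex, so the objective matches the
distance statistic; nearest-vertex is available as a documented fallback).
The inner step is the closed-form Kabsch/SVD solution with the determinant
corrected to +1 — reflections are forbidden because left and right models
are never cross-compared. No trimming or outlier rejection is applied: the
models are complete closed surfaces.

Nearest-point queries are exact and fast without any external spatial
index: the distance to the nearest reference *vertex* bounds the distance
to the surface from above, so a centroid k-d-tree ball query of radius
(bound + largest centroid-to-vertex triangle radius) provably contains the
nearest triangle, and the exact closest point is evaluated on that
candidate set only.

Initialization defaults to centroid + principal axes, enumerating the four
proper sign combinations and keeping the one with least surface RMS on a
vertex subsample; this recovers poses up to at least 30° rotation and
20 mm translation. Stopping: relative objective decrease below
`rel_tolerance = 1e-6` or `max_iterations = 100`, with an absolute floor
of 1e-12 mm for exact self-registration. The per-iteration objective RMS
is recorded; it is non-increasing by the usual two-step argument (new
correspondences cannot be farther than old pairs; Kabsch cannot increase
the paired sum of squares), and tests assert this on every run.

## Experiment design and statistics

With `n` subjects per sex, matches pair each subject's AM and PM model per
side (`4n` pairs); mismatches pair subject `i`'s AM with subject
`i+1 mod n`'s PM within each sex and side (`4n` pairs) — circular pairing
is the deterministic, balanced choice among the many unstated ways to draw
mismatches, and a seeded random re-pairing is available. Sexes and sides
are never mixed. At the study design size `n = 50` this gives 200 matches
and 200 mismatches, 100 per side each.

The RMS table feeds a full-factorial fixed-effects three-way ANOVA
(sex × side × group) fitted by OLS; on the balanced design the Type
I/II/III decompositions coincide (balance is asserted; unbalanced input
falls back to Type II and is flagged). Eta-squared is classical,
`SS_term / SS_total`, so the terms sum to at most 1. The multiple-
comparison family is the three main effects: Bonferroni-corrected alpha
`0.05 / 3 ≈ 0.017`, applied to interactions as well. P-values are kept at
full precision internally; the rendered report prints `<0.001`.

## Numerical and scale choices

Meshes are icosphere-based (default 3 subdivisions, 642 vertices), a
resolution at which the RMS statistic is stable to well under the 1 mm
decision scale while keeping a full 400-superimposition experiment at a
few minutes on one CPU. The test suite runs its end-to-end experiment at
10 subjects per sex (80 superimpositions) — the same generator regime at a
size that keeps the suite fast — while `scripts/acceptance.py` runs the
full 50-per-sex design. Mesh I/O canonicalizes to binary little-endian
PLY; CSV output rounds RMS to 4 decimals (two more than the decision needs,
avoiding round-trip loss).

## Known limitations

Synthetic shapes are star-shaped by construction, so they cannot represent
folds or overhangs; the ICP has no global multi-start beyond the PCA sign
enumeration and could in principle fall into a local minimum for shapes
far less similar than any tested here; the 1 mm threshold is taken as
given, and no ROC or likelihood-ratio analysis is performed; volumes are
handled as single 3D grids, not DICOM series.
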