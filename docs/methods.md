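# Methods

`ushisto` implements, as a reusable pipeline, the ground-truth-transfer
workflow used when resected-specimen 3D ultrasound (US) is validated
against histopathology: landmark registration of a US slice to its
whole-slide image (WSI), transfer of the pathologist's tumor annotation
(HTA) into the US frame, per-sector resection-margin and tumor-thickness
measurement, and agreement/correlation statistics between annotation
sources. Because paired patient data of this kind are not public, the
package ships a synthetic phantom generator with known ground truth;
every claim the test suite makes is a property of the method evaluated
on that phantom, not a reproduction of any clinical dataset.

## Coordinate conventions

All geometry lives in physical millimetres: origin at the image corner,
x rightward (columns), y downward (rows), pixel centres at half-integer
index offsets. 3D Slicer markup files use RAS world coordinates; `(R, A)`
maps to `(x, −y)` (and LPS input is converted through RAS). The slice
coordinate (S) is ignored on read and written as zero — the registration
is strictly in-plane, matching a workflow in which histology sections
are cut parallel to the US sweep.

## Registration

For each slice/slide pair the annotator supplies circumferential
landmarks along the specimen outline in both modalities and up to three
fiducial cannula tracks (left / middle / right along the specimen's long
axis). Four point-list variants are formed: (1) circumferential
landmarks only, validated on all fiducials; (2)–(4) circumferential
landmarks plus two of the three fiducials, validated on the left-out
one. With k < 3 fiducials the enumeration generalizes to variant 1 plus
all leave-one-out subsets of size k − 1; with none, registration is
refused because the target registration error (TRE) would be undefined.

The transform `T_M` maps US → WSI coordinates. Three models are
available:

* **rigid** — rotation + translation, closed-form orthogonal Procrustes
  (SVD of the cross-covariance);
* **similarity** (default) — adds one isotropic scale, the classical
  Umeyama solution. The scale term is essential here because formalin
  fixation and paraffin embedding shrink the tissue roughly isotropically
  relative to the fresh-specimen US, and a rigid model would push that
  shrinkage into the residuals;
* **affine** — normal equations; available for shear-like distortions,
  at the cost of needing non-collinear landmarks and being less
  interpretable.

A point configuration whose best orthogonal fit is a reflection raises
an error for rigid/similarity rather than silently flipping: a physical
slide cannot be mirrored relative to its US slice, so reflection demand
indicates a labelling mistake.

TRE for one variant is the mean Euclidean distance, in the WSI frame,
between the transformed US validation marker(s) and their WSI
counterparts. The variant with the lowest TRE wins; ties break toward
the lowest variant id so results are deterministic (and the noise-free
phantom, where every variant is exact, reports variant 1).

Annotation transfer applies `T_M⁻¹` to the HTA polygon vertices.
Contours are carried as polygons and rasterized only when a mask is
required (pixel-centre even-odd rule, half-open boundary convention), so
the high-resolution pathology contour is never resampled twice.

## Margins and thickness

A margin is the minimum Euclidean distance between tumor-boundary and
specimen-boundary points, both restricted to an angular wedge about the
tumor centroid. Defaults: the "deep" direction is +y (away from the
mucosal surface at the top of the image), wedge half-angle 45°, with
cranial and caudal at ±90° from deep; the mucosal sector is not
measured. Both boundaries are resampled at 0.05 mm before the
constrained nearest-pair search. Note that for a far-side sector the
wedge minimum is genuinely smaller than the on-axis distance (the
nearest admissible pair sits off-axis); the narrow-wedge limit recovers
the on-axis value, and the tests pin both behaviours on analytic circle
configurations. Tumor thickness is the extent of the tumor polygon
projected onto the deep axis.

Specimen boundaries are extracted from label masks by marching squares
at the 0.5 level. The raw marching-squares polygon of a binary mask
carries a staircase oscillation that inflates perimeter-type quantities
by ~6%; a 5-sample circular moving average over the vertices reduces the
error on a digitized circle to ~0.4% while moving the boundary by well
under a pixel. Sub-pixel accuracy beyond that is not attempted.

## Agreement statistics

Measurements from the two US sources (manual `US_M`, registered
`US_Reg`) are joined to the WSI measurement of the same slide and
region. Agreement is summarized Bland-Altman style — mean difference
and mean ± 1.96·SD limits of agreement (sample SD, n−1; no small-sample
t correction) — and association by Spearman's rank correlation
(Pearson on mid-ranks; exact two-sided permutation p for n ≤ 9, t
approximation with n − 2 df otherwise). Besides the pooled table,
strata are formed on the two-modality mean: [0, 5), [5, 10), [10, ∞) mm
— boundaries are left-closed since the conventional "< 5, 5 < 10, > 10"
labels leave the endpoints ambiguous. The < 5 mm stratum is the
clinically critical one (close margins trigger adjuvant treatment).
Strata with fewer than 3 pairs are flagged uncomputed. Slides from the
same patient are pooled without a clustering adjustment; p-values in
the report should be read accordingly.

## Segmentation metrics

Dice (two empty masks define DSC = 1), average surface distance and
HD95 operate on the pooled symmetric boundary-distance multiset:
distances from every boundary pixel of A to B's boundary and vice
versa, via a Euclidean distance transform with physical (possibly
anisotropic) spacing. Boundary pixels are mask pixels with a
face-neighbour outside (4-connectivity in 2D, 6 in 3D). HD95 is the
95th percentile with linear interpolation between order statistics —
the convention of the widely used evaluation tooling. Directed variants
are exposed behind a flag.

## The phantom

Each slice pair is built from vector geometry in the US frame:

* **specimen** — an ellipse (semi-axes a ≈ 11.5–16 mm by b ≈ 7.5–12.5 mm
  at patient level, with ±10% slice-to-slice variation) modulated by
  low-frequency radial perturbations, emulating a tongue-specimen
  cross-section;
* **tumor** — a smaller blob, offset toward deep, constrained to lie
  inside the specimen with at least 0.8 mm clearance (the generator
  shrinks and recentres up to 12 times, then raises a generation error
  naming the constraint);
* **fiducials** — up to three points at −0.55/0/+0.55 of the long
  semi-axis, emulating cannula tracks;
* **histology counterpart** — a known similarity transform (default
  0.90 isotropic shrinkage, 6° rotation, (1.2, 0.8) mm translation)
  applied to all US geometry, optionally followed by a smooth residual
  deformation (3×3 control points, spline-interpolated, amplitude in
  mm, default 0). The deformation displaces contours and
  circumferential landmarks but not the recorded fiducial truth pairs:
  the cannula track traverses the whole specimen and its centroid
  localization is treated as insensitive to the low-frequency field, so
  the stored ground-truth transform maps true fiducial positions
  exactly.

Size ranges were chosen so that a 29-slide cohort's measurements span
all three magnitude strata (a few millimetres for deep margins up to
>10 mm for thickness and long-axis margins), as a specimen study of
oral tongue carcinoma would. The 0.90 shrinkage default reflects the
order of magnitude commonly reported for fixation shrinkage of oral
soft tissue; it is configurable and nothing downstream assumes it.

Noise enters in exactly two observable places: landmark-selection
jitter (Gaussian per coordinate, default SD 0.1 mm — of the order of a
few US pixels at 0.076 mm spacing) and the manual US tumor annotation,
whose boundary is displaced by a smooth random radial field with
pointwise SD 1.0 mm by default (a sum of Fourier modes up to order 6
with variances summing to the target, so the displacement at any angle
is Gaussian with the stated SD). The pathologist's HTA is treated as
exact, matching its role as the reference standard. Manual-annotation
error in US has, to our knowledge, never been quantified directly; the
1.0 mm default is an assumption, not a fit.

Randomness is split per (patient, slice, purpose) via seed-sequence
spawn keys, so enabling one noise source never reshuffles another —
this is what makes the jitter-monotonicity tests paired and sharp.

A fixed fraction (default 3/32) of generated slides is excluded via a
dedicated stream, emulating the histopathology workflow's loss of
subdivided slides and tumor-free sections; the default cohort of
8 patients × 4 slices therefore retains 29 slides.

**What the phantom does not model:** US speckle and texture (images are
piecewise-constant intensity), H&E appearance, cannula artifact
physics, multi-focal or perforating tumors, out-of-plane (3D)
misalignment between the US slice and the section plane, and
non-smooth localized tissue damage. Passing tests therefore demonstrate
correctness of the geometry, estimation and statistics under the stated
noise model — not robustness to reading real images, which is the
annotator's task in this workflow, nor registration accuracy under
gross tissue distortion.

## Numerical choices and degenerate inputs

* Transform estimation is closed-form; no iterative optimizer is used
  at run time (optimizers appear only as test oracles).
* Rasterization resolves boundary ties half-open (left/top in) via an
  epsilon nudge of the pixel-centre test points; a zero-area or
  off-grid contour yields an empty mask with a warning.
* Empty masks, disconnected specimen masks, constant vectors
  (undefined rank correlation), empty sectors, singular transforms and
  spacing-free volume files all raise typed errors; spacing is never
  assumed to be 1 mm.
* The whole pipeline is deterministic under a fixed seed; report CSVs
  are byte-identical across reruns.

## Problem sizes

Default study: 8 patients × 4 slices (29 analyzed), 384×512 px slices
at 0.076 mm spacing. The replicate sweeps in the test suite use 50
vector-only replicates per jitter level (rasterization skipped where
only landmarks are needed). The full suite runs in under two minutes on
one CPU; the acceptance script in about one.
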