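# Methods

## The problem and the approach

Quantitative tissue microscopy needs every cell segmented in situ, but the
fluorescent stains conventionally used for segmentation (a nuclear dye plus
an F-actin or membrane counterstain) occupy detection channels that
experiments usually need for biologically informative markers.  Confocal
microscopes, however, always produce a free by-product signal: back-scattered
excitation light ("reflectance"), confocally sectioned like fluorescence and
available in 2D and 3D.  `lfseg` implements the label-free segmentation
strategy built on that signal:

1. **Training sections** are stained for nuclei and cytoskeleton/membrane
   while reflectance is captured simultaneously with the same microscope
   settings.  Three-class pixel labels — background / nuclei / cytoskeleton —
   are built by thresholding the fluorescence (`lfseg.ground_truth`).
2. A **three-class U-Net** (2D or 3D) is trained with cross-entropy to map
   the reflectance image, linearly rescaled to [0, 1] against the fixed
   acquisition bit depth, to per-pixel class probabilities
   (`lfseg.unet`, `lfseg.nn`).
3. **Instance segmentation**: one marker per cell is extracted from the
   smoothed, thresholded nuclei probability; cells are flooded from those
   markers by watershed over the elevation surface
   `P(cytoskeleton) − P(nuclei)`, restricted to the foreground mask
   `1 − P(background) ≥ t`; objects outside the 5th–95th size percentiles
   are discarded (`lfseg.segmentation`).
4. **Validation** scores automated objects against manual annotations with
   the Jaccard index `J(A, M) = |A∩M| / |A∪M|`; for volumes, orthogonal
   xy / zy / xz cross-sections are scored against 2D annotations
   (`lfseg.evaluation`).
5. **Profiling**: per-cell intensity and binarized fluorescence-area
   features, control-informed sequential gating, four-level expression
   binning, and nearest-cell-neighbor graphs (`lfseg.profiling`).

Networks are always trained on one section and validated on a *different*
section; the command-line `evaluate` stage refuses to score a model on its
own training scene unless explicitly overridden.

## Network and training schedules

The architecture is the standard U-Net encoder–decoder: per encoder level,
two 3×3 ("same"-padded) convolutions + ReLU and 2× max pooling with filter
doubling; a two-convolution bottleneck; a decoder of 2× transposed
convolutions, skip concatenation, and two convolutions per level; a 1×1
convolution and softmax to 3 classes.  Output size equals input size.  The
full-size profiles use encoder depth 4 with 64 first-layer filters
(64-128-256-512, bottleneck 1024).

Published schedules, kept as presets:

| preset | patches | batch | epochs | optimizer | lr | drop | L2 |
|---|---|---|---|---|---|---|---|
| `published2d` | 256² | 12 | 50 (frozen) / 150 (FFPE) | SGD, momentum 0.9 | 0.05 | ×0.1 / 10 ep | 1e-4 |
| `published3d` | 64³ | 8 | 150 | Adam | 5e-4 | ×0.95 / 5 ep | 1e-4 |

Patches are drawn at random offsets (reflect-padded at borders), augmented
by x/y reflection and rotation, and reshuffled every epoch.  Rotation is
restricted to 90° multiples to avoid interpolation artifacts in label
patches.  Zero-center normalization subtracts the training image's scalar
mean after unit rescaling.  Cross-entropy is unweighted by default; a
per-class weight option exists but is off everywhere in this package.

Because this package runs on plain CPUs, the engine behind the U-Net is a
compact numpy implementation (N-dimensional convolution via strided views,
hand-written backward passes, SGD-momentum/Adam with step decay and
decoupled-from-bias L2).  Gradients are verified against central finite
differences in the test-suite.  Everything is deterministic given the seeds,
so trained weights are bit-reproducible.

Reduced profiles sized for minutes-scale training on one CPU (used by the
test-suite and the reproduction script):

* `tiny` (2D): depth 2, 8 first-layer filters, 64² patches, batch 4,
  15 epochs × 64 patches, Adam 2e-3 (×0.5 / 6 epochs).
* `tiny3d`: depth 2, 8 filters, 32³ patches, batch 2, 24 epochs × 40
  patches, Adam 3e-3 (×0.5 / 6 epochs).

## Inference

Whole images are predicted in one pass when they fit; otherwise overlapping
tiles are blended with separable linear feather ramps and the result is
renormalized to sum to one per pixel.  Tile interiors dominate; the blend
error against whole-image inference is bounded in the acceptance tests
(max abs difference < 0.05 at 30 % overlap on a trained model; the halo
rule wants overlap/2 to reach the receptive field).  Inputs are
reflect-padded to the U-Net's grid (multiples of 2^depth) and cropped back.

## Watershed parameters

* `marker_threshold` 0.5 on the Gaussian-smoothed (σ = 1 px) nuclei
  probability; components below `min_marker_size` (10 px in 2D, 30 vox in
  3D) are discarded.
* `foreground_threshold` 0.5 on `1 − P(background)`.
* **Elevation smoothing** (σ default 4 px, ~cell diameter / 5): a
  well-trained network saturates its probabilities, leaving the elevation
  surface near-flat inside cells; the residual noise would otherwise steer
  the flood order arbitrarily.  Smoothing on the scale of half a cell
  radius turns each nucleus into a smooth attraction bowl — the same reason
  interactive declumping pipelines match their smoothing filter to the
  expected object diameter.  The pipeline protocols set it to
  `mean_cell_diameter / 5`.
* Connectivity is 8-connected (2D) / 26-connected (3D), configurable.
* The size filter uses linearly interpolated percentiles; objects strictly
  below the 5th or strictly above the 95th percentile are dropped, ties
  retained, single pass on the unfiltered distribution, labels preserved.

## Evaluation choices

Matching is manual-centric: every manual cell receives a score, automated
objects are consumed at most once, assignment is greedy by descending pixel
overlap with ties to lower ids (an exhaustive-assignment oracle backs this
in the tests), and unmatched manual cells score 0 (missed cells are false
negatives).  Manual cells clipped by the image border are excluded by
default (`exclude_border=False` includes them).  For volumes, plane labels
`xy`/`zy`/`xz` (either letter order) select orthogonal sections of a
(z, y, x) volume at a given index.

## Profiling choices

* The control threshold is the 95th percentile of the *positive* (nonzero)
  pixel intensities of a tissue-matched control image — the level removing
  ~95 % of control fluorescence.  Pixel-level, not cell-level: channels are
  binarized at this cutoff before area integration.
* Gating is sequential: mean (configurable: integrated) cell intensity
  ≥ cutoff, then fluorescence area fraction ≥ `min_area_fraction`
  (default 0.25 in the pipeline protocols).  The area gate is expressed as
  a fraction of cell area for scale invariance.  Gating is monotone by
  construction: raising the cutoff or adding the area gate never enlarges
  the positive set.
* Expression bins split the positive population at its intensity quartiles
  (dim / low / intermediate / high); boundary ties fall to the lower bin;
  fewer than 4 positives cannot support quartiles and all become "dim".
* Neighbors: the startpoint cell's pixel set is dilated by a Euclidean
  disc/ball of radius 3 px and every object the dilated set touches becomes
  an edge.  The dilation is scratch space only — the startpoint's stored
  geometry is never modified, which is how we read the description of
  dilated startpoints being "subsequently eroded" (restored).  Radius 0
  degrades to the declared pixel connectivity.

## The synthetic tissue simulator

Real lymphoid tissue is almost entirely contacting cells in layered 3D
arrangements.  The simulator reproduces the *geometry* of that regime —
Voronoi tessellation of minimum-distance (dart-throwing) seed points
clipped to an elliptical tissue mask, so nearly every cell touches its
neighbors — and the *information structure* of the acquisition:

* `nuclei_fluor`: the nucleus masks (distance-to-seed ≤
  `nucleus_fraction × diameter/2`).
* `structure_fluor`: diffuse cytoplasmic fill (0.55) plus a bright cortical
  shell (1.0, `shell_thickness` from the boundary).  The fill matters: a
  shells-only stain would put cell interiors in the background class and no
  foreground-restricted watershed could then recover whole cells; real
  phalloidin/WGA staining likewise covers the cytoplasm with cortical
  enrichment.
* `reflectance`: a fixed affine mixture (shell 0.8, nucleus 0.45, cytoplasm
  0.2, ambient 0.05) with per-pixel multiplicative lognormal speckle
  (σ = 0.25) then Gaussian blur — a stationary, learnable but
  noise-corrupted mapping from structure to intensity.  The coefficients
  are constants so every scene behaves like one microscope with paired
  settings.
* `marker`: intensity on the 2 px-dilated outer shell of a seeded subset of
  cells.  The rendered channel is clipped to within 2 px of the positive
  cells after blurring, so suprathreshold spill into adjacent cells never
  exceeds 2 px; this deliberately creates bystander-positive neighbors for
  the area gate to remove.
* `marker_control`: background noise only (a secondary-only control).
* In 3D every rendered slice z is scaled by `depth_attenuation**z`.

All randomness flows through one `numpy.random.Generator`; identical
parameters and seed give bit-identical scenes.

What the simulator does **not** emulate: optical physics (PSF shape,
refraction, scattering coefficients), autofluorescence, non-specific
antibody binding, anisotropic voxels, tile-scan stitching seams, and the
actual reflectance statistics of spleen / Peyer's patch / lymph node
tissue.  Passing the desk-scale protocols therefore demonstrates that the
pipeline is internally correct and recovers structure whenever *some*
learnable reflectance-structure relationship exists — it does not certify
accuracy on any particular real tissue, where that relationship is an
empirical question.

## Desk-scale study conditions (`lfseg.benchmarks`)

* 2D: 256² scenes, 60 cells of mean diameter 18 px, nucleus fraction 0.45,
  shell 2 px, noise σ 0.03, blur 1 px; train `tiny` on one scene (seed
  2s+1), score on another (seed 2s+2); tiled prediction (128², 30 %
  overlap); watershed defaults with elevation smoothing diameter/5; size
  filter; interior truth cells scored.
* 3D: 64³ scenes, 70 cells of diameter 16 px, nucleus fraction 0.55 (a
  16-voxel cell still needs a resolvable nucleus), depth attenuation 0.995
  per slice; train `tiny3d`; per-plane scoring on xy/zy/xz slices 20, 32,
  44 pooled per plane.
* Gating: the 2D conditions with 25 % marker-positive cells; cutoff from
  the scene's own control channel at the 95 % removal level; area-fraction
  gate 0.25; features measured on truth objects to isolate gating
  behaviour.

These sizes keep the full 2D protocol ≈ 30 s and the 3D protocol ≈ 6 min
on one CPU.

## Known limitations

* The numpy engine is single-threaded apart from BLAS and is not meant for
  the published full-size schedules (depth-4/64-filter nets on tile scans);
  the `published2d`/`published3d` presets exist as faithful records of those
  schedules and for users with patience or smaller images.
* Marker-controlled watershed requires a detectable nucleus per cell;
  cells whose nuclei fall below the marker threshold merge into a
  neighbor's basin — visible in the 3D desk-scale runs where nuclei span
  only a few voxels.
* The greedy matcher is not globally optimal for pathological overlap
  patterns (the exhaustive oracle in the tests covers the regimes used).
* `filter_by_size` with < ~20 objects makes percentile estimates coarse.
* 2D/3D anisotropy is not modelled: voxels are treated as cubic.
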